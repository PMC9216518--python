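"""Transcriptome-based tumor-microenvironment scoring.

Single-sample GSEA (ssGSEA) turns a bulk expression profile and a gene
signature into one enrichment score per (sample, signature) pair: genes are
ranked within the sample, and the score integrates the difference between
the rank-weighted ECDF of signature genes and the unweighted ECDF of the
remaining genes over the whole ranked list.  On top of it sit:

* ESTIMATE-style ImmuneScore / StromalScore — ssGSEA scores of an immune
  and a stromal infiltration signature;
* the cytolytic activity score (CYT) — geometric mean of granzyme A and
  perforin 1 transcript levels;
* TIS / IIS — aggregate means of z-scored constituent signature scores
  (nine T-cell subset signatures for TIS; innate plus adaptive immune
  signatures for IIS).

The ssGSEA convention used here: per-sample midranks, weight exponent 0.25
by default, integrated (summed) ECDF difference, and no cross-sample
normalization — z-scoring is an explicit separate step.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceMatrix, DataError, SampleAnnotation
from .diffabund import bh_adjust, mann_whitney
from .pathways import PathwayCollection

__all__ = [
    "ssgsea",
    "estimate_scores",
    "cyt_score",
    "aggregate_tis_iis",
    "compare_groups",
    "SignatureScoreTable",
]

DEFAULT_SSGSEA_ALPHA = 0.25
DEFAULT_CYT_GENES = ("GZMA", "PRF1")
DEFAULT_CYT_OFFSET = 0.01


@dataclasses.dataclass
class SignatureScoreTable:
    """Samples × signatures enrichment scores."""

    scores: pd.DataFrame
    normalization_tag: str = "raw"  # raw | zscored

    def zscore(self) -> "SignatureScoreTable":
        """Z-score each signature column across samples (population SD)."""
        sd = self.scores.std(axis=0, ddof=0)
        if (sd == 0).any():
            flat = list(sd.index[sd == 0])
            warnings.warn(f"constant signature score(s) left at 0 after z-scoring: {flat}")
        z = (self.scores - self.scores.mean(axis=0)) / sd.replace(0, np.nan)
        return SignatureScoreTable(z.fillna(0.0), normalization_tag="zscored")

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.columns)


def _ssgsea_sample(ranks: np.ndarray, order: np.ndarray, hit_mask: np.ndarray,
                   alpha_weight: float) -> float:
    """Integrated ECDF difference for one sample and one signature.

    ``ranks`` are the per-sample midranks (ascending: the top-expressed
    gene has rank N), ``order`` indexes genes by decreasing expression and
    ``hit_mask`` marks signature membership in that order.
    """
    n = ranks.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    w = np.where(hit_mask, ranks[order] ** alpha_weight, 0.0)
    total = w.sum()
    p_hit = np.cumsum(w) / total
    p_miss = np.cumsum(~hit_mask) / n_miss
    return float(np.sum(p_hit - p_miss))


def ssgsea(
    expr: AbundanceMatrix,
    signatures: PathwayCollection,
    alpha_weight: float = DEFAULT_SSGSEA_ALPHA,
) -> SignatureScoreTable:
    """Per-sample enrichment score for every signature.

    Signatures resolving to fewer than 2 measured genes are skipped with a
    warning; a signature spanning the whole gene universe has no miss ECDF
    and raises.
    """
    expr.require_complete()
    genes = [str(g).casefold() for g in expr.feature_ids]
    gene_index = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    resolved: dict[str, np.ndarray] = {}
    for name, members in signatures.sets.items():
        idx = sorted({gene_index[m.casefold()] for m in members if m.casefold() in gene_index})
        if len(idx) < 2:
            warnings.warn(f"signature {name!r} has fewer than 2 measured genes; skipped")
            continue
        if len(idx) == n:
            raise DataError(f"signature {name!r} equals the entire gene universe")
        resolved[name] = np.array(idx)
    if not resolved:
        raise DataError("no signature resolved to at least 2 measured genes")

    values = expr.values()
    out = np.empty((expr.n_samples, len(resolved)))
    names = list(resolved)
    for j in range(expr.n_samples):
        col = values[:, j]
        ranks = stats.rankdata(col)          # midranks, ascending
        order = np.argsort(-ranks, kind="stable")
        in_set = np.zeros(n, dtype=bool)
        for s, name in enumerate(names):
            in_set[:] = False
            in_set[resolved[name]] = True
            out[j, s] = _ssgsea_sample(ranks, order, in_set[order], alpha_weight)
    scores = pd.DataFrame(out, index=pd.Index(expr.sample_ids, name="sample_id"),
                          columns=names)
    return SignatureScoreTable(scores=scores, normalization_tag="raw")


def estimate_scores(
    expr: AbundanceMatrix,
    immune_sig: Sequence[str],
    stromal_sig: Sequence[str],
    alpha_weight: float = DEFAULT_SSGSEA_ALPHA,
) -> pd.DataFrame:
    """ESTIMATE-style ImmuneScore and StromalScore per sample.

    Both are plain ssGSEA scores of the supplied signatures (the published
    infiltration signatures are user-supplied inputs; no purity conversion
    is applied).
    """
    collection = PathwayCollection(
        {"ImmuneScore": tuple(immune_sig), "StromalScore": tuple(stromal_sig)}
    )
    table = ssgsea(expr, collection, alpha_weight=alpha_weight)
    return table.scores


def cyt_score(
    expr: AbundanceMatrix,
    gene_a: str = DEFAULT_CYT_GENES[0],
    gene_b: str = DEFAULT_CYT_GENES[1],
    offset: float = DEFAULT_CYT_OFFSET,
) -> pd.Series:
    """Cytolytic activity: geometric mean of two effector-gene transcript levels.

    Computed as ``exp(mean(log(a + offset), log(b + offset)))`` on the
    unlogged scale; the small offset keeps zero counts finite.
    """
    if expr.scale_tag == "log2":
        raise DataError("cyt_score expects unlogged expression values")
    for gene in (gene_a, gene_b):
        if gene not in expr.data.index:
            raise DataError(f"gene {gene!r} not present in the expression matrix")
    a = expr.data.loc[gene_a].astype(float)
    b = expr.data.loc[gene_b].astype(float)
    if (a < 0).any() or (b < 0).any():
        raise DataError("cyt_score requires nonnegative expression")
    score = np.exp((np.log(a + offset) + np.log(b + offset)) / 2.0)
    score.name = "CYT"
    return score


def aggregate_tis_iis(
    scores: SignatureScoreTable,
    tis_sets: Sequence[str],
    iis_sets: Sequence[str],
) -> pd.DataFrame:
    """TIS and IIS: per-sample means of z-scored constituent signature scores."""
    missing = [s for s in [*tis_sets, *iis_sets] if s not in scores.scores.columns]
    if missing:
        raise DataError(f"constituent signatures absent from score table: {sorted(set(missing))}")
    z = scores.scores if scores.normalization_tag == "zscored" else scores.zscore().scores
    return pd.DataFrame(
        {
            "TIS": z[list(tis_sets)].mean(axis=1),
            "IIS": z[list(iis_sets)].mean(axis=1),
        },
        index=z.index,
    )


def compare_groups(
    scores: pd.DataFrame,
    annotations: SampleAnnotation,
    grouping: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of every score between two groups.

    ``grouping`` names an annotation column with exactly two levels among
    the scored samples.  Returns per-score statistic, p, BH q and the
    direction (sign of the first-group-minus-second-group median).
    """
    col = annotations.column(grouping).reindex(scores.index)
    if col.isna().any():
        missing = list(scores.index[col.isna()])[:5]
        raise DataError(f"samples without {grouping!r} annotation: {missing}")
    levels = sorted(col.unique(), key=str)
    if len(levels) != 2:
        raise DataError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    idx_a = col.index[col == levels[0]]
    idx_b = col.index[col == levels[1]]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise DataError("both groups must be nonempty")

    rows = []
    for name in scores.columns:
        a = scores.loc[idx_a, name].to_numpy(dtype=float)
        b = scores.loc[idx_b, name].to_numpy(dtype=float)
        u, p = mann_whitney(a, b)
        rows.append((name, u, p, float(np.median(a) - np.median(b))))
    table = pd.DataFrame(rows, columns=["score", "statistic", "p", "median_diff"])
    table = table.set_index("score")
    table["q"] = bh_adjust(table["p"])
    table["direction"] = np.sign(table["median_diff"]).astype(int)
    table.attrs["group_a"] = str(levels[0])
    table.attrs["group_b"] = str(levels[1])
    table.attrs["alpha"] = alpha
    return table[["statistic", "p", "q", "median_diff", "direction"]]
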