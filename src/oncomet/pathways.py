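"""Pathway sets, the weighted differential-abundance (DA) score, pre-ranked
GSEA, and cross-modality pathway-score comparison.

The weighted DA score summarizes a two-group differential result over a
pathway's measured members::

    DA = (w1*x1 + w2*x2 + ... + wn*xn) / (w1 + w2 + ... + wn)

where ``w_i = |log2 fold change|`` of member i and ``x_i`` is the ±1/0
significance indicator (+1 significant up, −1 significant down, 0 not
significant).  DA is bounded in [−1, 1]: it reaches +1 exactly when every
measured member is significantly increased, −1 when every member is
significantly decreased, and 0 when no member is significant.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError
from .diffabund import DAResult, bh_adjust

__all__ = [
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "PathwayScore",
    "weighted_da_score",
    "scores_table",
    "EnrichmentResult",
    "gsea_preranked",
    "compare_modal_da_scores",
]


@dataclasses.dataclass
class PathwayCollection:
    """Named, nonempty sets of feature identifiers (GMT-backed)."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Sequence[str]) -> "PathwayCollection":
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise DataError(f"pathways not in collection: {missing}")
        return PathwayCollection(
            {n: self.sets[n] for n in names},
            {n: self.descriptions[n] for n in names if n in self.descriptions},
        )


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: name, description, then tab-separated members.

    Duplicate members within a set are removed (first occurrence kept).
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: malformed GMT line (needs name, "
                    f"description and at least one member)"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise DataError(f"{path}:{lineno}: pathway {name!r} has no members")
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicated pathway name {name!r}")
            sets[name] = tuple(deduped)
            descriptions[name] = description
    return PathwayCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Weighted DA score
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PathwayScore:
    name: str
    da: float
    n_measured: int
    n_up: int
    n_down: int
    weights: tuple[float, ...]
    indicators: tuple[int, ...]
    degenerate: bool = False  # all measured members had log2fc exactly 0


def weighted_da_score(
    da: DAResult,
    pathways: PathwayCollection,
    min_measured: int = 3,
    id_map: Mapping[str, str] | None = None,
) -> list[PathwayScore]:
    """Score each pathway by the |log2fc|-weighted mean of its indicators.

    Members are resolved against the tested feature universe by exact
    string match after case folding; ``id_map`` optionally translates
    platform feature names to pathway vocabulary first.  Pathways with
    fewer than ``min_measured`` measured members are excluded.
    """
    lookup: dict[str, tuple[float, int]] = {}
    for fid, row in da.table.iterrows():
        key = str(fid).casefold()
        if id_map is not None:
            key = str(id_map.get(fid, fid)).casefold()
        lookup[key] = (abs(float(row["log2fc"])), int(row["x"]))

    results: list[PathwayScore] = []
    excluded: list[str] = []
    for name, members in pathways.sets.items():
        measured = [m for m in members if m.casefold() in lookup]
        if len(measured) < min_measured:
            excluded.append(name)
            continue
        w = np.array([lookup[m.casefold()][0] for m in measured])
        x = np.array([lookup[m.casefold()][1] for m in measured])
        total = w.sum()
        if total == 0:
            score, degenerate = 0.0, True
        else:
            score, degenerate = float((w * x).sum() / total), False
        results.append(
            PathwayScore(
                name=name,
                da=score,
                n_measured=len(measured),
                n_up=int((x == 1).sum()),
                n_down=int((x == -1).sum()),
                weights=tuple(float(v) for v in w),
                indicators=tuple(int(v) for v in x),
                degenerate=degenerate,
            )
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} pathway(s) excluded with < {min_measured} measured "
            f"members: {excluded[:5]}{'...' if len(excluded) > 5 else ''}"
        )
    return results


def scores_table(scores: Sequence[PathwayScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "da": [s.da for s in scores],
            "n_measured": [s.n_measured for s in scores],
            "n_up": [s.n_up for s in scores],
            "n_down": [s.n_down for s in scores],
            "degenerate": [s.degenerate for s in scores],
        },
        index=pd.Index([s.name for s in scores], name="pathway"),
    )


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    q: float
    n_hits: int

    @property
    def direction(self) -> str:
        return "enriched" if self.es >= 0 else "depleted"


def _es_from_hits(
    sorted_weights: np.ndarray, hit_pos: np.ndarray, n_total: int
) -> float:
    """Enrichment score from the positions of a set in a ranked list.

    The running sum increases by the normalized weight at each hit and
    decreases by 1/(N − n_hits) at each miss; ES is the value of maximal
    absolute deviation.  Evaluating the running sum just after each hit and
    just before each hit captures both extremes without materializing the
    full length-N walk.
    """
    hit_pos = np.sort(hit_pos)
    h = hit_pos.size
    n_miss = n_total - h
    if n_miss == 0:
        raise DataError("pathway covers the entire ranked universe")
    w = sorted_weights[hit_pos]
    total = w.sum()
    if total == 0:
        # all-zero metric weights: fall back to unweighted steps
        cum_hit = np.arange(1, h + 1) / h
    else:
        cum_hit = np.cumsum(w) / total
    # misses encountered up to and including position p_i (1-based hit count i)
    i = np.arange(1, h + 1)
    miss_after = (hit_pos + 1 - i) / n_miss
    miss_before = (hit_pos - (i - 1)) / n_miss
    dev_after = cum_hit - miss_after                 # just after hit i
    dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before  # just before hit i
    candidates = np.concatenate([dev_after, dev_before])
    return float(candidates[np.argmax(np.abs(candidates))])


def gsea_preranked(
    ranked: pd.Series,
    pathways: PathwayCollection,
    alpha_weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Pre-ranked enrichment over a feature → metric ranking.

    ES is the maximal deviation between the |metric|^alpha_weight-weighted
    ECDF of in-set features and the unweighted ECDF of out-of-set features
    along the list ranked by decreasing metric.  The null distribution is
    generated by permuting set membership (random sets of matching size);
    NES = ES / mean(|null ES| of matching sign), and the permutation p is
    two-sided on |ES| over all permutations.  BH q is computed across
    pathways.
    """
    if n_perm < 100:
        raise DataError("n_perm must be at least 100")
    metric = ranked.astype(float)
    if not np.isfinite(metric.to_numpy()).all():
        raise DataError("ranking metric must be finite for all features")
    order = metric.sort_values(ascending=False, kind="mergesort").index
    sorted_metric = metric.loc[order].to_numpy()
    sorted_weights = np.abs(sorted_metric) ** alpha_weight
    position = {str(f).casefold(): i for i, f in enumerate(order)}
    n_total = len(order)
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    for name, members in pathways.sets.items():
        hit_pos = np.array(
            sorted({position[m.casefold()] for m in members if m.casefold() in position}),
            dtype=int,
        )
        if hit_pos.size == 0:
            warnings.warn(f"pathway {name!r} has no measured members; skipped")
            continue
        if hit_pos.size == n_total:
            raise DataError(f"pathway {name!r} equals the entire ranked universe")
        es = _es_from_hits(sorted_weights, hit_pos, n_total)
        null = np.empty(n_perm)
        for j in range(n_perm):
            perm_pos = rng.choice(n_total, size=hit_pos.size, replace=False)
            null[j] = _es_from_hits(sorted_weights, perm_pos, n_total)
        # two-sided permutation p over all nulls; NES normalized by the mean
        # |null ES| of matching sign (the GSEA convention)
        p = (1 + int((np.abs(null) >= abs(es) - 1e-12).sum())) / (n_perm + 1)
        same_sign = null >= 0 if es >= 0 else null < 0
        if same_sign.any():
            nes = es / max(np.abs(null[same_sign]).mean(), 1e-12)
        else:
            nes = es / max(np.abs(null).mean(), 1e-12)
        results.append(
            EnrichmentResult(name=name, es=es, nes=nes, p=p, q=np.nan, n_hits=hit_pos.size)
        )
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "n_hits": [r.n_hits for r in results],
            "direction": [r.direction for r in results],
        },
        index=pd.Index([r.name for r in results], name="pathway"),
    )


# ---------------------------------------------------------------------------
# Cross-modality comparison
# ---------------------------------------------------------------------------

def compare_modal_da_scores(
    metab_scores: Sequence[PathwayScore],
    rna_scores: Sequence[PathwayScore],
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of metabolite- vs RNA-based pathway DA scores.

    Joins on pathway name; requires at least 3 shared pathways.  Returns
    (rho, two-sided p, paired table).
    """
    a = {s.name: s.da for s in metab_scores}
    b = {s.name: s.da for s in rna_scores}
    shared = [n for n in a if n in b]
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} shared pathways; need at least 3")
    table = pd.DataFrame(
        {"metabolite_da": [a[n] for n in shared], "rna_da": [b[n] for n in shared]},
        index=pd.Index(shared, name="pathway"),
    )
    res = stats.spearmanr(table["metabolite_da"], table["rna_da"])
    return float(res.statistic), float(res.pvalue), table
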