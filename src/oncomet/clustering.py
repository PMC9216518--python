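"""MAD feature selection, subsampled hierarchical consensus clustering,
concordance-based model selection, and cluster-of-cluster assignment (COCA)
across data modalities.

The consensus procedure repeatedly draws a random subsample of the samples
(without replacement), runs Ward/Euclidean hierarchical clustering on the
subsample, and tallies how often each pair of samples lands in the same
cluster among the iterations where both were drawn.  The concordance of a
candidate k is the mean of |2·consensus − 1| over co-sampled off-diagonal
pairs: it is 1 exactly when every pair is either always or never
co-clustered, and near 0 when co-clustering is a coin flip.  The best k
maximizes concordance; the final membership is a Ward cut of the
(1 − consensus) distance matrix.

COCA one-hot encodes the per-modality cluster calls into a samples ×
(clusters across modalities) binary matrix and runs the same consensus
procedure on it, integrating modalities without sharing feature scales.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import AbundanceMatrix, DataError, SampleAnnotation

__all__ = [
    "mad_select",
    "ward_hclust",
    "ward_linkage",
    "consensus_cluster",
    "select_best_k",
    "encode_binary",
    "coca",
    "order_clusters_by_aggressiveness",
    "ConsensusResult",
    "COCAResult",
]

#: Study defaults for MAD feature selection.
DEFAULT_TOP_GENES = 3000
DEFAULT_TOP_METABOLITES = 400


def _as_frame(m: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.data if isinstance(m, AbundanceMatrix) else m


def mad_select(m: AbundanceMatrix, top_n: int) -> AbundanceMatrix:
    """Keep the ``top_n`` features by median absolute deviation.

    MAD is the raw median of |x − median(x)| (no consistency constant —
    ranking is unaffected).  Ties are broken by feature identifier so the
    selection is deterministic.
    """
    if top_n <= 0:
        raise DataError(f"top_n must be positive, got {top_n}")
    if top_n > m.n_features:
        raise DataError(f"top_n={top_n} exceeds feature count {m.n_features}")
    med = m.data.median(axis=1, skipna=True)
    mad = (m.data.sub(med, axis=0)).abs().median(axis=1, skipna=True)
    # stable sort over a lexicographically pre-sorted index gives the
    # deterministic tie-break on feature identifiers
    ranking = mad.sort_index().sort_values(ascending=False, kind="mergesort")
    keep = list(ranking.index[:top_n])
    return m.subset_features(keep)


def ward_linkage(x: np.ndarray) -> np.ndarray:
    """Ward linkage (Lance-Williams) over rows of ``x`` with Euclidean distance."""
    return linkage(x, method="ward")


def ward_hclust(m: AbundanceMatrix | pd.DataFrame, k: int) -> pd.Series:
    """Ward/Euclidean hierarchical clustering of the sample columns, cut to k."""
    df = _as_frame(m)
    n = df.shape[1]
    if k > n:
        raise DataError(f"k={k} exceeds number of samples {n}")
    if k <= 0:
        raise DataError(f"k must be positive, got {k}")
    if df.isna().any().any():
        raise DataError("clustering requires a complete matrix")
    z = ward_linkage(df.T.to_numpy(dtype=float))
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=df.columns, name="cluster")


@dataclasses.dataclass
class ConsensusResult:
    """Consensus clustering summary for one candidate k.

    ``consensus`` holds co-clustering frequencies estimated only from
    iterations where both samples were drawn; pairs never co-sampled are
    NaN and excluded from the concordance.
    """

    k: int
    consensus: pd.DataFrame
    cosample: pd.DataFrame
    membership: pd.Series
    concordance: float
    n_iter: int
    subsample_fraction: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.consensus.index)


def _rng(seed: int | None, *path: int) -> np.random.Generator:
    """Independent substream addressed by an integer path under one master seed."""
    entropy = 0 if seed is None else int(seed)
    return np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=tuple(path)))


def consensus_cluster(
    m: AbundanceMatrix | pd.DataFrame,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    n_iter: int = 50,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
) -> dict[int, ConsensusResult]:
    """Subsampled Ward consensus clustering for each k in ``k_range``.

    Each k uses its own seeded substream, so altering ``k_range`` does not
    perturb the draws for other values of k.
    """
    df = _as_frame(m)
    n = df.shape[1]
    if not 0 < subsample_fraction <= 1:
        raise DataError("subsample_fraction must be in (0, 1]")
    if n_iter < 1:
        raise DataError("n_iter must be at least 1")
    n_draw = math.ceil(subsample_fraction * n)
    samples = list(df.columns)
    results: dict[int, ConsensusResult] = {}
    for k in k_range:
        if k > n_draw:
            raise DataError(f"k={k} exceeds subsample size {n_draw}")
        rng = _rng(seed, k)
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(n_iter):
            idx = np.sort(rng.choice(n, size=n_draw, replace=False))
            sub = df.iloc[:, idx]
            labels = ward_hclust(sub, k).to_numpy()
            onehot = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(idx, idx)] += onehot
            co_sample[np.ix_(idx, idx)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), np.nan)
        np.fill_diagonal(consensus, 1.0)
        off_diag = ~np.eye(n, dtype=bool)
        defined = off_diag & ~np.isnan(consensus)
        n_undefined = int((off_diag & np.isnan(consensus)).sum() // 2)
        if n_undefined:
            warnings.warn(
                f"k={k}: {n_undefined} sample pair(s) never co-sampled; "
                "their consensus entries are undefined and excluded from concordance"
            )
        concordance = float(np.abs(2 * consensus[defined] - 1).mean())
        membership = _cut_consensus(consensus, samples, k)
        results[k] = ConsensusResult(
            k=k,
            consensus=pd.DataFrame(consensus, index=samples, columns=samples),
            cosample=pd.DataFrame(co_sample, index=samples, columns=samples),
            membership=membership,
            concordance=concordance,
            n_iter=n_iter,
            subsample_fraction=subsample_fraction,
        )
    return results


def _cut_consensus(consensus: np.ndarray, samples: list[str], k: int) -> pd.Series:
    """Final membership: Ward cut of (1 − consensus) treated as a distance."""
    dist = 1.0 - consensus
    # never-co-sampled pairs carry no evidence either way
    dist = np.where(np.isnan(dist), 0.5, dist)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=samples, name="cluster")


def select_best_k(results: Mapping[int, ConsensusResult]) -> int:
    """argmax of the concordance curve; ties go to the smallest k."""
    if not results:
        raise DataError("no consensus results to select from")
    return max(sorted(results), key=lambda k: results[k].concordance)


def encode_binary(memberships: Mapping[str, pd.Series]) -> pd.DataFrame:
    """One-hot encode per-modality cluster calls into a samples × clusters matrix.

    Samples missing from any modality are dropped with a warning; each row
    sums to the number of modalities.
    """
    if not memberships:
        raise DataError("no memberships given")
    modality_names = list(memberships)
    shared = list(memberships[modality_names[0]].index)
    for name in modality_names[1:]:
        index = set(memberships[name].index)
        shared = [s for s in shared if s in index]
    dropped = {
        s
        for name in modality_names
        for s in memberships[name].index
        if s not in shared
    }
    if dropped:
        warnings.warn(f"{len(dropped)} sample(s) missing from some modality; dropped")
    if not shared:
        raise DataError("no samples shared across modalities")
    blocks = []
    for name in modality_names:
        calls = memberships[name].loc[shared]
        onehot = pd.get_dummies(calls).astype(int)
        onehot.columns = [f"{name}:{c}" for c in onehot.columns]
        blocks.append(onehot)
    return pd.concat(blocks, axis=1)


@dataclasses.dataclass
class COCAResult:
    binary: pd.DataFrame
    membership: pd.Series           # sample → integer cluster
    labels: pd.Series | None        # sample → C1..Ck (after aggressiveness ordering)
    k: int
    concordance_by_k: dict[int, float]
    consensus: ConsensusResult
    label_map: dict[int, str] | None = None
    aggressive_proportion: dict[str, float] | None = None


def coca(
    memberships: Mapping[str, pd.Series],
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    n_iter: int = 50,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
    k_override: int | None = None,
) -> COCAResult:
    """Cluster-of-cluster assignment across ≥2 modalities.

    Runs consensus clustering on the one-hot encoded membership matrix.
    The returned concordance curve makes a ``k_override`` (e.g. choosing a
    smaller k than the concordance argmax to keep clusters populated)
    auditable.
    """
    if len(memberships) < 2:
        raise DataError("COCA requires at least 2 modalities")
    binary = encode_binary(memberships)
    results = consensus_cluster(
        binary.T.astype(float),
        k_range=k_range,
        n_iter=n_iter,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )
    curve = {k: r.concordance for k, r in results.items()}
    k = k_override if k_override is not None else select_best_k(results)
    if k not in results:
        raise DataError(f"k_override={k} not in evaluated k_range {sorted(results)}")
    chosen = results[k]
    return COCAResult(
        binary=binary,
        membership=chosen.membership,
        labels=None,
        k=k,
        concordance_by_k=curve,
        consensus=chosen,
    )


def order_clusters_by_aggressiveness(
    membership: pd.Series,
    annotations: SampleAnnotation,
) -> tuple[pd.Series, dict[int, str], dict[str, float]]:
    """Relabel clusters C1..Ck by nondecreasing proportion of aggressive tumors.

    Aggressive = widely invasive histology or recurrence.  Ties are broken
    by cluster size (ascending) then by lowest original cluster index.
    Returns (per-sample labels, original→label map, label→proportion).
    """
    agg = annotations.aggressive().reindex(membership.index)
    if agg.isna().any():
        missing = list(membership.index[agg.isna()])[:5]
        raise DataError(f"samples without annotation: {missing}")
    stats_rows = []
    for cluster_id, members in membership.groupby(membership):
        prop = float(agg.loc[members.index].mean())
        stats_rows.append((cluster_id, prop, len(members)))
    ordered = sorted(stats_rows, key=lambda r: (r[1], r[2], r[0]))
    label_map = {cid: f"C{i + 1}" for i, (cid, _, _) in enumerate(ordered)}
    proportions = {label_map[cid]: prop for cid, prop, _ in ordered}
    labels = membership.map(label_map)
    labels.name = "coca_cluster"
    return labels, label_map, proportions
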