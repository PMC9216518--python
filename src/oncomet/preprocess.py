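"""Metabolomics normalization chain and the freeze-time QC screen.

The chain applied to raw Metabolon-style intensities is

1. :func:`block_correct` — per-feature scaling so each run-day batch has
   median 1, removing day-to-day instrument drift while preserving ratios
   within a batch;
2. :func:`impute_min` — detection-limit imputation with the feature's
   minimum observed level across all samples;
3. :func:`pqn_normalize` — probabilistic quotient normalization, dividing
   each sample by its most probable dilution factor (the median ratio of
   the sample to a reference spectrum);
4. :func:`log2_transform`.

:func:`freeze_time_screen` is a quality-control step that flags features
whose abundance correlates with the time the specimen spent unfrozen.
Flagged features are reported, never removed.

All functions are pure: inputs are never mutated.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceMatrix, DataError, SampleAnnotation
from .diffabund import bh_adjust

__all__ = [
    "block_correct",
    "impute_min",
    "pqn_normalize",
    "log2_transform",
    "freeze_time_screen",
    "QCScreenResult",
    "normalize_chain",
]


def block_correct(m: AbundanceMatrix, blocks: SampleAnnotation | pd.Series) -> AbundanceMatrix:
    """Scale each (feature, run-day block) so the block median is 1.

    Missing values are ignored when computing the median; a feature that is
    entirely missing within some block cannot be corrected and raises.
    """
    m.require_scale("raw")
    block_series = blocks.blocks() if isinstance(blocks, SampleAnnotation) else blocks
    missing = [s for s in m.sample_ids if s not in block_series.index]
    if missing:
        raise DataError(f"samples without a block assignment: {missing[:5]}")
    out = m.data.copy()
    for block_id, cols in m.data.T.groupby(block_series.loc[m.sample_ids]):
        sub = cols.T  # features × samples-in-block
        med = sub.median(axis=1, skipna=True)
        if med.isna().any():
            feat = med.index[med.isna()][0]
            raise DataError(
                f"feature {feat!r} has no measured values in block {block_id!r}"
            )
        out.loc[:, sub.columns] = sub.div(med, axis=0)
    return m.with_data(out, "block_corrected")


def impute_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing entries with the feature's minimum observed level.

    Models values below the instrument's detection limit: the smallest
    measured intensity of a metabolite is taken as its effective floor.
    """
    m.require_scale("raw", "block_corrected")
    mins = m.data.min(axis=1, skipna=True)
    if mins.isna().any():
        feat = mins.index[mins.isna()][0]
        raise DataError(f"feature {feat!r} has no measured values; cannot impute")
    out = m.data.T.fillna(mins).T
    return m.with_data(out, "imputed")


def pqn_normalize(
    m: AbundanceMatrix, reference_samples: list[str] | None = None
) -> tuple[AbundanceMatrix, pd.Series]:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-feature median across samples (or
    across ``reference_samples`` if given).  Each sample's quotient is the
    median over features of sample/reference — the most probable dilution
    factor — and the sample is divided by it.

    Returns the normalized matrix and the per-sample quotients.
    """
    m.require_scale("raw", "block_corrected", "imputed")
    m.require_complete()
    m.require_positive()
    ref_cols = m.data if reference_samples is None else m.data.loc[:, reference_samples]
    reference = ref_cols.median(axis=1)
    if (reference <= 0).any():
        raise DataError("reference spectrum contains non-positive values")
    quotients = m.data.div(reference, axis=0).median(axis=0)
    quotients.name = "quotient"
    return m.with_data(m.data.div(quotients, axis=1), "pqn"), quotients


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    m.require_scale("raw", "block_corrected", "imputed", "pqn")
    m.require_complete()
    m.require_positive()
    return m.with_data(np.log2(m.data), "log2")


def normalize_chain(
    m: AbundanceMatrix, blocks: SampleAnnotation | pd.Series
) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.Series]:
    """Run the full chain; returns (log2 matrix, pqn matrix, quotients).

    The pqn-scale matrix is kept because fold changes are defined on the
    unlogged normalized scale.
    """
    corrected = block_correct(m, blocks)
    imputed = impute_min(corrected)
    normalized, quotients = pqn_normalize(imputed)
    return log2_transform(normalized), normalized, quotients


# ---------------------------------------------------------------------------
# Freeze-time QC screen
# ---------------------------------------------------------------------------

#: Sample sizes up to which the Spearman p-value is computed by exhaustive
#: permutation rather than the large-sample t approximation.
EXACT_SPEARMAN_MAX_N = 8


@dataclasses.dataclass
class QCScreenResult:
    """Per-feature Spearman association with freeze time.

    ``table`` has columns ``rho``, ``p``, ``q`` and ``flagged``; flagged is
    exactly ``q < q_threshold``.  Flagged features are candidates for
    pre-analytical confounding and are reported, not removed.
    """

    table: pd.DataFrame
    q_threshold: float

    @property
    def flagged_features(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])

    @property
    def n_flagged(self) -> int:
        return int(self.table["flagged"].sum())


def _spearman_exact_p(x: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman rho at tiny n.

    Enumerates all n! orderings of the freeze-time vector; ties are handled
    through midranks (Pearson correlation of rank vectors).
    """
    n = len(x)
    rx = stats.rankdata(x)
    rt = stats.rankdata(t)
    rx_c = rx - rx.mean()
    rt_c = rt - rt.mean()
    denom = np.sqrt((rx_c**2).sum() * (rt_c**2).sum())
    if denom == 0:
        raise DataError("constant vector: Spearman correlation undefined")
    rho_obs = float(rx_c @ rt_c / denom)
    perms = np.array(list(itertools.permutations(rt_c)))
    rho_all = perms @ rx_c / denom
    p = float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def freeze_time_screen(
    m: AbundanceMatrix,
    freeze_time: pd.Series | SampleAnnotation,
    q_threshold: float = 0.05,
) -> QCScreenResult:
    """Screen every feature for Spearman correlation with freeze time.

    p-values are tie-corrected; for n ≤ 8 samples they come from the exact
    permutation distribution of rho, otherwise from the usual t
    approximation.  q is the Benjamini-Hochberg adjustment across features.
    """
    if isinstance(freeze_time, SampleAnnotation):
        freeze_time = freeze_time.freeze_time()
    missing = [s for s in m.sample_ids if s not in freeze_time.index]
    if missing:
        raise DataError(f"freeze time unknown for samples: {missing[:5]}")
    t = freeze_time.loc[m.sample_ids].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise DataError("freeze-time vector is constant: correlation undefined")

    values = m.values()
    n = values.shape[1]
    rhos = np.empty(m.n_features)
    ps = np.empty(m.n_features)
    for i in range(m.n_features):
        if n <= EXACT_SPEARMAN_MAX_N:
            rhos[i], ps[i] = _spearman_exact_p(values[i], t)
        else:
            res = stats.spearmanr(values[i], t)
            rhos[i], ps[i] = res.statistic, res.pvalue
    qs = bh_adjust(ps)
    table = pd.DataFrame(
        {"rho": rhos, "p": ps, "q": qs, "flagged": qs < q_threshold},
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    return QCScreenResult(table=table, q_threshold=q_threshold)
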