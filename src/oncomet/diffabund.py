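"""Two-group differential testing: Mann-Whitney U for metabolites,
empirical-Bayes moderated t for genes, Benjamini-Hochberg correction, fold
changes, and the ±1/0 significance indicator consumed by the weighted
pathway DA score.

Conventions
-----------
* All p-values are two-sided.
* The fold-change estimator defaults to ``log2(mean(a)/mean(b))`` on the
  unlogged normalized scale; a median-ratio alternative is available and
  the choice is recorded in the result metadata.
* The BH family is the set of all features tested in one contrast.
* The indicator x is +1 when q < alpha and log2fc >= 0, −1 when q < alpha
  and log2fc < 0, and 0 otherwise.
"""
from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import AbundanceMatrix, DataError

__all__ = [
    "mann_whitney",
    "bh_adjust",
    "log2_fold_change",
    "differential_abundance",
    "moderated_t",
    "fit_variance_prior",
    "select_heatmap_features",
    "ContrastSpec",
    "DAResult",
]

#: Combined sample size at or below which (tie-free) Mann-Whitney p-values
#: are computed by exact enumeration of labelings.
EXACT_U_MAX_N = 12

FCDefinition = Literal["mean_ratio", "median_ratio"]


@dataclasses.dataclass
class ContrastSpec:
    """A two-group comparison: samples in ``group_a`` versus ``group_b``."""

    group_a: list[str]
    group_b: list[str]
    alpha: float = 0.05
    fc_definition: FCDefinition = "mean_ratio"

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise DataError("contrast groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise DataError("contrast groups must be disjoint")
        if not 0 < self.alpha < 1:
            raise DataError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclasses.dataclass
class DAResult:
    """Per-feature differential result.

    ``table`` columns: ``log2fc``, ``statistic``, ``p``, ``q``, ``x``.
    ``metadata`` records alpha, the group sizes, the test used and the
    fold-change definition so downstream tables are self-describing.
    """

    table: pd.DataFrame
    metadata: dict

    @property
    def alpha(self) -> float:
        return self.metadata["alpha"]

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["x"] != 0]


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of group a) with a two-sided p-value.

    Uses exact enumeration when the combined sample size is ≤ 12 and the
    data are tie-free; otherwise the normal approximation with midranks,
    tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_U_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(
    a: Sequence[float], b: Sequence[float], fc_definition: FCDefinition = "mean_ratio"
) -> float:
    """log2 ratio of group-a to group-b level on the unlogged scale."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if fc_definition == "mean_ratio":
        num, den = a.mean(), b.mean()
    elif fc_definition == "median_ratio":
        num, den = np.median(a), np.median(b)
    else:
        raise DataError(f"unknown fc_definition {fc_definition!r}")
    if num <= 0 or den <= 0:
        raise DataError("fold change undefined for non-positive group level")
    return float(np.log2(num / den))


def _indicator(q: np.ndarray, log2fc: np.ndarray, alpha: float) -> np.ndarray:
    x = np.zeros(q.shape, dtype=int)
    sig = q < alpha
    x[sig & (log2fc >= 0)] = 1
    x[sig & (log2fc < 0)] = -1
    return x


def differential_abundance(m: AbundanceMatrix, contrast: ContrastSpec) -> DAResult:
    """Per-feature Mann-Whitney test with BH correction and fold changes.

    The rank test is invariant to monotone transforms, so it may run on any
    scale; fold changes are always computed on the unlogged values.
    """
    if len(contrast.group_a) < 2 or len(contrast.group_b) < 2:
        raise DataError("each contrast group needs at least 2 samples")
    sub_a = m.subset_samples(contrast.group_a)
    sub_b = m.subset_samples(contrast.group_b)
    sub_a.require_complete()
    sub_b.require_complete()
    va, vb = sub_a.values(), sub_b.values()
    lin_a = sub_a.unlogged().to_numpy(dtype=float)
    lin_b = sub_b.unlogged().to_numpy(dtype=float)

    n_feat = m.n_features
    stat = np.empty(n_feat)
    p = np.empty(n_feat)
    fc = np.empty(n_feat)
    for i in range(n_feat):
        stat[i], p[i] = mann_whitney(va[i], vb[i])
        fc[i] = log2_fold_change(lin_a[i], lin_b[i], contrast.fc_definition)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"log2fc": fc, "statistic": stat, "p": p, "q": q,
         "x": _indicator(q, fc, contrast.alpha)},
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    metadata = {
        "test": "mann_whitney_u",
        "alpha": contrast.alpha,
        "fc_definition": contrast.fc_definition,
        "n_a": len(contrast.group_a),
        "n_b": len(contrast.group_b),
    }
    return DAResult(table=table, metadata=metadata)


# ---------------------------------------------------------------------------
# Moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _s02_given_d0(mean_log_s2: float, df: int, d0: float) -> float:
    """Solve the mean equation of the log-variance model for s0^2 at fixed d0."""
    log_s0 = mean_log_s2 - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    if np.isfinite(d0) and d0 > 0:
        log_s0 += special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
    return float(np.exp(log_s0))


def fit_variance_prior(s2: Sequence[float], df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square variance prior.

    Models per-gene sample variances as ``s2_g ~ s0^2 * d0/chi2(d0) *
    chi2(df)/df`` and matches the mean and variance of ``log(s2)`` using
    digamma/trigamma moments.  Returns ``(d0, s0_squared)``; ``d0`` is
    ``inf`` when the observed spread of log variances is no larger than
    expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    if df <= 0:
        raise DataError("residual degrees of freedom must be positive")
    if np.any(s2 <= 0):
        s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e_z = z.mean()
    var_z = z.var(ddof=1) if z.size > 1 else 0.0
    excess = var_z - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # no excess spread: all true variances equal; moment on the raw scale
        return np.inf, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0 = (
        e_z
        - special.polygamma(0, df / 2.0)
        + np.log(df / 2.0)
        + special.polygamma(0, d0 / 2.0)
        - np.log(d0 / 2.0)
    )
    return float(d0), float(np.exp(log_s0))


def moderated_t(
    m: AbundanceMatrix,
    contrast: ContrastSpec,
    prior_df: float | None = None,
) -> DAResult:
    """Two-sample moderated t-test on a log-scale expression matrix.

    The per-gene pooled variance ``s_g^2`` (df = n_a + n_b − 2) is shrunk
    toward a prior ``s0^2`` with prior df ``d0``::

        s_tilde^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

    and the t statistic referred to a t distribution with ``d0 + df``
    degrees of freedom.  ``(d0, s0^2)`` are estimated from the data by
    :func:`fit_variance_prior` unless ``prior_df`` forces d0 (0 recovers
    the ordinary t-test; ``inf`` pools all genes to a common variance).

    log2fc here is the difference of group means, which is the log ratio
    when the matrix holds log2 values.
    """
    if len(contrast.group_a) < 2 or len(contrast.group_b) < 2:
        raise DataError("each contrast group needs at least 2 samples")
    sub_a = m.subset_samples(contrast.group_a)
    sub_b = m.subset_samples(contrast.group_b)
    sub_a.require_complete()
    sub_b.require_complete()
    va, vb = sub_a.values(), sub_b.values()
    na, nb = va.shape[1], vb.shape[1]
    df_resid = na + nb - 2
    if df_resid <= 0:
        raise DataError("zero residual degrees of freedom")

    mean_a, mean_b = va.mean(axis=1), vb.mean(axis=1)
    ss = va.var(axis=1, ddof=1) * (na - 1) + vb.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s02 = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s02 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s02 = _s02_given_d0(np.log(np.maximum(s2, 1e-300)).mean(), df_resid, d0)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    delta = mean_a - mean_b
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"log2fc": delta, "statistic": t, "p": p, "q": q,
         "x": _indicator(q, delta, contrast.alpha)},
        index=pd.Index(m.feature_ids, name="feature_id"),
    )
    metadata = {
        "test": "moderated_t",
        "alpha": contrast.alpha,
        "n_a": na,
        "n_b": nb,
        "d0": d0,
        "s0_squared": s02,
    }
    return DAResult(table=table, metadata=metadata)


def select_heatmap_features(da: DAResult, q_cut: float, fc_cut: float) -> list[str]:
    """Features with q < q_cut and |log2fc| > fc_cut, strongest effect first."""
    t = da.table
    keep = t[(t["q"] < q_cut) & (t["log2fc"].abs() > fc_cut)]
    keep = keep.reindex(keep["log2fc"].abs().sort_values(ascending=False).index)
    return list(keep.index)
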