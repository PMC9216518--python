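"""Synthetic paired metabolomics / expression datasets with known ground truth.

The generator emulates the structure of a semiquantitative LC-MS tumor
metabolomics study with matched bulk RNA-seq:

* log-normal base abundances with per-feature location and spread drawn
  from configurable hyperpriors (positive, right-skewed MS intensities);
* multiplicative run-day batch factors shared by all samples in a block;
* per-sample dilution factors (what PQN is meant to undo);
* detection-limit censoring: the lowest quantile of each feature's values
  is emitted as missing;
* planted tumor-vs-normal log2 effects on chosen metabolites;
* a freeze-time covariate with an additive linear trend (on the log scale)
  on a small feature subset;
* latent sample clusters shared — imperfectly — across the two
  modalities, realized as Gaussian centroid shifts on a reserved feature
  block, with per-modality label corruption at rate 1 − modality_agreement;
* immune-infiltration gradients that shift signature genes proportionally
  to a per-sample infiltration level.

One master seed is expanded into named substreams (one per stage), so
adding a stage never perturbs the draws of earlier stages, and identical
configs with identical seeds are bit-reproducible.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, ConfigError, SampleAnnotation
from .pathways import PathwayCollection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_metabolomics",
    "simulate_expression",
    "simulate_multiomic",
]

# substream addresses under the master seed
_SUB_BLOCKS = 1
_SUB_FREEZE = 2
_SUB_MET_FEATURES = 3
_SUB_MET_VALUES = 4
_SUB_DILUTION = 5
_SUB_CLUSTERS = 6
_SUB_MET_CLUSTER_SHIFT = 7
_SUB_HISTOLOGY = 8
_SUB_GENOTYPE = 9
_SUB_EXPR_FEATURES = 10
_SUB_EXPR_VALUES = 11
_SUB_INFILTRATION = 12
_SUB_EXPR_CLUSTER_SHIFT = 13
_SUB_CORRUPT_MET = 14
_SUB_CORRUPT_EXPR = 15


@dataclasses.dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the profiled cohort: 32 tumors and 16 adjacent
    normals, 728 metabolites, a 16,853-gene transcriptome, and run-day
    batching; 12 features carry a freeze-time trend.  The missingness
    quantile is a free parameter of the generator (real detection-limit
    rates are instrument-dependent) and defaults to 5%.
    """

    n_tumor: int = 32
    n_normal: int = 16
    n_metabolites: int = 728
    n_genes: int = 16853
    n_blocks: int = 4
    effect_table: Sequence[tuple[str, float]] = ()
    dilution_range: tuple[float, float] = (0.5, 2.0)
    censor_quantile: float = 0.05
    n_freeze_assoc: int = 12
    freeze_slope: float = 0.04      # log2 units per hour of freeze delay
    freeze_time_range: tuple[float, float] = (0.0, 48.0)
    n_latent_clusters: int = 4
    cluster_sep: float = 2.0        # centroid scale, in units of feature SD
    n_cluster_features: int = 60    # reserved feature block carrying cluster shifts
    modality_agreement: float = 0.85
    infiltration_levels: Sequence[float] | None = None
    infiltration_gain: float = 2.0  # log2 shift of signature genes at level 1
    feature_log2_mean: tuple[float, float] = (17.0, 2.0)   # hyperprior (mu, sd)
    feature_log2_sd: tuple[float, float] = (0.5, 1.5)      # hyperprior (lo, hi)
    block_log2_sd: float = 0.3      # SD of per-(feature, block) batch factors
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("n_tumor", "n_normal", "n_metabolites", "n_genes",
                      "n_blocks", "n_freeze_assoc", "n_latent_clusters",
                      "n_cluster_features"):
            if getattr(self, field) < 0:
                raise ConfigError(f"{field} must be >= 0")
        if self.n_blocks == 0:
            raise ConfigError("n_blocks must be >= 1")
        lo, hi = self.dilution_range
        if lo <= 0 or hi < lo:
            raise ConfigError("dilution_range must be a positive interval (lo <= hi, lo > 0)")
        if not 0 <= self.censor_quantile < 1:
            raise ConfigError("censor_quantile must be in [0, 1)")
        if not 0 <= self.modality_agreement <= 1:
            raise ConfigError("modality_agreement must be in [0, 1]")
        if self.cluster_sep < 0:
            raise ConfigError("cluster_sep must be >= 0")
        if self.infiltration_levels is not None:
            levels = np.asarray(self.infiltration_levels, dtype=float)
            if np.any((levels < 0) | (levels > 1)):
                raise ConfigError("infiltration_levels must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_tumor + self.n_normal

    def rng(self, *path: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(int(self.seed), spawn_key=tuple(path))
        )


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted, keyed by emitted identifiers."""

    true_effects: dict[str, float]
    true_dilutions: dict[str, float]
    true_blocks: dict[str, int]
    true_clusters: dict[str, int]
    freeze_assoc_features: set[str]
    true_infiltration: dict[str, float] = dataclasses.field(default_factory=dict)
    modality_clusters: dict[str, dict[str, int]] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sample_ids(config: SimulationConfig) -> list[str]:
    width = max(2, len(str(max(config.n_tumor, config.n_normal))))
    tumors = [f"T{i + 1:0{width}d}" for i in range(config.n_tumor)]
    normals = [f"N{i + 1:0{width}d}" for i in range(config.n_normal)]
    return tumors + normals


def _shared_sample_frame(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Sample annotations and latent assignments shared by both modalities."""
    samples = _sample_ids(config)
    n = config.n_samples
    is_tumor = np.array([s.startswith("T") for s in samples])

    rng_blocks = config.rng(_SUB_BLOCKS)
    blocks = rng_blocks.permutation(np.arange(n) % config.n_blocks)

    rng_freeze = config.rng(_SUB_FREEZE)
    lo, hi = config.freeze_time_range
    freeze = rng_freeze.uniform(lo, hi, size=n)

    # latent clusters among tumor samples, balanced then shuffled
    clusters = np.full(n, -1)
    if config.n_latent_clusters > 0 and config.n_tumor > 0:
        rng_cl = config.rng(_SUB_CLUSTERS)
        assign = rng_cl.permutation(np.arange(config.n_tumor) % config.n_latent_clusters)
        clusters[is_tumor] = assign

    # histology and genotype flags; aggressiveness enriched in later clusters
    rng_hist = config.rng(_SUB_HISTOLOGY)
    rng_geno = config.rng(_SUB_GENOTYPE)
    histology = np.where(is_tumor, "HMIN", "normal").astype(object)
    recurrence = np.zeros(n, dtype=bool)
    k = max(config.n_latent_clusters, 1)
    for i in range(n):
        if not is_tumor[i]:
            continue
        c = clusters[i] if clusters[i] >= 0 else 0
        p_wide = 0.2 + 0.6 * (c / max(k - 1, 1))
        if rng_hist.random() < p_wide:
            histology[i] = "HWIDE"
            recurrence[i] = rng_hist.random() < 0.15 + 0.5 * (c / max(k - 1, 1))
    gloh = is_tumor & (rng_geno.random(n) < 0.5)
    mtdna = is_tumor & (rng_geno.random(n) < 0.65)
    mtor = is_tumor & (rng_geno.random(n) < 0.8)
    tert = is_tumor & (rng_geno.random(n) < 0.2)

    ann = pd.DataFrame(
        {
            "group": np.where(is_tumor, "tumor", "normal"),
            "histology": histology,
            "recurrence": recurrence,
            "gLOH": gloh,
            "mtDNA": mtdna,
            "mTOR": mtor,
            "TERT": tert,
            "block": blocks,
            "freeze_time": freeze,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    latent = {
        "is_tumor": is_tumor,
        "clusters": clusters,
        "samples": samples,
    }
    return ann, latent


def _corrupt_labels(
    clusters: np.ndarray, agreement: float, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Reassign each labeled sample to a random other cluster w.p. 1 − agreement."""
    out = clusters.copy()
    if n_clusters < 2:
        return out
    for i in range(out.size):
        if out[i] < 0:
            continue
        if rng.random() < 1.0 - agreement:
            choices = [c for c in range(n_clusters) if c != out[i]]
            out[i] = rng.choice(choices)
    return out


def _cluster_shift_matrix(
    n_features: int,
    feature_sd: np.ndarray,
    clusters: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    start: int,
) -> np.ndarray:
    """Additive log2 shifts for the reserved cluster-feature block.

    Each cluster gets a Gaussian centroid of scale ``cluster_sep`` (in
    units of the feature SD) on ``n_cluster_features`` features starting at
    index ``start``.
    """
    shifts = np.zeros((n_features, clusters.size))
    if config.cluster_sep == 0 or config.n_latent_clusters == 0:
        return shifts
    stop = min(start + config.n_cluster_features, n_features)
    block = np.arange(start, stop)
    centroids = rng.normal(
        0.0, 1.0, size=(config.n_latent_clusters, block.size)
    ) * config.cluster_sep
    for j, c in enumerate(clusters):
        if c >= 0:
            shifts[block, j] = centroids[c] * feature_sd[block]
    return shifts


def simulate_metabolomics(
    config: SimulationConfig,
    cluster_labels: np.ndarray | None = None,
) -> tuple[AbundanceMatrix, SampleAnnotation, GroundTruth]:
    """Generate a raw metabolite matrix with batches, dilutions and censoring.

    Emitted values are ``2^(base + effects) × block_factor × dilution``;
    entries below each feature's ``censor_quantile`` are NaN.
    ``cluster_labels`` overrides the drawn latent partition (used by
    :func:`simulate_multiomic` to inject per-modality corrupted labels).
    """
    ann, latent = _shared_sample_frame(config)
    samples: list[str] = latent["samples"]
    is_tumor: np.ndarray = latent["is_tumor"]
    clusters: np.ndarray = latent["clusters"] if cluster_labels is None else cluster_labels
    n, p = config.n_samples, config.n_metabolites

    features = [f"M{i + 1:04d}" for i in range(p)]
    f_index = {f: i for i, f in enumerate(features)}

    rng_feat = config.rng(_SUB_MET_FEATURES)
    mu = rng_feat.normal(*config.feature_log2_mean, size=p)
    sd = rng_feat.uniform(*config.feature_log2_sd, size=p)
    block_factors = np.exp2(
        rng_feat.normal(0.0, config.block_log2_sd, size=(p, config.n_blocks))
    )

    rng_vals = config.rng(_SUB_MET_VALUES)
    log2_vals = mu[:, None] + sd[:, None] * rng_vals.standard_normal((p, n))

    # planted tumor effects
    true_effects: dict[str, float] = {}
    for fid, effect in config.effect_table:
        if fid not in f_index:
            raise ConfigError(f"effect_table names unknown feature {fid!r}")
        true_effects[fid] = float(effect)
        log2_vals[f_index[fid]] += float(effect) * is_tumor

    # freeze-time trend on a feature subset disjoint from planted effects
    free = [f for f in features if f not in true_effects]
    if config.n_freeze_assoc > len(free):
        raise ConfigError("n_freeze_assoc exceeds available features")
    freeze_feats = list(rng_feat.choice(free, size=config.n_freeze_assoc, replace=False))
    t_centered = ann["freeze_time"].to_numpy() - ann["freeze_time"].mean()
    for fid in freeze_feats:
        log2_vals[f_index[fid]] += config.freeze_slope * t_centered

    # latent cluster shifts on a reserved block (placed after effect features)
    rng_shift = config.rng(_SUB_MET_CLUSTER_SHIFT)
    start = min(len(true_effects) + config.n_freeze_assoc, p)
    log2_vals += _cluster_shift_matrix(p, sd, clusters, config, rng_shift, start)

    rng_dil = config.rng(_SUB_DILUTION)
    dilution = rng_dil.uniform(*config.dilution_range, size=n)

    values = np.exp2(log2_vals)
    values *= block_factors[:, ann["block"].to_numpy()]
    values *= dilution[None, :]

    if config.censor_quantile > 0:
        cutoffs = np.quantile(values, config.censor_quantile, axis=1, keepdims=True)
        values = np.where(values < cutoffs, np.nan, values)

    matrix = AbundanceMatrix(
        pd.DataFrame(values, index=pd.Index(features, name="feature_id"), columns=samples),
        scale_tag="raw",
    )
    truth = GroundTruth(
        true_effects=true_effects,
        true_dilutions=dict(zip(samples, dilution.tolist())),
        true_blocks=dict(zip(samples, ann["block"].tolist())),
        true_clusters={s: int(c) for s, c in zip(samples, clusters) if c >= 0},
        freeze_assoc_features=set(freeze_feats),
    )
    return matrix, SampleAnnotation(ann), truth


def simulate_expression(
    config: SimulationConfig,
    signatures: PathwayCollection | None = None,
    cluster_labels: np.ndarray | None = None,
) -> tuple[AbundanceMatrix, SampleAnnotation, GroundTruth]:
    """Generate a TPM-like expression matrix with infiltration gradients.

    Genes belonging to any supplied signature are shifted per sample by
    ``infiltration_gain × level`` log2 units; a reserved gene block carries
    latent cluster shifts.  Values are emitted on the linear scale with no
    batch structure or censoring (normalized expression input).
    """
    if config.infiltration_levels is not None and (signatures is None or len(signatures) == 0):
        raise ConfigError("infiltration_levels given but signatures is empty")
    ann, latent = _shared_sample_frame(config)
    samples: list[str] = latent["samples"]
    clusters: np.ndarray = latent["clusters"] if cluster_labels is None else cluster_labels
    n, p = config.n_samples, config.n_genes

    genes = [f"G{i + 1:05d}" for i in range(p)]
    g_index = {g.casefold(): i for i, g in enumerate(genes)}

    rng_feat = config.rng(_SUB_EXPR_FEATURES)
    mu = rng_feat.normal(5.0, 2.0, size=p)
    sd = rng_feat.uniform(*config.feature_log2_sd, size=p)

    rng_vals = config.rng(_SUB_EXPR_VALUES)
    log2_vals = mu[:, None] + sd[:, None] * rng_vals.standard_normal((p, n))

    # infiltration gradient on signature genes
    infiltration = np.zeros(n)
    sig_gene_idx: set[int] = set()
    if signatures is not None and len(signatures) > 0:
        if config.infiltration_levels is not None:
            levels = np.asarray(config.infiltration_levels, dtype=float)
            if levels.size != n:
                raise ConfigError(
                    f"infiltration_levels has {levels.size} entries for {n} samples"
                )
            infiltration = levels
        else:
            infiltration = config.rng(_SUB_INFILTRATION).uniform(0.0, 1.0, size=n)
        for name, members in signatures.sets.items():
            for m in members:
                idx = g_index.get(m.casefold())
                if idx is None:
                    warnings.warn(f"signature gene {m!r} not in gene universe; skipped")
                    continue
                sig_gene_idx.add(idx)
        for idx in sig_gene_idx:
            log2_vals[idx] += config.infiltration_gain * infiltration

    # latent cluster shifts on a reserved block of non-signature genes
    rng_shift = config.rng(_SUB_EXPR_CLUSTER_SHIFT)
    start = 0
    while start in sig_gene_idx:
        start += 1
    log2_vals += _cluster_shift_matrix(p, sd, clusters, config, rng_shift, start)

    matrix = AbundanceMatrix(
        pd.DataFrame(np.exp2(log2_vals), index=pd.Index(genes, name="feature_id"),
                     columns=samples),
        scale_tag="raw",
    )
    truth = GroundTruth(
        true_effects={},
        true_dilutions={},
        true_blocks=dict(zip(samples, ann["block"].tolist())),
        true_clusters={s: int(c) for s, c in zip(samples, clusters) if c >= 0},
        freeze_assoc_features=set(),
        true_infiltration=dict(zip(samples, infiltration.tolist())),
    )
    return matrix, SampleAnnotation(ann), truth


def simulate_multiomic(
    config: SimulationConfig,
    signatures: PathwayCollection | None = None,
) -> tuple[AbundanceMatrix, AbundanceMatrix, SampleAnnotation, GroundTruth]:
    """Paired metabolomics and expression sharing one latent partition.

    The shared partition drives both modalities after independent
    per-modality label corruption at rate ``1 − modality_agreement``; the
    corrupted labels (what each modality's data actually reflect) are
    recorded in ``GroundTruth.modality_clusters``.
    """
    ann, latent = _shared_sample_frame(config)
    samples: list[str] = latent["samples"]
    clusters: np.ndarray = latent["clusters"]
    k = config.n_latent_clusters

    met_labels = _corrupt_labels(
        clusters, config.modality_agreement, k, config.rng(_SUB_CORRUPT_MET)
    )
    expr_labels = _corrupt_labels(
        clusters, config.modality_agreement, k, config.rng(_SUB_CORRUPT_EXPR)
    )

    met_matrix, _, met_truth = simulate_metabolomics(config, cluster_labels=met_labels)
    expr_matrix, _, expr_truth = simulate_expression(
        config, signatures, cluster_labels=expr_labels
    )

    truth = GroundTruth(
        true_effects=met_truth.true_effects,
        true_dilutions=met_truth.true_dilutions,
        true_blocks=met_truth.true_blocks,
        true_clusters={s: int(c) for s, c in zip(samples, clusters) if c >= 0},
        freeze_assoc_features=met_truth.freeze_assoc_features,
        true_infiltration=expr_truth.true_infiltration,
        modality_clusters={
            "metabolomics": {s: int(c) for s, c in zip(samples, met_labels) if c >= 0},
            "rna": {s: int(c) for s, c in zip(samples, expr_labels) if c >= 0},
        },
    )
    return met_matrix, expr_matrix, SampleAnnotation(ann), truth
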