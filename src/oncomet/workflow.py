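"""End-to-end driver chaining the analysis stages.

Stage order: normalize → freeze-time QC → differential abundance →
pathway DA scores (both modalities) → per-modality consensus clustering →
COCA → aggressiveness-ordered labels → microenvironment scoring → report.

Every run writes a manifest (config snapshot, package version, seeds,
SHA-256 checksums of each output, accumulated warnings) so that re-running
with identical inputs is auditable byte for byte.  Stage outputs are
written before the next stage begins; a failure aborts with the stage name
and leaves prior outputs and a partial manifest on disk.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import AbundanceMatrix, ConfigError, DataError, SampleAnnotation
from .clustering import (
    DEFAULT_TOP_GENES,
    DEFAULT_TOP_METABOLITES,
    coca,
    consensus_cluster,
    mad_select,
    order_clusters_by_aggressiveness,
    select_best_k,
)
from .diffabund import ContrastSpec, differential_abundance, moderated_t
from .immune import aggregate_tis_iis, compare_groups, cyt_score, ssgsea
from .io import read_annotation, read_matrix, write_json, write_table
from .pathways import (
    compare_modal_da_scores,
    read_gmt,
    scores_table,
    weighted_da_score,
)
from .preprocess import freeze_time_screen, log2_transform, normalize_chain

logger = logging.getLogger("oncomet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Paths, thresholds and clustering parameters for one pipeline run."""

    metabolite_matrix: str
    expression_matrix: str
    annotations: str
    pathways_gmt: str
    signatures_gmt: str

    alpha: float = 0.05
    freeze_q: float = 0.05
    metab_heatmap: tuple[float, float] = (0.05, 1.0)     # (q cut, |log2fc| cut)
    gene_heatmap: tuple[float, float] = (0.005, 1.5)
    min_measured: int = 3

    mad_genes: int = DEFAULT_TOP_GENES
    mad_metabolites: int = DEFAULT_TOP_METABOLITES
    k_range: Sequence[int] = (2, 3, 4, 5, 6)
    n_iter: int = 50
    subsample_fraction: float = 0.8
    seed: int = 0
    k_override: int | None = None

    tis_sets: Sequence[str] = ()
    iis_sets: Sequence[str] = ()
    cyt_genes: tuple[str, str] = ("GZMA", "PRF1")
    gloh_column: str = "gLOH"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for field in ("metabolite_matrix", "expression_matrix", "annotations",
                      "pathways_gmt", "signatures_gmt"):
            p = getattr(self, field)
            if not Path(p).exists():
                raise ConfigError(f"{field}: path does not exist: {p}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ConfigError("subsample_fraction must be in (0, 1]")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["tis_sets"], d["iis_sets"] = list(self.tis_sets), list(self.iis_sets)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.snapshot(),
        "version": __version__,
        "seed": config.seed,
        "outputs": {},
        "warnings": [],
        "stages_completed": [],
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    def finish_stage(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        write_json(manifest, outdir / "manifest.json")
        logger.info("stage %s complete", stage)

    state: dict = {}
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for stage, fn in _STAGES:
                try:
                    fn(config, state, emit)
                except Exception as exc:  # noqa: BLE001 — abort with stage name
                    manifest["warnings"].extend(str(w.message) for w in caught)
                    manifest["failed_stage"] = stage
                    write_json(manifest, outdir / "manifest.json")
                    raise PipelineError(stage, exc) from exc
                finish_stage(stage)
            manifest["warnings"].extend(str(w.message) for w in caught)
    finally:
        write_json(manifest, outdir / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stages (each: fn(config, state, emit))
# --------------------------------------------------------------------------

def _stage_load(cfg: RunConfig, st: dict, emit) -> None:
    st["metab_raw"] = read_matrix(cfg.metabolite_matrix, scale_tag="raw")
    st["expr_raw"] = read_matrix(cfg.expression_matrix, scale_tag="raw")
    st["ann"] = read_annotation(cfg.annotations)
    st["pathways"] = read_gmt(cfg.pathways_gmt)
    st["signatures"] = read_gmt(cfg.signatures_gmt)


def _stage_normalize(cfg: RunConfig, st: dict, emit) -> None:
    log2m, pqnm, quotients = normalize_chain(st["metab_raw"], st["ann"])
    st["metab_log2"], st["metab_pqn"] = log2m, pqnm
    st["expr_log2"] = log2_transform(st["expr_raw"])
    emit("metabolites.normalized.tsv",
         lambda p: write_table(log2m.data, p, {"scale_tag": "log2"}, "feature_id"))
    emit("pqn_quotients.tsv",
         lambda p: write_table(quotients.to_frame(), p, {}, "sample_id"))


def _stage_qc(cfg: RunConfig, st: dict, emit) -> None:
    screen = freeze_time_screen(st["metab_log2"], st["ann"], q_threshold=cfg.freeze_q)
    st["qc"] = screen
    emit("freeze_time_screen.tsv",
         lambda p: write_table(screen.table, p,
                               {"q_threshold": cfg.freeze_q,
                                "n_flagged": screen.n_flagged}, "feature_id"))


def _contrast(cfg: RunConfig, st: dict) -> ContrastSpec:
    ann: SampleAnnotation = st["ann"]
    return ContrastSpec(
        group_a=ann.samples_in_group("tumor"),
        group_b=ann.samples_in_group("normal"),
        alpha=cfg.alpha,
    )


def _stage_da(cfg: RunConfig, st: dict, emit) -> None:
    contrast = _contrast(cfg, st)
    st["da_metab"] = differential_abundance(st["metab_pqn"], contrast)
    st["de_genes"] = moderated_t(st["expr_log2"], contrast)
    emit("da_metabolites.tsv",
         lambda p: write_table(st["da_metab"].table, p, st["da_metab"].metadata,
                               "feature_id"))
    emit("de_genes.tsv",
         lambda p: write_table(st["de_genes"].table, p, st["de_genes"].metadata,
                               "feature_id"))


def _stage_pathways(cfg: RunConfig, st: dict, emit) -> None:
    metab_scores = weighted_da_score(st["da_metab"], st["pathways"], cfg.min_measured)
    rna_scores = weighted_da_score(st["de_genes"], st["pathways"], cfg.min_measured)
    st["pathway_da"] = {"metabolomics": metab_scores, "rna": rna_scores}
    emit("pathway_da_metabolites.tsv",
         lambda p: write_table(scores_table(metab_scores), p,
                               {"min_measured": cfg.min_measured}, "pathway"))
    emit("pathway_da_rna.tsv",
         lambda p: write_table(scores_table(rna_scores), p,
                               {"min_measured": cfg.min_measured}, "pathway"))
    try:
        rho, p, paired = compare_modal_da_scores(metab_scores, rna_scores)
        st["modal_rho"] = (rho, p)
        emit("pathway_da_comparison.tsv",
             lambda path: write_table(paired, path,
                                      {"spearman_rho": rho, "p": p}, "pathway"))
    except DataError as exc:
        warnings.warn(f"cross-modality DA comparison skipped: {exc}")


def _stage_cluster(cfg: RunConfig, st: dict, emit) -> None:
    ann: SampleAnnotation = st["ann"]
    tumors = ann.samples_in_group("tumor")
    memberships: dict[str, pd.Series] = {}
    for modality, matrix, top_n in (
        ("rna", st["expr_log2"], cfg.mad_genes),
        ("metabolomics", st["metab_log2"], cfg.mad_metabolites),
    ):
        sub = matrix.subset_samples([s for s in tumors if s in matrix.sample_ids])
        selected = mad_select(sub, min(top_n, sub.n_features))
        results = consensus_cluster(
            selected, k_range=cfg.k_range, n_iter=cfg.n_iter,
            subsample_fraction=cfg.subsample_fraction, seed=cfg.seed,
        )
        best = select_best_k(results)
        memberships[modality] = results[best].membership
        st[f"consensus_{modality}"] = results
        emit(f"membership_{modality}.tsv",
             lambda p, r=results, b=best: write_table(
                 r[b].membership.to_frame(), p,
                 {"best_k": b,
                  "concordance": {k: round(v.concordance, 6) for k, v in r.items()}},
                 "sample_id"))
    st["memberships"] = memberships


def _stage_coca(cfg: RunConfig, st: dict, emit) -> None:
    result = coca(
        st["memberships"], k_range=cfg.k_range, n_iter=cfg.n_iter,
        subsample_fraction=cfg.subsample_fraction, seed=cfg.seed,
        k_override=cfg.k_override,
    )
    labels, label_map, proportions = order_clusters_by_aggressiveness(
        result.membership, st["ann"]
    )
    result.labels = labels
    result.label_map = label_map
    result.aggressive_proportion = proportions
    st["coca"] = result
    emit("coca_membership.tsv",
         lambda p: write_table(
             pd.DataFrame({"cluster": result.membership, "label": labels}), p,
             {"k": result.k, "k_override": cfg.k_override,
              "concordance_by_k": {k: round(v, 6)
                                   for k, v in result.concordance_by_k.items()},
              "aggressive_proportion": proportions}, "sample_id"))
    emit("coca_binary.tsv", lambda p: write_table(result.binary, p, {}, "sample_id"))


def _stage_immune(cfg: RunConfig, st: dict, emit) -> None:
    expr_log2: AbundanceMatrix = st["expr_log2"]
    scores = ssgsea(expr_log2, st["signatures"])
    st["ssgsea"] = scores
    frames = [scores.scores]
    tis = [s for s in cfg.tis_sets if s in scores.scores.columns]
    iis = [s for s in cfg.iis_sets if s in scores.scores.columns]
    if tis and iis:
        frames.append(aggregate_tis_iis(scores, tis, iis))
    ga, gb = cfg.cyt_genes
    if ga in st["expr_raw"].data.index and gb in st["expr_raw"].data.index:
        frames.append(cyt_score(st["expr_raw"], ga, gb).to_frame())
    combined = pd.concat(frames, axis=1)
    st["immune_scores"] = combined
    emit("immune_scores.tsv", lambda p: write_table(combined, p, {}, "sample_id"))
    ann: SampleAnnotation = st["ann"]
    if cfg.gloh_column in ann.table.columns:
        tumors = [s for s in ann.samples_in_group("tumor") if s in combined.index]
        if tumors:
            try:
                comp = compare_groups(combined.loc[tumors], ann, cfg.gloh_column,
                                      alpha=cfg.alpha)
                st["immune_gloh"] = comp
                emit("immune_gloh_comparison.tsv",
                     lambda p: write_table(comp, p, dict(comp.attrs), "score"))
            except DataError as exc:
                warnings.warn(f"gLOH comparison skipped: {exc}")


def _stage_report(cfg: RunConfig, st: dict, emit) -> None:
    table = composition_table(st["coca"].labels, st["ann"])
    st["report"] = table
    emit("cluster_composition.tsv", lambda p: write_table(table, p, {}, "cluster"))
    _plot_report(cfg, st, emit)


_STAGES = [
    ("load", _stage_load),
    ("normalize", _stage_normalize),
    ("qc_freeze", _stage_qc),
    ("differential", _stage_da),
    ("pathway_scores", _stage_pathways),
    ("consensus_cluster", _stage_cluster),
    ("coca", _stage_coca),
    ("immune", _stage_immune),
    ("report", _stage_report),
]


def composition_table(labels: pd.Series, annotations: SampleAnnotation) -> pd.DataFrame:
    """Per-cluster counts and proportions of histology and genotype flags."""
    ann = annotations.table.reindex(labels.index)
    rows = []
    for label in sorted(labels.unique()):
        members = labels.index[labels == label]
        sub = ann.loc[members]
        n = len(members)
        if n == 0:
            raise DataError(f"cluster {label} is empty")
        row: dict[str, object] = {"n": n}
        hist = sub["histology"].astype(str).str.upper()
        row["HMIN"] = int((hist == "HMIN").sum())
        row["HWIDE"] = int((hist == "HWIDE").sum())
        for flag in ("recurrence", "gLOH", "mtDNA", "mTOR", "TERT"):
            if flag in sub.columns:
                row[flag] = int(sub[flag].astype(bool).sum())
        for key in list(row):
            if key != "n":
                row[f"prop_{key}"] = row[key] / n
        rows.append((label, row))
    return pd.DataFrame({label: row for label, row in rows}).T.rename_axis("cluster")


def _plot_report(cfg: RunConfig, st: dict, emit) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    scores = st["pathway_da"]["metabolomics"]
    if scores:
        top = sorted(scores, key=lambda s: abs(s.da), reverse=True)[:15]
        axes[0].barh([s.name for s in top], [s.da for s in top],
                     color=["firebrick" if s.da >= 0 else "steelblue" for s in top])
        axes[0].set_xlabel("weighted DA score")
        axes[0].set_xlim(-1, 1)
        axes[0].set_title("Metabolite pathway DA (tumor vs normal)")
    curve = st["coca"].concordance_by_k
    axes[1].plot(list(curve), list(curve.values()), marker="o")
    axes[1].axvline(st["coca"].k, color="gray", linestyle="--")
    axes[1].set_xlabel("k")
    axes[1].set_ylabel("concordance")
    axes[1].set_title("COCA concordance curve")
    fig.tight_layout()

    def save(path):
        fig.savefig(path, dpi=120)
        plt.close(fig)

    emit("report.png", save)
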