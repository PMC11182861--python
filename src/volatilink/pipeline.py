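"""End-to-end orchestration of the paired volatilome-metabolome analysis.

Stage order: internal-standard normalisation -> blank subtraction (volatiles)
-> surface-area / protein scaling -> prevalence and RSD filters -> log10 +
mean-centring -> per-dataset differential t-tests, PCA and PERMANOVA ->
combined Spearman/Holm correlation screen -> significant edges -> k-core
clusters -> co-pathway validation and volatile -> pathway assignment.

Inputs are either file paths (abundance tables, per-dataset metadata,
pathway map) or a synthetic study generated in memory. Every stage logs the
sample and compound counts flowing in and out.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .datatypes import (
    CompoundTable,
    METABOLITE,
    PathwayMap,
    ResultReport,
    SampleMetadata,
    ValidationError,
    VOLATILE,
)
from .diffstats import differential_abundance, pca_summary, permanova_by_treatment
from .network import extract_clusters, significant_correlations
from .pathways import assign_volatile_pathways, co_pathway_fraction
from .preprocess import (
    PreprocessConfig,
    filter_prevalence,
    filter_rsd,
    log_center,
    normalize_internal_standard,
    normalize_scale,
    subtract_blanks,
)
from .simulate import SimConfig, generate_paired_dataset


@dataclass
class PipelineConfig:
    """Inputs, thresholds and rule variants for a full run.

    Defaults are the analysis thresholds of the emulated study: Euclidean
    PERMANOVA with 999 permutations, |rho| > 0.7 and adjusted p < 0.05 for
    correlation edges, PCA driver loadings beyond +/-0.2, and network
    clusters at k = 5.
    """

    volatile_table: str | None = None
    metabolite_table: str | None = None
    volatile_meta: str | None = None
    metabolite_meta: str | None = None
    pathway_map: str | None = None
    synthetic: SimConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    filter_prevalence_volatiles: bool = True
    filter_prevalence_metabolites: bool = False
    filter_rsd_volatiles: bool = False
    filter_rsd_metabolites: bool = True
    r_threshold: float = 0.7
    p_threshold: float = 0.05
    loading_threshold: float = 0.2
    cluster_k: int = 5
    n_perm: int = 999
    adjust_differential: str = "bh"
    alpha: float = 0.05
    welch: bool = True
    seed: int = 20240617

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValidationError("r_threshold must lie in (0, 1)")
        if not 0 < self.p_threshold <= 1:
            raise ValidationError("p_threshold must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must lie in (0, 1]")
        if self.loading_threshold <= 0:
            raise ValidationError("loading_threshold must be positive")
        if self.cluster_k < 1:
            raise ValidationError("cluster_k must be >= 1")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if isinstance(self.preprocess, dict):
            self.preprocess = PreprocessConfig(**self.preprocess)
        if isinstance(self.synthetic, dict):
            self.synthetic = SimConfig(**self.synthetic)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        study = generate_paired_dataset(config.synthetic, seed=config.seed)
        return (
            study.volatiles,
            study.metabolites,
            study.meta_volatile,
            study.meta_metabolite,
            study.pathway_map,
        )
    required = {
        "volatile_table": config.volatile_table,
        "metabolite_table": config.metabolite_table,
        "volatile_meta": config.volatile_meta,
        "metabolite_meta": config.metabolite_meta,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ValidationError(f"missing inputs {missing} (or set synthetic)")
    volatiles = vio.read_compound_table(config.volatile_table, kind=VOLATILE)
    metabolites = vio.read_compound_table(config.metabolite_table, kind=METABOLITE)
    meta_vol = vio.read_sample_metadata(config.volatile_meta)
    meta_met = vio.read_sample_metadata(config.metabolite_meta)
    pmap = (
        vio.read_pathway_map(config.pathway_map)
        if config.pathway_map
        else PathwayMap.from_pairs([])
    )
    return volatiles, metabolites, meta_vol, meta_met, pmap


def preprocess_dataset(
    table: CompoundTable,
    meta: SampleMetadata,
    config: PreprocessConfig,
    do_prevalence: bool,
    do_rsd: bool,
    stage_log: list[dict] | None = None,
    filter_logs: list[pd.DataFrame] | None = None,
) -> tuple[CompoundTable, CompoundTable]:
    """Run the normalisation/filter chain; returns (pre-log, log-centred) tables."""

    def log(stage: str, t: CompoundTable) -> None:
        if stage_log is not None:
            stage_log.append(
                {"dataset": table.kind, "stage": stage, "n_samples": t.n_samples, "n_compounds": t.n_compounds}
            )

    log("raw", table)
    t = normalize_internal_standard(table, meta)
    log("is_normalised", t)
    has_blanks = bool(set(t.sample_ids) & set(meta.blanks()))
    if has_blanks:
        t = subtract_blanks(t, meta, pooled=config.pooled_blanks)
        log("blank_subtracted", t)
    t = normalize_scale(t, meta)
    log("scaled", t)
    if do_prevalence:
        t, flog = filter_prevalence(t, meta, config)
        if filter_logs is not None and len(flog):
            filter_logs.append(flog.assign(dataset=table.kind))
        log("filtered_prevalence", t)
    if do_rsd:
        t, flog = filter_rsd(t, meta, config)
        if filter_logs is not None and len(flog):
            filter_logs.append(flog.assign(dataset=table.kind))
        log("filtered_rsd", t)
    lc = log_center(t, config)
    log("log_centred", lc)
    return t, lc


def run_pipeline(config: PipelineConfig) -> ResultReport:
    """Execute the full analysis and return a populated :class:`ResultReport`."""
    volatiles, metabolites, meta_vol, meta_met, pmap = _load_inputs(config)
    stage_log: list[dict] = []
    filter_logs: list[pd.DataFrame] = []
    warnings: list[str] = []

    vol_pre, vol_lc = preprocess_dataset(
        volatiles, meta_vol, config.preprocess,
        do_prevalence=config.filter_prevalence_volatiles,
        do_rsd=config.filter_rsd_volatiles,
        stage_log=stage_log, filter_logs=filter_logs,
    )
    met_pre, met_lc = preprocess_dataset(
        metabolites, meta_met, config.preprocess,
        do_prevalence=config.filter_prevalence_metabolites,
        do_rsd=config.filter_rsd_metabolites,
        stage_log=stage_log, filter_logs=filter_logs,
    )

    differential = pd.concat(
        [
            differential_abundance(
                vol_lc, vol_pre, meta_vol,
                adjust=config.adjust_differential, alpha=config.alpha, welch=config.welch,
            ),
            differential_abundance(
                met_lc, met_pre, meta_met,
                adjust=config.adjust_differential, alpha=config.alpha, welch=config.welch,
            ),
        ],
        ignore_index=True,
    )

    permanova_results = {
        VOLATILE: permanova_by_treatment(vol_lc, meta_vol, n_perm=config.n_perm, seed=config.seed),
        METABOLITE: permanova_by_treatment(met_lc, meta_met, n_perm=config.n_perm, seed=config.seed),
    }
    pca_results = {
        VOLATILE: pca_summary(vol_lc, loading_threshold=config.loading_threshold),
        METABOLITE: pca_summary(met_lc, loading_threshold=config.loading_threshold),
    }

    edges, rho, _, _ = significant_correlations(
        vol_lc, met_lc, r_threshold=config.r_threshold, p_threshold=config.p_threshold
    )
    constant = [c for c in rho.columns if rho.loc[c].isna().all()]
    if constant:
        warnings.append(f"rho undefined for constant compounds: {constant}")

    clusters = extract_clusters(edges, k=config.cluster_k)
    co_pathway = co_pathway_fraction(edges, pmap)
    assignments = assign_volatile_pathways(edges, pmap)

    stage_frame = pd.DataFrame(stage_log, columns=["dataset", "stage", "n_samples", "n_compounds"])
    filter_frame = (
        pd.concat(filter_logs, ignore_index=True)
        if filter_logs
        else pd.DataFrame(columns=["compound_id", "reason", "statistic", "threshold", "dataset"])
    )

    return ResultReport(
        differential=differential,
        permanova=permanova_results,
        pca=pca_results,
        edges=edges,
        clusters=clusters,
        co_pathway=co_pathway,
        assignments=assignments,
        stage_log=stage_frame,
        filter_log=filter_frame,
        config=config.to_dict(),
        warnings=warnings,
    )
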