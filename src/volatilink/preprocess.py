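"""Normalisation and filtering chain from raw peak areas to log-centred matrices.

The chain mirrors standard untargeted GC-MS practice for this study design:

1. divide each sample by its internal-standard signal,
2. subtract the per-treatment seawater-blank mean per compound, flooring
   negatives to zero (a sample detecting less than the blank background is
   treated as not detected),
3. divide by the per-sample scale factor (coral surface area for volatiles,
   tissue protein content for metabolites),
4. drop unreliable compounds — a prevalence filter (detected in too few
   replicates in every treatment group) and a reproducibility filter
   (within-group relative standard deviation above a ceiling),
5. log10-transform and mean-centre per compound.

Filters never alter retained values; they only drop columns, and each removal
is recorded in a filter log (compound_id, reason, statistic, threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import CompoundTable, SampleMetadata, TREATMENTS, ValidationError

FILTER_LOG_COLUMNS = ("compound_id", "reason", "statistic", "threshold")


@dataclass
class PreprocessConfig:
    """Thresholds and rule variants for the preprocessing chain.

    min_detected_replicates
        A compound is kept only if detected (value > 0) in at least this many
        replicates of some treatment group (default 4 out of n=6, i.e. drop
        when detected in three or fewer).
    max_rsd
        Within-group relative standard deviation ceiling (sd/mean; default
        0.5, i.e. 50%).
    prevalence_mode
        ``"any_group"`` (default): retain when the detection count reaches the
        minimum in at least one group — a compound robustly present under only
        one condition is informative. ``"all_groups"``: require it in every
        group.
    rsd_mode
        ``"either_group"`` (default): exclude when the RSD exceeds the ceiling
        in either group, since noise in one group can mask broader trends.
        ``"both_groups"``: exclude only when both groups exceed it.
    zero_replacement
        Rule for zeros ahead of the log transform; ``"half_min"`` replaces
        zeros with half the smallest positive value of that compound.
    pooled_blanks
        Subtract the mean over all blanks instead of per-treatment blanks.
    """

    min_detected_replicates: int = 4
    max_rsd: float = 0.5
    prevalence_mode: str = "any_group"
    rsd_mode: str = "either_group"
    zero_replacement: str = "half_min"
    log_base: int = 10
    pooled_blanks: bool = False

    def __post_init__(self) -> None:
        if self.min_detected_replicates < 1:
            raise ValidationError("min_detected_replicates must be >= 1")
        if not self.max_rsd > 0:
            raise ValidationError("max_rsd must be positive")
        if self.prevalence_mode not in ("any_group", "all_groups"):
            raise ValidationError(f"unknown prevalence_mode {self.prevalence_mode!r}")
        if self.rsd_mode not in ("either_group", "both_groups"):
            raise ValidationError(f"unknown rsd_mode {self.rsd_mode!r}")
        if self.zero_replacement != "half_min":
            raise ValidationError(f"unknown zero_replacement rule {self.zero_replacement!r}")
        if self.log_base != 10:
            raise ValidationError("log_base is fixed at 10")


def _empty_filter_log() -> pd.DataFrame:
    return pd.DataFrame(columns=list(FILTER_LOG_COLUMNS))


def normalize_by_reference(
    table: CompoundTable,
    reference: Mapping[str, float] | pd.Series,
    stage: str,
) -> CompoundTable:
    """Divide each sample row by its per-sample positive reference scalar."""
    reference = pd.Series(reference, dtype=float)
    missing = [s for s in table.sample_ids if s not in reference.index]
    if missing:
        raise ValidationError(f"reference value missing for samples: {missing}")
    ref = reference.loc[table.sample_ids]
    bad = [s for s, v in ref.items() if not v > 0]
    if bad:
        raise ValidationError(f"reference must be positive; offending samples: {bad}")
    data = table.data.div(ref, axis=0)
    return table.replace_data(data, stage=stage)


def normalize_internal_standard(table: CompoundTable, meta: SampleMetadata) -> CompoundTable:
    """Internal-standard normalisation (first reference division)."""
    ref = meta.require(table.sample_ids, "internal_standard_area")
    return normalize_by_reference(table, ref, stage="is_normalised")


def normalize_scale(table: CompoundTable, meta: SampleMetadata) -> CompoundTable:
    """Surface-area (volatiles) or protein-content (metabolites) normalisation."""
    ref = meta.require(table.sample_ids, "scale_factor")
    return normalize_by_reference(table, ref, stage="scaled")


def subtract_blanks(
    table: CompoundTable,
    meta: SampleMetadata,
    pooled: bool = False,
) -> CompoundTable:
    """Subtract per-compound seawater-blank means; floor negatives to 0.

    Blank means are computed per treatment group by default (each treatment's
    blanks were run under that treatment's light), or pooled over all blanks
    with ``pooled=True``. Blank samples are removed from the output.
    """
    blanks = [s for s in table.sample_ids if s in set(meta.blanks())]
    corals = [s for s in table.sample_ids if s not in set(meta.blanks())]
    if not blanks:
        raise ValidationError("no blank samples present in table; cannot blank-subtract")
    data = table.data.loc[corals].copy()
    if pooled:
        blank_mean = table.data.loc[blanks].mean(axis=0)
        data = data.sub(blank_mean, axis=1)
    else:
        for treatment in TREATMENTS:
            group = [s for s in corals if meta.treatment_of(s) == treatment]
            if not group:
                continue
            group_blanks = [s for s in blanks if meta.treatment_of(s) == treatment]
            if not group_blanks:
                raise ValidationError(
                    f"no blanks for treatment {treatment!r}; use pooled=True to share blanks"
                )
            blank_mean = table.data.loc[group_blanks].mean(axis=0)
            data.loc[group] = data.loc[group].sub(blank_mean, axis=1)
    data = data.clip(lower=0.0)
    return table.replace_data(data, stage="blank_subtracted")


def _group_rows(table: CompoundTable, meta: SampleMetadata) -> dict[str, list[str]]:
    groups = {}
    for treatment in TREATMENTS:
        members = [s for s in table.sample_ids if s in set(meta.group_members(treatment))]
        if members:
            groups[treatment] = members
    if not groups:
        raise ValidationError("no non-blank samples with known treatment in table")
    return groups


def filter_prevalence(
    table: CompoundTable,
    meta: SampleMetadata,
    config: PreprocessConfig | None = None,
) -> tuple[CompoundTable, pd.DataFrame]:
    """Drop compounds detected in too few replicates.

    Detection means value > 0. Under the default ``any_group`` mode a compound
    is retained iff its detection count reaches ``min_detected_replicates`` in
    at least one treatment group.
    """
    config = config or PreprocessConfig()
    groups = _group_rows(table, meta)
    counts = pd.DataFrame(
        {t: (table.data.loc[members] > 0).sum(axis=0) for t, members in groups.items()}
    )
    if config.prevalence_mode == "any_group":
        keep = (counts >= config.min_detected_replicates).any(axis=1)
    else:
        keep = (counts >= config.min_detected_replicates).all(axis=1)
    removed = counts.index[~keep]
    log = pd.DataFrame(
        {
            "compound_id": removed,
            "reason": "prevalence",
            "statistic": counts.loc[removed].max(axis=1).to_numpy(dtype=float),
            "threshold": float(config.min_detected_replicates),
        },
        columns=list(FILTER_LOG_COLUMNS),
    )
    kept_table = table.replace_data(table.data.loc[:, keep[keep].index], stage="filtered")
    return kept_table, log


def filter_rsd(
    table: CompoundTable,
    meta: SampleMetadata,
    config: PreprocessConfig | None = None,
) -> tuple[CompoundTable, pd.DataFrame]:
    """Drop compounds whose within-group relative standard deviation is too high.

    RSD = sample standard deviation / mean, per treatment group. A group with
    mean 0 is treated as failing (infinite RSD). Groups need >= 2 replicates.
    """
    config = config or PreprocessConfig()
    groups = _group_rows(table, meta)
    rsd = {}
    for treatment, members in groups.items():
        if len(members) < 2:
            raise ValidationError(f"group {treatment!r} has {len(members)} replicate(s); RSD undefined")
        sub = table.data.loc[members]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = sd / mean
        ratio = ratio.where(mean > 0, np.inf)  # mean 0 -> failing
        rsd[treatment] = ratio
    rsd = pd.DataFrame(rsd)
    if config.rsd_mode == "either_group":
        drop = (rsd > config.max_rsd).any(axis=1)
    else:
        drop = (rsd > config.max_rsd).all(axis=1)
    removed = rsd.index[drop]
    log = pd.DataFrame(
        {
            "compound_id": removed,
            "reason": "rsd",
            "statistic": rsd.loc[removed].max(axis=1).to_numpy(dtype=float),
            "threshold": float(config.max_rsd),
        },
        columns=list(FILTER_LOG_COLUMNS),
    )
    kept = table.replace_data(table.data.loc[:, rsd.index[~drop]], stage="filtered")
    return kept, log


def log_center(table: CompoundTable, config: PreprocessConfig | None = None) -> CompoundTable:
    """log10-transform and mean-centre each compound.

    Zeros are first replaced per the configured rule (default: half the
    smallest positive value of that compound across samples). A compound that
    is zero in every sample at this stage is an error — it should have been
    removed by the prevalence filter.
    """
    config = config or PreprocessConfig()
    data = table.data.copy()
    all_zero = (data <= 0).all(axis=0)
    if all_zero.any():
        raise ValidationError(
            f"compounds with no positive values reached log_center: {list(all_zero[all_zero].index)}"
        )
    if (data.to_numpy() <= 0).any():
        min_pos = data.where(data > 0).min(axis=0)
        fill = min_pos / 2.0
        data = data.mask(data <= 0, other=fill, axis=1)
    logged = np.log10(data)
    centred = logged - logged.mean(axis=0)
    return table.replace_data(centred, stage="log_centred")
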