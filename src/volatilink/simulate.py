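"""Synthetic paired volatilome-metabolome studies with known ground truth.

The generator emulates a two-treatment chamber experiment: two groups of
coral fragments (control and transient high light, n = 6 each), seawater
blanks run per treatment (n = 3 each), ~113 headspace volatiles and ~121
tissue metabolites.

Abundances are zero-inflated log-normal. On the log10 scale each compound is

    s_ij = baseline_j + effect_j * [high light] + sigma_f * f_{block(j), i}
           + noise_sd * eps_ij

where f is a per-pathway-block latent factor shared by every compound of the
block across both datasets (creating pathway-linked correlation structure;
``block_loading`` is the induced log-scale correlation between two compounds
of the same block), effect_j is the planted treatment effect (log2 fold
change, converted to log10), and eps is standard Gaussian noise. Signals
below the detection limit record as 0 — zero inflation as instrument
limit-of-detection left-truncation, which keeps truth recoverable. Raw peak
areas then fold in the per-sample surface area (volatiles) or protein content
(metabolites), an additive seawater background for a subset of
blank-contaminated volatiles, and the per-sample internal-standard signal, so
the preprocessing chain has real work to undo.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CompoundTable,
    CONTROL,
    HIGH_LIGHT,
    METABOLITE,
    PathwayMap,
    SampleMetadata,
    TIMEPOINTS,
    TREATMENTS,
    ValidationError,
    VOLATILE,
)

LOG10_2 = float(np.log10(2.0))

#: Group-mean PSII efficiencies printed for the study design this generator
#: emulates: (treatment, timepoint) -> mean of n = 3 replicates.
PSII_STUDY_MEANS: dict[tuple[str, str], float] = {
    (CONTROL, "before"): 0.340,
    (HIGH_LIGHT, "before"): 0.381,
    (CONTROL, "end_of_light"): 0.222,
    (HIGH_LIGHT, "end_of_light"): 0.031,
    (CONTROL, "recovery"): 0.247,
    (HIGH_LIGHT, "recovery"): 0.173,
}


@dataclass
class SimConfig:
    """Study-design and noise parameters for the paired generator.

    Defaults mirror the emulated design: 6 replicates and 3 blanks per
    treatment, 113 volatiles / 121 metabolites (keeping the multiple-testing
    burden realistic), 8 pathway blocks, planted effects on ~16 volatiles and
    ~31 metabolites at several-fold magnitudes. Replicate variation is split
    between shared pathway-block co-variation (block_loading 0.97, matching
    the near-perfect correlations such screens report) and independent
    log-scale noise of 0.025, keeping within-group relative standard
    deviations around 30-40% so the reproducibility filter passes most
    compounds, as in the emulated study.
    """

    n_reps_per_group: int = 6
    n_blanks_per_group: int = 3
    n_volatiles: int = 113
    n_metabolites: int = 121
    n_pathways: int = 8
    #: induced log-scale correlation between same-block compounds, in [0, 1)
    block_loading: float = 0.97
    frac_volatiles_in_blocks: float = 0.4
    frac_metabolites_in_blocks: float = 0.6
    #: compound index -> planted log2 fold change; None selects the default
    #: scheme (volatiles: ~10 decreases at -3, ~6 increases at +3.5;
    #: metabolites: ~17 increases at +2.5, ~14 decreases at -2.5, scaled to
    #: the table size)
    planted_effects_volatile: dict[int, float] | None = None
    planted_effects_metabolite: dict[int, float] | None = None
    #: log10-abundance detection limits (left-truncation to 0)
    detection_limit_volatile: float = 4.6
    detection_limit_metabolite: float = -np.inf
    #: log10 background level of blank-contaminated volatiles
    blank_level: float = 4.8
    frac_blank_contaminated: float = 0.15
    noise_sd: float = 0.025
    baseline_mean_volatile: float = 5.0
    baseline_mean_metabolite: float = 6.0
    baseline_sd: float = 0.7
    internal_standard_volatile: float = 1.0e6
    internal_standard_metabolite: float = 1.0
    internal_standard_cv: float = 0.03
    surface_area_mean: float = 25.0
    surface_area_sd: float = 2.0
    protein_mean: float = 2.0
    protein_sd: float = 0.2
    #: chance a block metabolite carries a second, unrelated pathway
    extra_annotation_rate: float = 0.05
    #: chance an off-block metabolite carries some random pathway
    background_annotation_rate: float = 0.3
    seed: int = 20240617

    def __post_init__(self) -> None:
        for name in ("n_reps_per_group", "n_blanks_per_group", "n_volatiles", "n_metabolites", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.block_loading < 1.0:
            raise ValidationError("block_loading must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for name, n in (
            ("planted_effects_volatile", self.n_volatiles),
            ("planted_effects_metabolite", self.n_metabolites),
        ):
            planted = getattr(self, name)
            if planted is not None:
                if len(planted) > n:
                    raise ValidationError(f"{name}: more planted effects than compounds")
                bad = [i for i in planted if not 0 <= int(i) < n]
                if bad:
                    raise ValidationError(f"{name}: indices out of range: {bad}")


@dataclass
class StudyTruth:
    """Ground truth of one generated study."""

    differential_volatiles: dict[str, float]
    differential_metabolites: dict[str, float]
    block_membership: dict[str, int | None]
    pathway_links: dict[int, str]
    volatile_origin: dict[str, int]

    @property
    def differential_set(self) -> frozenset[str]:
        return frozenset(self.differential_volatiles) | frozenset(self.differential_metabolites)


@dataclass
class SimStudy:
    """One generated paired study: tables, metadata, pathway map and truth."""

    volatiles: CompoundTable
    metabolites: CompoundTable
    meta_volatile: SampleMetadata
    meta_metabolite: SampleMetadata
    pathway_map: PathwayMap
    truth: StudyTruth
    config: SimConfig


def _default_planted(n: int, scheme: tuple[tuple[int, float], ...], n_reference: int) -> list[float]:
    """Scale the (count at reference size, effect) scheme to a table of n compounds."""
    effects = []
    for count, effect in scheme:
        scaled = int(round(count * n / n_reference))
        effects.extend([effect] * scaled)
    return effects[:n]


def _planted_vector(
    explicit: dict[int, float] | None,
    n: int,
    scheme: tuple[tuple[int, float], ...],
    n_reference: int,
    rng: np.random.Generator,
) -> np.ndarray:
    delta = np.zeros(n)
    if explicit is not None:
        for idx, effect in explicit.items():
            delta[int(idx)] = float(effect)
        return delta
    effects = _default_planted(n, scheme, n_reference)
    if effects:
        positions = rng.choice(n, size=len(effects), replace=False)
        delta[positions] = effects
    return delta


_VOLATILE_SCHEME = ((10, -3.0), (6, 3.5))
_METABOLITE_SCHEME = ((17, 2.5), (14, -2.5))


def generate_paired_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimStudy:
    """Generate one paired study (raw tables, metadata, pathway map, truth)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_rep, n_blank = config.n_reps_per_group, config.n_blanks_per_group
    corals = [f"C{i + 1}" for i in range(n_rep)] + [f"H{i + 1}" for i in range(n_rep)]
    blanks = [f"BC{i + 1}" for i in range(n_blank)] + [f"BH{i + 1}" for i in range(n_blank)]
    coral_treatment = np.array([CONTROL] * n_rep + [HIGH_LIGHT] * n_rep)
    blank_treatment = np.array([CONTROL] * n_blank + [HIGH_LIGHT] * n_blank)
    is_high = (coral_treatment == HIGH_LIGHT).astype(float)
    n_coral = len(corals)

    vol_ids = [f"vol_{i + 1:03d}" for i in range(config.n_volatiles)]
    met_ids = [f"met_{i + 1:03d}" for i in range(config.n_metabolites)]

    # pathway blocks, round-robin over the first frac * n compounds
    n_vol_block = int(round(config.frac_volatiles_in_blocks * config.n_volatiles))
    n_met_block = int(round(config.frac_metabolites_in_blocks * config.n_metabolites))
    vol_block = np.full(config.n_volatiles, -1)
    vol_block[:n_vol_block] = np.arange(n_vol_block) % config.n_pathways
    met_block = np.full(config.n_metabolites, -1)
    met_block[:n_met_block] = np.arange(n_met_block) % config.n_pathways

    factors = rng.standard_normal((config.n_pathways, n_coral))
    r = config.block_loading
    sigma_f = config.noise_sd * np.sqrt(r / (1.0 - r)) if r > 0 else 0.0

    delta_vol = _planted_vector(
        config.planted_effects_volatile, config.n_volatiles, _VOLATILE_SCHEME, 113, rng
    )
    delta_met = _planted_vector(
        config.planted_effects_metabolite, config.n_metabolites, _METABOLITE_SCHEME, 121, rng
    )

    def signals(n_compounds, baseline_mean, block, delta, detection_limit):
        baseline = rng.normal(baseline_mean, config.baseline_sd, size=n_compounds)
        s = (
            baseline[None, :]
            + LOG10_2 * delta[None, :] * is_high[:, None]
            + config.noise_sd * rng.standard_normal((n_coral, n_compounds))
        )
        in_block = block >= 0
        if sigma_f > 0 and in_block.any():
            s[:, in_block] += sigma_f * factors[block[in_block]].T
        amount = np.power(10.0, s)
        amount[s < detection_limit] = 0.0
        return amount

    vol_amount = signals(
        config.n_volatiles, config.baseline_mean_volatile, vol_block, delta_vol,
        config.detection_limit_volatile,
    )
    met_amount = signals(
        config.n_metabolites, config.baseline_mean_metabolite, met_block, delta_met,
        config.detection_limit_metabolite,
    )

    # seawater background in a subset of volatiles, shared by corals and blanks
    n_contam = int(round(config.frac_blank_contaminated * config.n_volatiles))
    contaminated = rng.choice(config.n_volatiles, size=n_contam, replace=False) if n_contam else np.array([], dtype=int)
    bg_level = np.zeros(config.n_volatiles)
    bg_level[contaminated] = config.blank_level + rng.normal(0.0, 0.3, size=n_contam)

    def background(n_samples):
        bg = np.zeros((n_samples, config.n_volatiles))
        if n_contam:
            wobble = rng.normal(0.0, 0.15, size=(n_samples, n_contam))
            bg[:, contaminated] = np.power(10.0, bg_level[contaminated][None, :] + wobble)
        return bg

    area = rng.normal(config.surface_area_mean, config.surface_area_sd, size=n_coral).clip(min=1.0)
    protein = rng.normal(config.protein_mean, config.protein_sd, size=n_coral).clip(min=0.1)
    is_vol = rng.normal(
        config.internal_standard_volatile,
        config.internal_standard_cv * config.internal_standard_volatile,
        size=n_coral + len(blanks),
    ).clip(min=1e-6)
    is_met = rng.normal(
        config.internal_standard_metabolite,
        config.internal_standard_cv * config.internal_standard_metabolite,
        size=n_coral,
    ).clip(min=1e-6)

    vol_raw_corals = (area[:, None] * vol_amount + background(n_coral)) * is_vol[:n_coral, None]
    vol_raw_blanks = background(len(blanks)) * is_vol[n_coral:, None]
    vol_data = pd.DataFrame(
        np.vstack([vol_raw_corals, vol_raw_blanks]), index=corals + blanks, columns=vol_ids
    )
    met_data = pd.DataFrame(
        met_amount * protein[:, None] * is_met[:, None], index=corals, columns=met_ids
    )

    meta_vol = SampleMetadata(
        frame=pd.DataFrame(
            {
                "treatment": np.concatenate([coral_treatment, blank_treatment]),
                "is_blank": [False] * n_coral + [True] * len(blanks),
                "internal_standard_area": is_vol,
                "scale_factor": np.concatenate([area, np.full(len(blanks), np.nan)]),
            },
            index=corals + blanks,
        )
    )
    meta_met = SampleMetadata(
        frame=pd.DataFrame(
            {
                "treatment": coral_treatment,
                "is_blank": [False] * n_coral,
                "internal_standard_area": is_met,
                "scale_factor": protein,
            },
            index=corals,
        )
    )

    pathway_links = {k: f"map{11 + k:05d}" for k in range(config.n_pathways)}
    pairs: list[tuple[str, str]] = []
    for i, met in enumerate(met_ids):
        if met_block[i] >= 0:
            pairs.append((met, pathway_links[int(met_block[i])]))
            if rng.random() < config.extra_annotation_rate and config.n_pathways > 1:
                other = int(rng.integers(config.n_pathways))
                if other != met_block[i]:
                    pairs.append((met, pathway_links[other]))
        elif rng.random() < config.background_annotation_rate:
            pairs.append((met, pathway_links[int(rng.integers(config.n_pathways))]))
    pmap = PathwayMap.from_pairs(pairs)

    truth = StudyTruth(
        differential_volatiles={vol_ids[i]: float(delta_vol[i]) for i in np.flatnonzero(delta_vol)},
        differential_metabolites={met_ids[i]: float(delta_met[i]) for i in np.flatnonzero(delta_met)},
        block_membership={
            **{vol_ids[i]: (int(vol_block[i]) if vol_block[i] >= 0 else None) for i in range(config.n_volatiles)},
            **{met_ids[i]: (int(met_block[i]) if met_block[i] >= 0 else None) for i in range(config.n_metabolites)},
        },
        pathway_links=pathway_links,
        volatile_origin={vol_ids[i]: int(vol_block[i]) for i in range(config.n_volatiles) if vol_block[i] >= 0},
    )

    return SimStudy(
        volatiles=CompoundTable(data=vol_data, kind=VOLATILE, stage="raw"),
        metabolites=CompoundTable(data=met_data, kind=METABOLITE, stage="raw"),
        meta_volatile=meta_vol,
        meta_metabolite=meta_met,
        pathway_map=pmap,
        truth=truth,
        config=config,
    )


def clean_config(**overrides) -> SimConfig:
    """A low-noise, fully detected, uncontaminated configuration.

    No planted effects, no zeros, no blank background and weak block
    structure: the preprocessing chain applied to such a study should retain
    every compound.
    """
    defaults = dict(
        planted_effects_volatile={},
        planted_effects_metabolite={},
        detection_limit_volatile=-np.inf,
        detection_limit_metabolite=-np.inf,
        frac_blank_contaminated=0.0,
        noise_sd=0.05,
        block_loading=0.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def generate_fluorometry(
    cell_means: Mapping[tuple[str, str], float] | None = None,
    sd: float = 0.02,
    n: int = 3,
    seed: int = 20240617,
) -> pd.DataFrame:
    """Gaussian replicate PSII efficiencies around per-cell means, clipped to [0, 1].

    ``cell_means`` maps (treatment, timepoint) to the cell mean and defaults
    to :data:`PSII_STUDY_MEANS`. Deterministic given ``seed``.
    """
    cell_means = dict(cell_means) if cell_means is not None else dict(PSII_STUDY_MEANS)
    if sd <= 0:
        raise ValidationError("sd must be positive")
    if n < 2:
        raise ValidationError("need n >= 2 replicates per cell")
    for (treatment, timepoint), mean in cell_means.items():
        if treatment not in TREATMENTS or timepoint not in TIMEPOINTS:
            raise ValidationError(f"invalid cell ({treatment!r}, {timepoint!r})")
        if not 0.0 <= float(mean) <= 1.0:
            raise ValidationError(f"cell mean out of [0, 1]: {mean}")
    rng = np.random.default_rng(seed)
    rows = []
    for (treatment, timepoint), mean in sorted(cell_means.items()):
        values = np.clip(rng.normal(float(mean), sd, size=n), 0.0, 1.0)
        for i, value in enumerate(values):
            rows.append(
                {
                    "sample_id": f"{treatment[:1].upper()}{i + 1}",
                    "treatment": treatment,
                    "timepoint": timepoint,
                    "efficiency": float(value),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "treatment", "timepoint", "efficiency"])
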