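"""Core data containers for paired volatilome-metabolome studies.

The analysis operates on two wide abundance tables (samples x compounds; GC-MS
peak areas), one for headspace volatiles and one for tissue metabolites, plus
per-sample metadata carrying the treatment label, a blank flag and the two
normalisation scalars (internal-standard peak area and surface area or protein
content), and a compound -> pathway membership map with KEGG-style identifiers.

Every container validates its structural invariants at construction so that
violations surface at the boundary rather than deep inside a pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VOLATILE = "volatile"
METABOLITE = "metabolite"
KINDS = (VOLATILE, METABOLITE)

CONTROL = "control"
HIGH_LIGHT = "high_light"
TREATMENTS = (CONTROL, HIGH_LIGHT)

#: Provenance stages a table moves through, in pipeline order.
STAGES = (
    "raw",
    "is_normalised",
    "blank_subtracted",
    "scaled",
    "filtered",
    "log_centred",
)

TIMEPOINTS = ("before", "end_of_light", "recovery")


class ValidationError(ValueError):
    """A container or operation input violates a stated invariant."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dupes = sorted(set(index[index.duplicated()].astype(str)))
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class CompoundTable:
    """Samples x compounds abundance matrix with provenance.

    Values are peak areas or normalised abundances; 0 means "not detected".
    All values must be finite and, until the ``log_centred`` stage,
    non-negative.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and compound
        identifiers as columns.
    kind
        ``"volatile"`` or ``"metabolite"``.
    stage
        One of :data:`STAGES`; tracks where in the pipeline the table sits.
    """

    data: pd.DataFrame
    kind: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown compound kind {self.kind!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        _check_unique(self.data.index, "sample identifiers")
        _check_unique(self.data.columns, "compound identifiers")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric abundance values: {exc}") from exc
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("abundance values must be finite (use 0 for not detected)")
        if self.stage != "log_centred" and values.size and (values < 0).any():
            raise ValidationError(f"negative abundances are not allowed at stage {self.stage!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def replace_data(self, data: pd.DataFrame, stage: str | None = None) -> "CompoundTable":
        """Return a new table with the same kind and an updated matrix/stage."""
        return CompoundTable(data=data, kind=self.kind, stage=stage or self.stage)

    def subset_samples(self, sample_ids: Sequence[str], stage: str | None = None) -> "CompoundTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return self.replace_data(self.data.loc[list(sample_ids)], stage=stage)

    def subset_compounds(self, compound_ids: Sequence[str], stage: str | None = None) -> "CompoundTable":
        missing = [c for c in compound_ids if c not in self.data.columns]
        if missing:
            raise ValidationError(f"compounds not in table: {missing}")
        return self.replace_data(self.data.loc[:, list(compound_ids)], stage=stage)


META_COLUMNS = ("treatment", "is_blank", "internal_standard_area", "scale_factor")


@dataclass
class SampleMetadata:
    """Per-sample treatment labels, blank flags and normalisation scalars.

    ``internal_standard_area`` is the spiked reference signal (peak area of
    chlorobenzene-D5 for volatile runs, relative abundance of 13C6-sorbitol
    for metabolite runs) and must be positive for every sample.
    ``scale_factor`` is the coral surface area in cm^2 (volatiles) or the
    protein content of the extracted tissue (metabolites); it must be positive
    for every non-blank sample, while seawater blanks may leave it missing.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.frame, pd.DataFrame):
            raise ValidationError("metadata must be a pandas DataFrame")
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        _check_unique(self.frame.index, "sample identifiers")
        frame = self.frame.copy()
        frame["is_blank"] = frame["is_blank"].astype(bool)
        frame["treatment"] = frame["treatment"].astype(str)
        bad = sorted(set(frame["treatment"]) - set(TREATMENTS))
        if bad:
            raise ValidationError(f"unknown treatments {bad}; expected {TREATMENTS}")
        is_area = pd.to_numeric(frame["internal_standard_area"], errors="coerce")
        if not (is_area > 0).all():
            offenders = list(frame.index[~(is_area > 0)])
            raise ValidationError(f"internal_standard_area must be positive for all samples: {offenders}")
        frame["internal_standard_area"] = is_area
        scale = pd.to_numeric(frame["scale_factor"], errors="coerce")
        nonblank = ~frame["is_blank"]
        if not (scale[nonblank] > 0).all():
            offenders = list(frame.index[nonblank & ~(scale > 0)])
            raise ValidationError(f"scale_factor must be positive for non-blank samples: {offenders}")
        frame["scale_factor"] = scale
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def blanks(self) -> list[str]:
        return list(self.frame.index[self.frame["is_blank"]])

    def corals(self) -> list[str]:
        """Non-blank (coral fragment) sample identifiers."""
        return list(self.frame.index[~self.frame["is_blank"]])

    def treatment_of(self, sample_id: str) -> str:
        if sample_id not in self.frame.index:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return str(self.frame.loc[sample_id, "treatment"])

    def group_members(self, treatment: str, include_blanks: bool = False) -> list[str]:
        mask = self.frame["treatment"] == treatment
        if not include_blanks:
            mask &= ~self.frame["is_blank"]
        return list(self.frame.index[mask])

    def treatment_labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        return self.frame.loc[list(sample_ids), "treatment"].to_numpy()

    def require(self, sample_ids: Sequence[str], column: str) -> pd.Series:
        """Positive per-sample scalars for ``column``, erroring on offenders."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        series = self.frame.loc[list(sample_ids), column]
        bad = [s for s, v in series.items() if not (pd.notna(v) and v > 0)]
        if bad:
            raise ValidationError(f"{column} must be positive; offending samples: {bad}")
        return series.astype(float)


@dataclass(frozen=True)
class PathwayMap:
    """Compound -> pathway membership as a set of (compound, pathway) pairs."""

    entries: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PathwayMap":
        entries = frozenset((str(c), str(p)) for c, p in pairs)
        return cls(entries=entries)

    def __len__(self) -> int:
        return len(self.entries)

    def pathways_of(self, compound_id: str) -> frozenset[str]:
        return frozenset(p for c, p in self.entries if c == compound_id)

    def as_dict(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for c, p in self.entries:
            out.setdefault(c, set()).add(p)
        return {c: frozenset(ps) for c, ps in out.items()}

    @property
    def annotated_compounds(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.entries)

    @property
    def pathway_ids(self) -> frozenset[str]:
        return frozenset(p for _, p in self.entries)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA on Euclidean distances.

    ``pseudo_f`` is NaN when all samples are identical (zero total sum of
    squares) and +inf when groups are internally identical but distinct.
    """

    pseudo_f: float
    r_squared: float
    p_value: float
    n_perm: int
    seed: int | None
    method: str
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float


@dataclass
class PcaSummary:
    """PCA of a mean-centred matrix via singular value decomposition.

    ``loadings`` holds unit-norm eigenvector coefficients (compounds x
    components); ``drivers`` are compounds whose absolute loading on PC1 or
    PC2 exceeds ``threshold`` (0.2 by default, the dimensionless convention
    under which such driver thresholds are comparable).
    """

    variance_explained: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    drivers: list[str]
    threshold: float


EDGE_COLUMNS = ("compound_a", "compound_b", "rho", "p_raw", "p_adj", "sign")


@dataclass
class EdgeSet:
    """Significant correlation pairs over a compound universe.

    ``edges`` has one row per unordered pair (compound_a < compound_b
    lexicographically) with Spearman rho, raw and adjusted p, and sign
    (positive iff rho > 0). ``kinds`` maps every universe compound to
    volatile/metabolite.
    """

    edges: pd.DataFrame
    universe: list[str]
    kinds: pd.Series

    def __post_init__(self) -> None:
        for col in EDGE_COLUMNS:
            if col not in self.edges.columns:
                raise ValidationError(f"edge table missing column {col!r}")
        if len(self.edges):
            if (self.edges["compound_a"] == self.edges["compound_b"]).any():
                raise ValidationError("self-edges are not allowed")
            keys = {tuple(sorted(p)) for p in zip(self.edges["compound_a"], self.edges["compound_b"])}
            if len(keys) != len(self.edges):
                raise ValidationError("duplicate unordered pairs in edge table")
        unknown = set(self.universe) - set(self.kinds.index)
        if unknown:
            raise ValidationError(f"kinds missing for universe compounds: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.edges)

    def _subset(self, mask: pd.Series) -> "EdgeSet":
        return EdgeSet(edges=self.edges[mask].reset_index(drop=True), universe=self.universe, kinds=self.kinds)

    def positive(self) -> "EdgeSet":
        return self._subset(self.edges["sign"] == "positive")

    def negative(self) -> "EdgeSet":
        return self._subset(self.edges["sign"] == "negative")

    @property
    def n_positive(self) -> int:
        return int((self.edges["sign"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.edges["sign"] == "negative").sum())

    def between(self, kind_a: str, kind_b: str) -> "EdgeSet":
        """Edges whose endpoint kinds match {kind_a, kind_b} (unordered)."""
        ka = self.edges["compound_a"].map(self.kinds)
        kb = self.edges["compound_b"].map(self.kinds)
        want = frozenset((kind_a, kind_b))
        mask = [frozenset((a, b)) == want for a, b in zip(ka, kb)]
        return self._subset(pd.Series(mask, index=self.edges.index, dtype=bool))


@dataclass
class NetworkCluster:
    """A connected component of the k-core of the positive-correlation graph.

    ``within_degree`` counts intra-cluster edges per member (each >= k by the
    k-core property); ``hub_rank`` orders members by total correlation count
    in the full positive network, descending, ties lexicographic.
    """

    cluster_id: int
    members: list[str]
    within_degree: dict[str, int]
    hub_rank: list[tuple[str, int]]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PathwayAssignment:
    """Tentative pathway attribution of one volatile via metabolite correlations."""

    volatile_id: str
    assigned_pathways: dict[str, int]
    correlated_metabolites: list[str]

    @property
    def assigned(self) -> bool:
        return bool(self.assigned_pathways)

    @property
    def top_pathway(self) -> str | None:
        """Highest-support pathway; ties broken lexicographically."""
        if not self.assigned_pathways:
            return None
        return min(self.assigned_pathways, key=lambda p: (-self.assigned_pathways[p], p))


@dataclass
class CoPathwayResult:
    """Co-pathway validation statistic over significant metabolite pairs.

    ``fraction`` is None (undefined) when no significant metabolite pair has
    both endpoints annotated; ``ledger`` lists every considered pair with its
    shared-pathway verdict.
    """

    fraction: float | None
    n_shared: int
    n_pairs: int
    ledger: pd.DataFrame


@dataclass
class ResultReport:
    """Everything a full pipeline run produces."""

    differential: pd.DataFrame
    permanova: dict[str, PermanovaResult]
    pca: dict[str, PcaSummary]
    edges: EdgeSet
    clusters: list[NetworkCluster]
    co_pathway: CoPathwayResult
    assignments: list[PathwayAssignment]
    stage_log: pd.DataFrame
    filter_log: pd.DataFrame
    config: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
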