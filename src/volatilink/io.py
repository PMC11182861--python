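"""Readers and writers for abundance tables, metadata, pathway maps and reports.

All inputs are delimited text (comma or tab, auto-detected). Abundance tables
are wide — first column sample identifier, remaining columns compounds — and
empty cells mean "not detected", loading as 0. Numeric output is written with
12 significant digits so write -> read round-trips reproduce values exactly at
that precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    EdgeSet,
    CompoundTable,
    CoPathwayResult,
    NetworkCluster,
    PathwayAssignment,
    PathwayMap,
    ResultReport,
    SampleMetadata,
    TIMEPOINTS,
    TREATMENTS,
    ValidationError,
)

FLOAT_FORMAT = "%.12g"


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _header_fields(path: Path, sep: str) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
    return header.split(sep)


def read_compound_table(path: str | Path, kind: str) -> CompoundTable:
    """Read a wide samples x compounds abundance table (stage ``raw``).

    Empty cells load as 0 (not detected). Duplicate sample or compound
    identifiers, and negative or non-numeric cells, raise
    :class:`ValidationError`.
    """
    path = Path(path)
    sep = _detect_sep(path)
    compounds = _header_fields(path, sep)[1:]
    if len(compounds) != len(set(compounds)):
        dupes = sorted({c for c in compounds if compounds.count(c) > 1})
        raise ValidationError(f"duplicate compound identifiers in {path.name}: {dupes}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.columns = compounds
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"duplicate sample identifiers in {path.name}: {dupes}")
    values = raw.replace("", np.nan)
    try:
        numeric = values.apply(pd.to_numeric)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path.name}: {exc}") from exc
    numeric = numeric.fillna(0.0)
    if (numeric.to_numpy() < 0).any():
        raise ValidationError(f"negative abundance in {path.name}")
    return CompoundTable(data=numeric, kind=kind, stage="raw")


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata (sample_id, treatment, is_blank, internal_standard_area, scale_factor)."""
    path = Path(path)
    sep = _detect_sep(path)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    if "is_blank" in frame.columns:
        frame["is_blank"] = (
            frame["is_blank"].astype(str).str.strip().str.lower().map(
                {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
            )
        )
        if frame["is_blank"].isna().any():
            raise ValidationError(f"unparseable is_blank values in {path.name}")
    return SampleMetadata(frame=frame)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(Path(path), sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read a two-column (compound_id, pathway_id) map; duplicates collapse."""
    path = Path(path)
    sep = _detect_sep(path)
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) != 2:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected 2 fields (compound_id, pathway_id), got {len(fields)}"
                )
            if lineno == 1 and [f.strip().lower() for f in fields] == ["compound_id", "pathway_id"]:
                continue  # optional header row
            pairs.append((fields[0].strip(), fields[1].strip()))
    return PathwayMap.from_pairs(pairs)


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("compound_id\tpathway_id\n")
        for compound, pathway in sorted(pmap.entries):
            fh.write(f"{compound}\t{pathway}\n")


def read_fluorometry(path: str | Path) -> pd.DataFrame:
    """Read replicate-level PSII photochemical-efficiency measurements."""
    path = Path(path)
    sep = _detect_sep(path)
    frame = pd.read_csv(path, sep=sep)
    required = {"sample_id", "treatment", "timepoint", "efficiency"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"fluorometry table missing columns: {sorted(missing)}")
    bad_t = sorted(set(frame["treatment"]) - set(TREATMENTS))
    if bad_t:
        raise ValidationError(f"unknown treatments {bad_t}")
    bad_tp = sorted(set(frame["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(f"unknown timepoints {bad_tp}")
    eff = pd.to_numeric(frame["efficiency"])
    if not ((eff >= 0) & (eff <= 1)).all():
        raise ValidationError("efficiency values must lie in [0, 1]")
    frame["efficiency"] = eff
    return frame


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------


def clusters_frame(clusters: Iterable[NetworkCluster]) -> pd.DataFrame:
    rows = []
    for cluster in clusters:
        total = dict(cluster.hub_rank)
        for member in cluster.members:
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "compound_id": member,
                    "within_degree": cluster.within_degree[member],
                    "total_correlations": total[member],
                }
            )
    return pd.DataFrame(rows, columns=["cluster_id", "compound_id", "within_degree", "total_correlations"])


def assignments_frame(assignments: Iterable[PathwayAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        if not a.assigned_pathways:
            rows.append(
                {"volatile_id": a.volatile_id, "pathway_id": "", "support": 0, "correlated_metabolites": ""}
            )
            continue
        for pathway, support in sorted(a.assigned_pathways.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    "volatile_id": a.volatile_id,
                    "pathway_id": pathway,
                    "support": support,
                    "correlated_metabolites": ";".join(a.correlated_metabolites),
                }
            )
    return pd.DataFrame(rows, columns=["volatile_id", "pathway_id", "support", "correlated_metabolites"])


def write_report(report: ResultReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as a directory of TSV tables plus a JSON summary.

    Returns the mapping of logical table name to written path. Numeric fields
    round-trip at 12 significant digits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["differential"] = out / "differential.tsv"
    report.differential.to_csv(paths["differential"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    paths["edges"] = out / "edges.tsv"
    edges = report.edges.edges.copy()
    edges.insert(2, "kind_a", edges["compound_a"].map(report.edges.kinds))
    edges.insert(3, "kind_b", edges["compound_b"].map(report.edges.kinds))
    edges.to_csv(paths["edges"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    paths["clusters"] = out / "clusters.tsv"
    clusters_frame(report.clusters).to_csv(paths["clusters"], sep="\t", index=False)

    paths["assignments"] = out / "pathway_assignments.tsv"
    assignments_frame(report.assignments).to_csv(paths["assignments"], sep="\t", index=False)

    paths["co_pathway_pairs"] = out / "co_pathway_pairs.tsv"
    report.co_pathway.ledger.to_csv(paths["co_pathway_pairs"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    paths["stage_log"] = out / "stage_log.tsv"
    report.stage_log.to_csv(paths["stage_log"], sep="\t", index=False)

    paths["filter_log"] = out / "filter_log.tsv"
    report.filter_log.to_csv(paths["filter_log"], sep="\t", index=False, float_format=FLOAT_FORMAT)

    summary = {
        "config": report.config,
        "warnings": report.warnings,
        "permanova": {
            kind: {
                "pseudo_f": res.pseudo_f,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "method": res.method,
                "seed": res.seed,
                "df_between": res.df_between,
                "df_within": res.df_within,
            }
            for kind, res in report.permanova.items()
        },
        "pca": {
            kind: {
                "variance_explained_pc1_pc2": float(np.sum(p.variance_explained[:2])),
                "drivers": p.drivers,
            }
            for kind, p in report.pca.items()
        },
        "n_edges_positive": report.edges.n_positive,
        "n_edges_negative": report.edges.n_negative,
        "n_clusters": len(report.clusters),
        "cluster_sizes": [c.size for c in report.clusters],
        "co_pathway_fraction": report.co_pathway.fraction,
        "n_significant": int(report.differential["significant"].sum()) if len(report.differential) else 0,
    }
    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return paths
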