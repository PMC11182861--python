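"""Pathway co-membership validation and correlation-based volatile assignment.

Two computations link the correlation screen to KEGG-style pathway
annotations:

* the **co-pathway fraction** — among significantly correlated metabolite
  pairs with both endpoints annotated, the proportion sharing at least one
  pathway. A high fraction supports using correlations as pathway evidence.
* **volatile -> pathway assignment** — each volatile inherits the pathway
  annotations of the metabolites it significantly (and, by default,
  positively) correlates with, with a per-pathway support count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    METABOLITE,
    VOLATILE,
    CoPathwayResult,
    EdgeSet,
    PathwayAssignment,
    PathwayMap,
    ValidationError,
)


def co_pathway_fraction(
    edges: EdgeSet,
    pmap: PathwayMap,
    mode: str = "annotated_only",
) -> CoPathwayResult:
    """Fraction of significant metabolite pairs sharing >= 1 pathway.

    ``mode="annotated_only"`` (default) excludes pairs with any unannotated
    endpoint from the denominator — missing annotation is missing data, not
    evidence of different pathways. ``mode="inclusive"`` keeps such pairs in
    the denominator as non-shared. With zero qualifying pairs the fraction is
    undefined (None), not 0.
    """
    if mode not in ("annotated_only", "inclusive"):
        raise ValidationError(f"unknown mode {mode!r}")
    met_edges = edges.between(METABOLITE, METABOLITE).edges
    annotations = pmap.as_dict()
    rows = []
    for row in met_edges.itertuples(index=False):
        pa = annotations.get(row.compound_a, frozenset())
        pb = annotations.get(row.compound_b, frozenset())
        annotated = bool(pa) and bool(pb)
        shared = sorted(pa & pb)
        rows.append(
            {
                "compound_a": row.compound_a,
                "compound_b": row.compound_b,
                "rho": row.rho,
                "both_annotated": annotated,
                "shares_pathway": bool(shared),
                "shared_pathways": ";".join(shared),
            }
        )
    ledger = pd.DataFrame(
        rows,
        columns=["compound_a", "compound_b", "rho", "both_annotated", "shares_pathway", "shared_pathways"],
    )
    if mode == "annotated_only":
        denom_mask = ledger["both_annotated"] if len(ledger) else pd.Series(dtype=bool)
    else:
        denom_mask = pd.Series(True, index=ledger.index)
    n_pairs = int(denom_mask.sum()) if len(ledger) else 0
    n_shared = int((ledger["shares_pathway"] & denom_mask).sum()) if len(ledger) else 0
    fraction = (n_shared / n_pairs) if n_pairs > 0 else None
    return CoPathwayResult(fraction=fraction, n_shared=n_shared, n_pairs=n_pairs, ledger=ledger)


def assign_volatile_pathways(
    edges: EdgeSet,
    pmap: PathwayMap,
    positive_only: bool = True,
) -> list[PathwayAssignment]:
    """Assign volatiles to pathways via their correlated, annotated metabolites.

    For every volatile in the edge universe, the qualifying edges are its
    significant volatile-metabolite correlations (positive-sign only by
    default); its assigned pathways are the union of the annotated correlated
    metabolites' pathways, with support = number of those metabolites carrying
    each pathway. Volatiles with no qualifying annotated partner are reported
    unassigned.
    """
    pool = edges.positive() if positive_only else edges
    vm = pool.between(VOLATILE, METABOLITE).edges
    annotations = pmap.as_dict()
    volatiles = sorted(c for c in edges.universe if edges.kinds[c] == VOLATILE)
    partners: dict[str, set[str]] = {v: set() for v in volatiles}
    for row in vm.itertuples(index=False):
        if edges.kinds[row.compound_a] == VOLATILE:
            vol, met = row.compound_a, row.compound_b
        else:
            vol, met = row.compound_b, row.compound_a
        partners[vol].add(met)
    assignments = []
    for vol in volatiles:
        mets = sorted(partners[vol])
        support: dict[str, int] = {}
        annotated_mets = []
        for met in mets:
            pathways = annotations.get(met, frozenset())
            if not pathways:
                continue
            annotated_mets.append(met)
            for p in pathways:
                support[p] = support.get(p, 0) + 1
        assignments.append(
            PathwayAssignment(
                volatile_id=vol,
                assigned_pathways=support,
                correlated_metabolites=annotated_mets,
            )
        )
    return assignments


def permute_annotations(pmap: PathwayMap, rng: np.random.Generator) -> PathwayMap:
    """Randomly reassign annotation sets among the annotated compounds.

    The multiset of annotation sets and the annotated-compound universe are
    preserved; only which compound carries which set changes. Used for the
    null distribution of the co-pathway fraction.
    """
    annotations = pmap.as_dict()
    compounds = sorted(annotations)
    sets = [annotations[c] for c in compounds]
    order = rng.permutation(len(compounds))
    pairs = []
    for compound, idx in zip(compounds, order):
        for pathway in sets[idx]:
            pairs.append((compound, pathway))
    return PathwayMap.from_pairs(pairs)


def background_sharing_probability(pmap: PathwayMap) -> float:
    """Probability that two distinct random annotated compounds share a pathway."""
    sets = list(pmap.as_dict().values())
    m = len(sets)
    if m < 2:
        raise ValidationError("need >= 2 annotated compounds")
    shared = sum(1 for i in range(m) for j in range(i + 1, m) if sets[i] & sets[j])
    return shared / (m * (m - 1) / 2)
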