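"""Spearman correlation screening, Holm adjustment and k-core clustering.

The combined volatile + metabolite log-centred matrix is screened for
monotone associations: Spearman rho for every unordered compound pair
(average ranks for ties), a t-approximation p-value with n-2 degrees of
freedom, Holm step-down adjustment over the whole family of defined pairs,
and an edge for every pair with |rho| above a threshold and adjusted p below
a cutoff. Compounds constant across samples have undefined rho; their pairs
are reported missing and excluded from the Holm family.

Clusters follow the rule "every compound correlates with at least k others in
the cluster", which is exactly the defining property of the k-core: clusters
are the connected components of the k-core of the positive-edge graph.
"""

from __future__ import annotations

from itertools import permutations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CompoundTable, EdgeSet, NetworkCluster, ValidationError


def combine_tables(volatiles: CompoundTable, metabolites: CompoundTable) -> tuple[pd.DataFrame, pd.Series]:
    """Join two log-centred tables on their shared samples.

    Returns the combined samples x compounds matrix and the per-compound kind
    series. Compound identifiers must not overlap between datasets.
    """
    overlap = set(volatiles.compound_ids) & set(metabolites.compound_ids)
    if overlap:
        raise ValidationError(f"compound identifiers appear in both datasets: {sorted(overlap)}")
    shared = [s for s in volatiles.sample_ids if s in set(metabolites.sample_ids)]
    if len(shared) < 4:
        raise ValidationError(f"need >= 4 shared samples for correlation screening, got {len(shared)}")
    combined = pd.concat([volatiles.data.loc[shared], metabolites.data.loc[shared]], axis=1)
    kinds = pd.Series(
        {**{c: volatiles.kind for c in volatiles.compound_ids},
         **{c: metabolites.kind for c in metabolites.compound_ids}}
    )
    return combined, kinds


def spearman_all_pairs(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and t-approximation p-values.

    rho is the Pearson correlation of average ranks. p = 2 * P(T_{n-2} >=
    |rho| * sqrt((n-2)/(1-rho^2))). Pairs involving a constant column are NaN
    in both matrices; the diagonal carries rho 1 and p NaN (excluded
    downstream).
    """
    n = data.shape[0]
    if n < 4:
        raise ValidationError(f"need >= 4 samples, got {n}")
    x = data.to_numpy(dtype=float)
    constant = np.ptp(x, axis=0) == 0
    ranks = stats.rankdata(x, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    np.fill_diagonal(p, np.nan)
    index = data.columns
    return (
        pd.DataFrame(rho, index=index, columns=index),
        pd.DataFrame(p, index=index, columns=index),
    )


def spearman_exact_pvalue(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman rho of one pair (n <= 10).

    Enumerates all n! orderings of one margin; intended for small-sample
    spot checks, not the all-pairs screen.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValidationError("paired vectors must have equal length")
    if n > 10:
        raise ValidationError("exact permutation p is limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("constant input: rho undefined")

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    observed = _rho(rx, ry)
    count = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if abs(_rho(rx, np.asarray(perm))) >= abs(observed) - 1e-12:
            count += 1
    return observed, count / total


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (familywise error control).

    adj p_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending order,
    mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def holm_adjust_matrix(p: pd.DataFrame) -> pd.DataFrame:
    """Holm adjustment over the family of all defined unordered pairs."""
    cols = p.columns
    m = len(cols)
    iu = np.triu_indices(m, k=1)
    flat = p.to_numpy()[iu]
    defined = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if defined.any():
        adj[defined] = holm_adjust(flat[defined])
    out = np.full((m, m), np.nan)
    out[iu] = adj
    out.T[iu] = adj
    return pd.DataFrame(out, index=cols, columns=cols)


def select_significant_edges(
    rho: pd.DataFrame,
    p_adj: pd.DataFrame,
    kinds: Mapping[str, str] | pd.Series,
    r_threshold: float = 0.7,
    p_threshold: float = 0.05,
    p_raw: pd.DataFrame | None = None,
) -> EdgeSet:
    """Edges for pairs with |rho| > r_threshold and adjusted p < p_threshold."""
    cols = list(rho.columns)
    kinds = pd.Series(kinds).loc[cols]
    r = rho.to_numpy()
    pa = p_adj.to_numpy()
    praw = p_raw.to_numpy() if p_raw is not None else np.full_like(pa, np.nan)
    iu = np.triu_indices(len(cols), k=1)
    keep = (~np.isnan(r[iu])) & (np.abs(r[iu]) > r_threshold) & (pa[iu] < p_threshold)
    ia, ib = iu[0][keep], iu[1][keep]
    edges = pd.DataFrame(
        {
            "compound_a": [cols[i] for i in ia],
            "compound_b": [cols[j] for j in ib],
            "rho": r[ia, ib],
            "p_raw": praw[ia, ib],
            "p_adj": pa[ia, ib],
        }
    )
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    # canonical unordered orientation
    swap = edges["compound_a"] > edges["compound_b"]
    edges.loc[swap, ["compound_a", "compound_b"]] = edges.loc[swap, ["compound_b", "compound_a"]].to_numpy()
    edges = edges.sort_values(["compound_a", "compound_b"]).reset_index(drop=True)
    return EdgeSet(edges=edges, universe=cols, kinds=kinds)


def significant_correlations(
    volatiles_lc: CompoundTable,
    metabolites_lc: CompoundTable,
    r_threshold: float = 0.7,
    p_threshold: float = 0.05,
    compounds: Sequence[str] | None = None,
) -> tuple[EdgeSet, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Combined-matrix Spearman/Holm screen returning the EdgeSet and matrices.

    ``compounds`` optionally restricts the screen (and hence the Holm family)
    to a subset, e.g. the differentially abundant compounds.
    """
    combined, kinds = combine_tables(volatiles_lc, metabolites_lc)
    if compounds is not None:
        keep = [c for c in combined.columns if c in set(compounds)]
        combined = combined.loc[:, keep]
        kinds = kinds.loc[keep]
    rho, p = spearman_all_pairs(combined)
    p_adj = holm_adjust_matrix(p)
    edges = select_significant_edges(rho, p_adj, kinds, r_threshold, p_threshold, p_raw=p)
    return edges, rho, p, p_adj


def positive_graph(edges: EdgeSet) -> nx.Graph:
    """Undirected simple graph of the positive-sign edges."""
    graph = nx.Graph()
    graph.add_nodes_from(edges.universe)
    pos = edges.positive().edges
    graph.add_edges_from(zip(pos["compound_a"], pos["compound_b"]))
    return graph


def extract_clusters(edges: EdgeSet, k: int = 5) -> list[NetworkCluster]:
    """Connected components of the k-core of the positive-correlation graph.

    Iteratively removing vertices of degree < k until a fixed point leaves the
    maximal subgraph in which every compound correlates with at least k others;
    its connected components are the clusters. Clusters are ordered by size
    (descending), ties by smallest member id; hub_rank orders members by total
    correlation count in the full positive network.
    """
    graph = positive_graph(edges)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    core = nx.k_core(graph, k=k)
    components = sorted(nx.connected_components(core), key=lambda c: (-len(c), min(c)))
    clusters = []
    for cid, comp in enumerate(components, start=1):
        members = sorted(comp)
        sub = core.subgraph(comp)
        within = {m: int(sub.degree(m)) for m in members}
        totals = {m: int(graph.degree(m)) for m in members}
        hub_rank = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        clusters.append(
            NetworkCluster(cluster_id=cid, members=members, within_degree=within, hub_rank=hub_rank)
        )
    return clusters
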