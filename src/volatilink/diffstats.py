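"""Per-compound differential abundance, PCA and permutation PERMANOVA.

The PERMANOVA here is the one-factor permutational multivariate ANOVA of
Anderson (2001) on Euclidean distances of the log-centred matrix:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within
    pseudo-F  = (SS_between / (a-1)) / (SS_within / (N-a))

The p-value comes from permuting treatment labels over samples. When the
number of distinct label assignments is small (<= ``exhaustive_limit``) the
full permutation distribution is enumerated, giving an exact, seed-independent
p = #(F_perm >= F_obs) / #assignments (the identity assignment included).
Otherwise ``n_perm`` random permutations are drawn and the standard
(count + 1) / (n_perm + 1) estimate is reported.
"""

from __future__ import annotations

import warnings
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CompoundTable,
    CONTROL,
    HIGH_LIGHT,
    PcaSummary,
    PermanovaResult,
    SampleMetadata,
    ValidationError,
)

DEFAULT_SEED = 20240617

DIFFERENTIAL_COLUMNS = (
    "compound_id",
    "kind",
    "fold_change",
    "log2_fc",
    "t_stat",
    "p_raw",
    "p_adj",
    "significant",
)


def adjust_pvalues(p_raw: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``"bh"`` (FDR), ``"holm"`` or ``"none"``."""
    p_raw = np.asarray(p_raw, dtype=float)
    if p_raw.size == 0:
        return p_raw.copy()
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return p_raw.copy()
    sm_method = {"bh": "fdr_bh", "holm": "holm"}.get(method)
    if sm_method is None:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p_raw, method=sm_method)[1]


def differential_abundance(
    table_lc: CompoundTable,
    table_pre: CompoundTable,
    meta: SampleMetadata,
    adjust: str = "bh",
    alpha: float = 0.05,
    welch: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per compound plus fold change on pre-log values.

    The t-test (Welch by default; pooled-variance with ``welch=False``) runs
    on the log-centred values; the fold change is the high-light group mean
    divided by the control group mean of the pre-log normalised table (0/0
    gives NaN, x/0 gives +inf). Adjusted p-values are computed across the
    compounds of this table only, so volatiles and metabolites are corrected
    separately when processed as separate tables.
    """
    if list(table_lc.compound_ids) != list(table_pre.compound_ids):
        raise ValidationError("log-centred and pre-log tables must share compounds in order")
    control = [s for s in table_lc.sample_ids if s in set(meta.group_members(CONTROL))]
    treated = [s for s in table_lc.sample_ids if s in set(meta.group_members(HIGH_LIGHT))]
    if len(control) < 2 or len(treated) < 2:
        raise ValidationError(
            f"need >= 2 replicates per group (control={len(control)}, high_light={len(treated)})"
        )
    x = table_lc.data.loc[treated].to_numpy()
    y = table_lc.data.loc[control].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant compounds trip scipy's precision-loss warning; the
        # zero-difference case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_raw = stats.ttest_ind(x, y, axis=0, equal_var=not welch)
    # Zero-variance, zero-difference compounds: no evidence of change.
    nodiff = np.isnan(t_stat) & np.isclose(x.mean(axis=0), y.mean(axis=0))
    t_stat = np.where(nodiff, 0.0, t_stat)
    p_raw = np.where(nodiff, 1.0, p_raw)

    mean_treat = table_pre.data.loc[treated].mean(axis=0).to_numpy()
    mean_ctrl = table_pre.data.loc[control].mean(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_treat / mean_ctrl
        fold = np.where((mean_treat == 0) & (mean_ctrl == 0), np.nan, fold)
        log2_fc = np.log2(fold)

    p_adj = adjust_pvalues(p_raw, method=adjust)
    return pd.DataFrame(
        {
            "compound_id": table_lc.compound_ids,
            "kind": table_lc.kind,
            "fold_change": fold,
            "log2_fc": log2_fc,
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        columns=list(DIFFERENTIAL_COLUMNS),
    )


def pca_summary(
    table_lc: CompoundTable,
    loading_threshold: float = 0.2,
) -> PcaSummary:
    """PCA of the mean-centred matrix via SVD.

    variance_explained sums to 1 over all components; loadings are unit-norm
    right singular vectors; drivers are compounds with |loading| above the
    threshold on PC1 or PC2. Component signs are fixed so the largest-
    magnitude loading of each component is positive.
    """
    if table_lc.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if table_lc.n_compounds < 2:
        raise ValidationError("PCA needs at least 2 compounds")
    x = table_lc.values - table_lc.values.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    var = s**2 / total if total > 0 else np.zeros_like(s)
    # deterministic sign convention
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    comps = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=table_lc.compound_ids, columns=comps)
    scores = pd.DataFrame(u * s, index=table_lc.sample_ids, columns=comps)
    lead = loadings.iloc[:, : min(2, loadings.shape[1])]
    drivers = list(lead.index[(lead.abs() > loading_threshold).any(axis=1)])
    return PcaSummary(
        variance_explained=var,
        loadings=loadings,
        scores=scores,
        drivers=drivers,
        threshold=loading_threshold,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _distinct_permutations(items: np.ndarray):
    """Yield distinct permutations of a label multiset in lexicographic order."""
    counts = {}
    for item in items.tolist():
        counts[item] = counts.get(item, 0) + 1
    keys = sorted(counts)
    n = len(items)
    perm: list = []

    def rec():
        if len(perm) == n:
            yield tuple(perm)
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                perm.append(k)
                yield from rec()
                perm.pop()
                counts[k] += 1

    yield from rec()


def n_distinct_assignments(labels: Sequence) -> int:
    """Number of distinct label assignments (multinomial coefficient)."""
    labels = list(labels)
    total = factorial(len(labels))
    for _, count in pd.Series(labels).value_counts().items():
        total //= factorial(int(count))
    return total


def _ss_within_batch(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """SS_within for a batch of label-code vectors (batch x N)."""
    out = np.zeros(codes.shape[0])
    for g in range(n_groups):
        mask = (codes == g).astype(float)
        n_g = mask.sum(axis=1)
        out += np.einsum("bi,ij,bj->b", mask, d2, mask) / (2.0 * n_g)
    return out


def permanova(
    data: CompoundTable | pd.DataFrame | np.ndarray,
    labels: Sequence,
    n_perm: int = 999,
    seed: int | None = DEFAULT_SEED,
    method: str = "auto",
    exhaustive_limit: int = 10_000,
) -> PermanovaResult:
    """One-factor PERMANOVA on Euclidean distances with label permutations.

    Parameters
    ----------
    data
        Samples x variables matrix (rows are observations).
    labels
        Group label per sample; any number of levels >= 2.
    method
        ``"auto"`` enumerates all distinct assignments when their count is at
        most ``exhaustive_limit`` and falls back to Monte-Carlo sampling
        otherwise; ``"exact"`` forces enumeration; ``"sampled"`` forces
        Monte-Carlo with ``n_perm`` draws.
    """
    if isinstance(data, CompoundTable):
        x = data.values
    elif isinstance(data, pd.DataFrame):
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(list(labels))
    if len(labels) != x.shape[0]:
        raise ValidationError("one label per sample is required")
    levels, codes = np.unique(labels, return_inverse=True)
    a = len(levels)
    n = x.shape[0]
    if a < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(levels[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValidationError(f"groups with a single sample make within-group SS degenerate: {small}")
    if method not in ("auto", "exact", "sampled"):
        raise ValidationError(f"unknown method {method!r}")

    d2 = squareform(pdist(x, metric="euclidean") ** 2)
    ss_total = float(d2.sum()) / (2.0 * n)
    ss_within = float(_ss_within_batch(d2, codes[None, :], a)[0])
    ss_between = ss_total - ss_within
    df_between, df_within = a - 1, n - a

    if ss_total <= 1e-12:  # all samples identical: statistic undefined
        return PermanovaResult(
            pseudo_f=float("nan"), r_squared=float("nan"), p_value=float("nan"),
            n_perm=0, seed=seed, method="degenerate",
            df_between=df_between, df_within=df_within,
            ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        )

    def f_from_ssw(ssw: np.ndarray) -> np.ndarray:
        ssb = ss_total - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / df_between) / (ssw / df_within)

    f_obs = float(f_from_ssw(np.array([ss_within]))[0])
    r_squared = ss_between / ss_total

    n_exact = n_distinct_assignments(labels)
    use_exact = method == "exact" or (method == "auto" and n_exact <= exhaustive_limit)
    if use_exact:
        perms = np.array(list(_distinct_permutations(codes)), dtype=int)
        f_perm = f_from_ssw(_ss_within_batch(d2, perms, a))
        count = int(np.sum(f_perm >= f_obs - 1e-12))
        p_value = count / n_exact
        return PermanovaResult(
            pseudo_f=f_obs, r_squared=r_squared, p_value=p_value,
            n_perm=n_exact, seed=None, method="exact",
            df_between=df_between, df_within=df_within,
            ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        )

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)], dtype=int)
    f_perm = f_from_ssw(_ss_within_batch(d2, perms, a))
    count = int(np.sum(f_perm >= f_obs - 1e-12))
    p_value = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=f_obs, r_squared=r_squared, p_value=p_value,
        n_perm=n_perm, seed=seed, method="sampled",
        df_between=df_between, df_within=df_within,
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
    )


def permanova_by_treatment(
    table_lc: CompoundTable,
    meta: SampleMetadata,
    n_perm: int = 999,
    seed: int | None = DEFAULT_SEED,
    method: str = "auto",
) -> PermanovaResult:
    """PERMANOVA of a log-centred table against its treatment labels."""
    labels = meta.treatment_labels(table_lc.sample_ids)
    return permanova(table_lc, labels, n_perm=n_perm, seed=seed, method=method)
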