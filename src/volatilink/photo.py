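"""Statistics for PSII photochemical-efficiency (fluorometry) measurements.

Replicate-level Fv/Fm and Fq'/Fm' values, recorded per treatment group at
three timepoints (before the light exposure, at the end of it, and after
recovery), are analysed with a two-factor ANOVA with interaction, Tukey HSD
pairwise comparisons across the treatment x timepoint cells, and simple
group-mean ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import TIMEPOINTS, TREATMENTS, ValidationError


def _validate(data: pd.DataFrame) -> pd.DataFrame:
    required = {"treatment", "timepoint", "efficiency"}
    missing = required - set(data.columns)
    if missing:
        raise ValidationError(f"fluorometry data missing columns: {sorted(missing)}")
    bad_t = sorted(set(data["treatment"]) - set(TREATMENTS))
    if bad_t:
        raise ValidationError(f"unknown treatments {bad_t}")
    bad_tp = sorted(set(data["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(f"unknown timepoints {bad_tp}")
    eff = pd.to_numeric(data["efficiency"])
    if not ((eff >= 0) & (eff <= 1)).all():
        raise ValidationError("efficiency must lie in [0, 1]")
    cell_sizes = data.groupby(["treatment", "timepoint"], observed=True).size()
    if (cell_sizes < 2).any():
        small = list(cell_sizes[cell_sizes < 2].index)
        raise ValidationError(f"cells with < 2 replicates (no within-cell variance): {small}")
    return data


def is_balanced(data: pd.DataFrame) -> bool:
    """True when every treatment x timepoint cell has the same replicate count."""
    sizes = data.groupby(["treatment", "timepoint"], observed=True).size()
    return sizes.nunique() == 1


def interaction_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA with interaction (sequential, type-I sums of squares).

    Returns a tidy table with one row per term (treatment, timepoint,
    treatment:timepoint, residual) carrying df, sum_sq, F and p. For the
    balanced designs this targets, type-I and type-II decompositions
    coincide. When the residual sum of squares is (numerically) zero the F
    ratios are undefined and reported as NaN.
    """
    data = _validate(data)
    model = smf.ols("efficiency ~ C(treatment) * C(timepoint)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=1)
    rename = {
        "C(treatment)": "treatment",
        "C(timepoint)": "timepoint",
        "C(treatment):C(timepoint)": "treatment:timepoint",
        "Residual": "residual",
    }
    out = table.rename(index=rename).reset_index(names="factor")
    out = out.rename(columns={"df": "Df", "PR(>F)": "p"})
    resid_ms = float(out.loc[out["factor"] == "residual", "sum_sq"].iloc[0]) / float(
        out.loc[out["factor"] == "residual", "Df"].iloc[0]
    )
    if resid_ms < 1e-30:
        out.loc[out["factor"] != "residual", ["F", "p"]] = np.nan
    return out[["factor", "Df", "sum_sq", "F", "p"]]


def interaction_test(data: pd.DataFrame) -> tuple[float, float, int]:
    """(F, p, df) of the treatment x timepoint interaction term."""
    table = interaction_anova(data)
    row = table[table["factor"] == "treatment:timepoint"].iloc[0]
    return float(row["F"]), float(row["p"]), int(row["Df"])


def tukey_hsd(data: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over all treatment x timepoint cell pairs.

    Adjusted p-values come from the studentized range distribution with the
    pooled within-cell variance. Returns one row per unordered cell pair.
    """
    data = _validate(data)
    cells = data["treatment"].astype(str) + "@" + data["timepoint"].astype(str)
    if data.groupby(cells).size().min() < 2:
        raise ValidationError("every cell needs >= 2 replicates for Tukey HSD")
    within_var = data.groupby(cells)["efficiency"].var(ddof=1)
    if (within_var <= 0).all():
        # all cells internally constant: no within-cell variance to studentize
        pairs = sorted(set(cells))
        rows = []
        for i, a in enumerate(pairs):
            for b in pairs[i + 1 :]:
                ma = data.loc[cells == a, "efficiency"].mean()
                mb = data.loc[cells == b, "efficiency"].mean()
                rows.append({"cell_a": a, "cell_b": b, "mean_diff": mb - ma, "p_adj": np.nan, "reject": False})
        return pd.DataFrame(rows)
    result = pairwise_tukeyhsd(endog=data["efficiency"].to_numpy(), groups=cells.to_numpy(), alpha=alpha)
    frame = pd.DataFrame(result.summary().data[1:], columns=result.summary().data[0])
    out = pd.DataFrame(
        {
            "cell_a": frame["group1"],
            "cell_b": frame["group2"],
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": result.pvalues,
            "reject": result.reject,
        }
    )
    return out


def mean_ratio(numerator: float, denominator: float) -> tuple[float, int]:
    """Ratio of two group means and its nearest-integer rounding."""
    if not denominator > 0:
        raise ValidationError("denominator mean must be positive")
    ratio = float(numerator) / float(denominator)
    return ratio, int(round(ratio))
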