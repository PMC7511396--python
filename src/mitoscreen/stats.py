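"""Group comparisons used by the assays.

Two-way fixed-effects ANOVA (genotype × timepoint/condition) with Sidak- or
Tukey-adjusted per-timepoint genotype contrasts, and a mixed (repeated
measures) ANOVA for the time-lapse assays with time as the within-subject
factor and genotype between subjects.

The unit of replication is the differentiation round, not the single cell:
per-cell values are averaged per round first (``collapse_to_rounds``), so the
reported n matches independent biological replicates and avoids
pseudoreplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


@dataclass
class GroupComparison:
    """ANOVA table plus per-contrast raw and adjusted p-values."""

    anova: pd.DataFrame  # factor, F, p
    contrasts: pd.DataFrame  # timepoint, estimate, p_raw, p_adj
    correction: str
    n: int


def sidak_adjust(p: np.ndarray | float, k: int) -> np.ndarray | float:
    """Sidak family-wise adjustment 1 − (1 − p)^k for k contrasts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=np.float64)) ** k


def collapse_to_rounds(
    per_cell: pd.DataFrame,
    value: str,
    by: tuple[str, ...] = ("genotype", "timepoint", "round"),
) -> pd.DataFrame:
    """Average per-cell values within each differentiation round."""
    return per_cell.groupby(list(by), as_index=False)[value].mean()


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "timepoint",
    correction: str = "sidak",
) -> GroupComparison:
    """Two-way fixed-effects ANOVA with multiplicity-adjusted contrasts.

    Requires >= 2 levels per factor and >= 2 replicates in every design
    cell.  Contrasts compare the two genotype levels within each timepoint
    (the usual post-test layout); with more than two levels of ``factor_a``
    all pairwise within-timepoint differences are reported.
    """
    if correction not in ("sidak", "tukey"):
        raise ValueError("correction must be 'sidak' or 'tukey'")
    df = table[[value, factor_a, factor_b]].dropna().copy()
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("need >= 2 levels per factor")
    cell_sizes = df.groupby([factor_a, factor_b]).size()
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in cell_sizes.index:
                raise ValueError(f"empty design cell: {factor_a}={a!r}, {factor_b}={b!r}")
            if cell_sizes[(a, b)] < 2:
                raise ValueError(
                    f"design cell {factor_a}={a!r}, {factor_b}={b!r} has "
                    f"{cell_sizes[(a, b)]} replicate(s); need >= 2"
                )
    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
    }
    anova = (
        aov.rename(index=rename)
        .reset_index()
        .rename(columns={"index": "factor", "F": "F", "PR(>F)": "p"})
    )
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    df_resid = float(aov.loc["Residual", "df"])

    rows = []
    pairs = [
        (levels_a[i], levels_a[j])
        for i in range(len(levels_a))
        for j in range(i + 1, len(levels_a))
    ]
    for b in levels_b:
        for a1, a2 in pairs:
            g1 = df[(df[factor_a] == a1) & (df[factor_b] == b)][value]
            g2 = df[(df[factor_a] == a2) & (df[factor_b] == b)][value]
            est = g1.mean() - g2.mean()
            se = np.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2)))
            t = est / se
            if correction == "sidak":
                p_raw = 2.0 * sps.t.sf(abs(t), df_resid)
            else:
                # studentized-range p for the pairwise family of genotype levels
                p_raw = sps.studentized_range.sf(abs(t) * np.sqrt(2.0), len(levels_a), df_resid)
            rows.append(
                {
                    factor_b: b,
                    "contrast": f"{a1} - {a2}",
                    "estimate": est,
                    "t": t,
                    "p_raw": float(min(p_raw, 1.0)),
                }
            )
    contrasts = pd.DataFrame(rows)
    k = len(contrasts)
    if correction == "sidak":
        contrasts["p_adj"] = sidak_adjust(contrasts["p_raw"].to_numpy(), k)
    else:
        # Tukey already controls the genotype family per timepoint; adjust the
        # timepoint family with Sidak on top so the whole table is one family.
        contrasts["p_adj"] = sidak_adjust(contrasts["p_raw"].to_numpy(), len(levels_b))
    contrasts["p_adj"] = contrasts["p_adj"].clip(upper=1.0)
    return GroupComparison(anova=anova, contrasts=contrasts, correction=correction, n=len(df))


def repeated_measures_anova(
    table: pd.DataFrame,
    value: str = "m",
    subject: str = "subject",
    within: str = "frame",
    between: str = "group",
) -> GroupComparison:
    """Mixed ANOVA across all time points: time within subject, genotype
    between.  Subjects are replicate differentiation rounds.

    Returns the genotype (between) main effect together with the time and
    interaction terms.  Frames must match across groups and every group
    needs >= 2 subjects.
    """
    import pingouin as pg

    df = table[[value, subject, within, between]].dropna().copy()
    frames_by_group = df.groupby(between)[within].unique()
    ref = set(frames_by_group.iloc[0])
    for g, frames in frames_by_group.items():
        if set(frames) != ref:
            raise ValueError(f"group {g!r} has different time points than the others")
    n_subj = df.groupby(between)[subject].nunique()
    if (n_subj < 2).any():
        bad = n_subj[n_subj < 2].index.tolist()
        raise ValueError(f"groups {bad} have a single subject; repeated-measures needs >= 2")
    aov = pg.mixed_anova(data=df, dv=value, within=within, between=between, subject=subject)
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    anova = aov.rename(columns={"Source": "factor", pcol: "p"})[["factor", "F", "p"]]
    row = anova[anova["factor"] == between].iloc[0]
    contrasts = pd.DataFrame(
        [{"contrast": f"{between} main effect", "estimate": np.nan, "p_raw": row["p"], "p_adj": row["p"]}]
    )
    return GroupComparison(
        anova=anova, contrasts=contrasts, correction="none", n=int(df[subject].nunique())
    )
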