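"""Genotype/variant association statistics for behaviour profiles.

Univariate and multivariate layers around the discriminant model: a
canonical-variate (MANOVA) map with Bonferroni-adjusted group confidence
ellipses, two-way fixed-effects ANOVAs with the farm as a block, variant
presence/absence ANOVAs (each genotype decomposes into its two allele
variants), Brown-Forsythe/Levene variance-equality tests, two-way
random-effects intraclass correlations (ICC2) of the daily behaviours, and
per-variable distribution reports (skewness, kurtosis, Shapiro-Wilk).

p-values are reported raw; report annotations mark p < 0.1 and p < 0.05
(the dual thresholds conventional in this literature) and no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import linalg, stats

from .discriminant import _scatter_matrices

__all__ = [
    "ManovaMap",
    "manova_map",
    "two_way_anova",
    "variant_presence_anova",
    "levene_test",
    "Icc2Result",
    "icc2",
    "distribution_report",
    "genotype_variants",
]


# -------------------------------------------------------------- MANOVA map
@dataclass
class ManovaMap:
    """Canonical-variate map: centroids, loadings, ellipses, axis shares."""

    classes: list
    variables: list
    centroids: pd.DataFrame           # (G, n_axes) canonical coordinates
    loadings: pd.DataFrame            # (d, n_axes) variable coefficients
    proportion_of_variation: np.ndarray
    ellipses: pd.DataFrame            # centre_x/y, semi_major/minor, angle_deg
    coverage: float
    per_variable_p: pd.Series         # univariate F per variable

    def plot(self, ax=None):
        """Centroid/ellipse map on the first two canonical axes."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse

        if ax is None:
            _, ax = plt.subplots()
        for _, row in self.ellipses.iterrows():
            ax.add_patch(
                Ellipse(
                    (row["centre_x"], row["centre_y"]),
                    2 * row["semi_major"],
                    2 * row["semi_minor"],
                    angle=row["angle_deg"],
                    fill=False,
                )
            )
            ax.annotate(row["class"], (row["centre_x"], row["centre_y"]))
        for var in self.loadings.index:
            x, y = self.loadings.loc[var].iloc[:2]
            ax.arrow(0, 0, x, y, head_width=0.02, color="grey")
            ax.annotate(var, (x, y), fontsize=7)
        p1, p2 = self.proportion_of_variation[:2]
        ax.set_xlabel(f"axis 1 ({p1:.1%})")
        ax.set_ylabel(f"axis 2 ({p2:.1%})")
        ax.autoscale_view()
        return ax


def manova_map(
    scaled: pd.DataFrame,
    labels,
    variables: list[str],
    coverage: float = 0.95,
) -> ManovaMap:
    """Canonical variate analysis of class separation.

    Group centroids and variable loadings are projected on the eigen-axes
    of the between/within scatter; each axis carries its eigenvalue share
    of the discriminable variation.  Per-group confidence ellipses for the
    centroid use a chi-square radius in the canonical space (where the
    pooled within covariance is the identity) scaled by ``1/sqrt(n_g)``,
    with the coverage Bonferroni-split across the G simultaneous regions.
    Per-variable p-values are univariate F tests within the same framework.
    """
    X = scaled[list(variables)].to_numpy(float)
    y = np.asarray(labels)
    Sw, Sb, classes = _scatter_matrices(X, y)
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError:
        ridge = 1e-6 * np.trace(Sw) / Sw.shape[0]
        evals, evecs = linalg.eigh(Sb, Sw + ridge * np.eye(Sw.shape[0]))
    order = np.argsort(evals)[::-1]
    n_axes = min(len(classes) - 1, X.shape[1])
    evals = np.clip(evals[order][:n_axes], 0, None)
    A = evecs[:, order][:, :n_axes]
    for j in range(A.shape[1]):
        nz = np.flatnonzero(np.abs(A[:, j]) > 1e-12)
        if nz.size and A[nz[0], j] < 0:
            A[:, j] = -A[:, j]
    grand = X.mean(axis=0)
    axis_names = [f"axis_{i + 1}" for i in range(n_axes)]
    centroids = pd.DataFrame(
        [(X[y == c].mean(axis=0) - grand) @ A for c in classes],
        index=list(classes),
        columns=axis_names,
    )
    loadings = pd.DataFrame(A, index=list(variables), columns=axis_names)

    G = len(classes)
    alpha = (1 - coverage) / G  # Bonferroni split across groups
    radius2 = stats.chi2.ppf(1 - alpha, 2)
    rows = []
    for c in classes:
        n_g = int((y == c).sum())
        r = np.sqrt(radius2 / n_g)
        rows.append(
            {
                "class": c,
                "centre_x": centroids.loc[c, "axis_1"],
                "centre_y": centroids.loc[c, "axis_2"] if n_axes > 1 else 0.0,
                "semi_major": r,
                "semi_minor": r,
                "angle_deg": 0.0,
            }
        )
    ellipses = pd.DataFrame(rows)

    pvals = {}
    for v in variables:
        groups = [scaled.loc[y == c, v].to_numpy(float) for c in classes]
        pvals[v] = stats.f_oneway(*groups).pvalue
    return ManovaMap(
        list(classes),
        list(variables),
        centroids,
        loadings,
        evals / evals.sum() if evals.sum() > 0 else evals,
        ellipses,
        coverage,
        pd.Series(pvals),
    )


# -------------------------------------------------------------------- ANOVA
def _is_balanced(df: pd.DataFrame, factor_a: str, factor_b: str) -> bool:
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    full = df[factor_a].nunique() * df[factor_b].nunique()
    return len(counts) == full and counts.nunique() == 1


def two_way_anova(
    values,
    genotype,
    farm,
    interaction: bool = False,
) -> pd.DataFrame:
    """Additive two-way fixed-effects ANOVA: treatment + farm block.

    Type-I sums of squares on balanced designs (where term order is
    immaterial), type-II otherwise.  The headline model is additive; the
    genotype x farm interaction is available as a diagnostic and is skipped
    with a note when a cell is empty.  Returns the ANOVA table with columns
    ``term, sum_sq, df, F, p``.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, float), "genotype": np.asarray(genotype),
         "farm": np.asarray(farm)}
    ).dropna()
    if df["genotype"].nunique() < 2 or df["farm"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    formula = "value ~ C(genotype) + C(farm)"
    if interaction:
        cells = df.groupby(["genotype", "farm"]).size()
        full = df["genotype"].nunique() * df["farm"].nunique()
        if len(cells) < full:
            raise ValueError("empty genotype x farm cell; interaction diagnostic skipped")
        formula += " + C(genotype):C(farm)"
    fit = smf.ols(formula, data=df).fit()
    typ = 1 if _is_balanced(df, "genotype", "farm") else 2
    table = sm.stats.anova_lm(fit, typ=typ).reset_index()
    table.columns = ["term"] + list(table.columns[1:])
    table["term"] = (
        table["term"]
        .str.replace("C(genotype)", "genotype", regex=False)
        .str.replace("C(farm)", "farm", regex=False)
        .str.replace(":", " x ")
        .str.strip()
    )
    table = table.rename(columns={"PR(>F)": "p"})
    table["ss_type"] = typ
    return table


def genotype_variants(genotype: str) -> set[str]:
    """Decompose a two-allele genotype label into its variant set."""
    return set(genotype)


def variant_presence_anova(values, genotype, farm) -> pd.DataFrame:
    """Two-way ANOVA of each variant's presence/absence indicator + farm.

    For each variant occurring in the cohort, cows are coded 1 when the
    variant appears in their genotype.  Variants with no contrast (all cows
    carry, or none carries) are skipped with a note row.
    """
    genotype = np.asarray(genotype)
    variants = sorted({v for g in genotype for v in genotype_variants(g)})
    rows = []
    for v in variants:
        present = np.array([v in genotype_variants(g) for g in genotype], dtype=int)
        if present.min() == present.max():
            rows.append(
                {"variant": v, "term": "presence", "sum_sq": np.nan, "df": np.nan,
                 "F": np.nan, "p": np.nan, "note": "no contrast; skipped"}
            )
            continue
        table = two_way_anova(values, present, farm)
        for _, r in table.iterrows():
            rows.append(
                {"variant": v, "term": r["term"].replace("genotype", "presence"),
                 "sum_sq": r["sum_sq"], "df": r["df"], "F": r.get("F", np.nan),
                 "p": r.get("p", np.nan), "note": ""}
            )
    return pd.DataFrame(rows)


def levene_test(values, genotype, center: str = "median"):
    """Equality of variance across genotypes (Brown-Forsythe by default).

    ANOVA on absolute deviations from the group centre; ``center`` follows
    :func:`scipy.stats.levene`.  Returns ``(statistic, p)``.
    """
    values = np.asarray(values, float)
    genotype = np.asarray(genotype)
    groups = [values[genotype == g] for g in np.unique(genotype)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    res = stats.levene(*groups, center=center)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------- ICC2
@dataclass
class Icc2Result:
    variable: str
    icc2: float
    ms_rows: float     # between-cow mean square
    ms_cols: float     # between-day mean square
    ms_error: float
    n_cows: int
    k_days: int


def icc2(
    daily: pd.DataFrame,
    variable: str,
    cow_col: str = "cow_id",
    day_col: str = "date",
) -> Icc2Result:
    """Two-way random-effects intraclass correlation (single measure).

    Rows are cows, columns are repeated measurement days.  From the
    two-way decomposition with n cows and k days:

        ICC2 = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    Unbalanced panels are reduced to the largest complete sub-panel: days
    observed for every cow (listwise day alignment).
    """
    wide = daily.pivot_table(index=cow_col, columns=day_col, values=variable)
    wide = wide.dropna(axis=1)  # largest complete sub-panel by day
    n, k = wide.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 cows and >= 2 complete days for ICC2")
    X = wide.to_numpy(float)
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
    return Icc2Result(variable, float(icc), float(ms_r), float(ms_c), float(ms_e), n, k)


# ------------------------------------------------------------- distributions
def distribution_report(
    profiles: pd.DataFrame,
    variables: list[str],
    genotype_col: str = "genotype",
    flag_alpha: float = 0.01,
) -> pd.DataFrame:
    """Skewness, kurtosis and Shapiro-Wilk normality per variable x genotype.

    Rows with genotype ``"(all)"`` pool every cow.  ``flagged`` marks
    variable/genotype combinations whose Shapiro-Wilk p falls below
    ``flag_alpha`` (transform failed to normalize).
    """
    rows = []
    groups = [("(all)", profiles)] + [
        (g, grp) for g, grp in profiles.groupby(genotype_col, sort=True)
    ]
    for g, grp in groups:
        for v in variables:
            x = grp[v].dropna().to_numpy(float)
            if len(x) < 3:
                continue
            if np.ptp(x) == 0:
                sw_p = np.nan
            else:
                sw_p = float(stats.shapiro(x).pvalue)
            rows.append(
                {
                    "variable": v,
                    "genotype": g,
                    "n": len(x),
                    "skewness": float(stats.skew(x, bias=False)) if len(x) > 2 else np.nan,
                    "kurtosis": float(stats.kurtosis(x, bias=False)) if len(x) > 3 else np.nan,
                    "shapiro_p": sw_p,
                    "flagged": bool(sw_p < flag_alpha) if np.isfinite(sw_p) else False,
                }
            )
    out = pd.DataFrame(rows)
    out["p_lt_0.1"] = out["shapiro_p"] < 0.1
    out["p_lt_0.05"] = out["shapiro_p"] < 0.05
    return out
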