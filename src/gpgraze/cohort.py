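"""Balanced cohort construction by under-sampling.

Unbalanced genotype cohorts compromise discriminant classifiers, so the
training set is built by randomly discarding cows from over-represented
genotype x farm cells until every cell holds the same number of cows
(four per cell over four farms and five genotypes gives the canonical
80-cow training roster, 16 per genotype).  Genotypes rarer than a 5%
frequency floor are excluded up front.  Cows flagged as multivariate
outliers (robust Mahalanobis distance from a minimum-covariance-determinant
fit against a chi-square quantile) are removed before sampling.  Remaining
eligible cows form the unbalanced testing set.  Missing profile cells are
completed by iterative low-rank (SVD) imputation with a cross-validated
rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from sklearn.decomposition import PCA

__all__ = [
    "CohortDesign",
    "detect_multivariate_outliers",
    "screen_outliers_within_genotype",
    "build_training_set",
    "build_testing_set",
    "impute_missing",
]


@dataclass
class CohortDesign:
    """Training/testing rosters plus screening and imputation bookkeeping."""

    training: pd.DataFrame = None
    testing: pd.DataFrame = None
    outliers: list = field(default_factory=list)
    seed: int | None = None
    imputation_log: pd.DataFrame = None

    def roster(self) -> pd.DataFrame:
        """Single roster table: ``cow_id, role, genotype, farm_id``."""
        frames = []
        for role, df in (("train", self.training), ("test", self.testing)):
            if df is not None and len(df):
                frames.append(
                    df[["cow_id", "genotype", "farm_id"]].assign(role=role)
                )
        out = pd.concat(frames, ignore_index=True)
        return out[["cow_id", "role", "genotype", "farm_id"]]


def detect_multivariate_outliers(
    profiles: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.01,
    n_components: int | None = None,
    seed: int | None = 0,
    support_fraction: float = 0.9,
) -> list[str]:
    """Flag cows whose robust squared Mahalanobis distance is extreme.

    Robust location/scatter come from a minimum-covariance-determinant
    subset search (with its standard reweighting step); squared distances
    are compared with the ``1 - alpha`` chi-square quantile at the working
    dimension.  ``n_components`` optionally reduces the variable block by
    PCA first, which keeps the scatter estimable when cows are scarce
    relative to the 35 variables.  ``support_fraction`` sets the assumed
    clean fraction; the 0.9 default targets individual anomalies and keeps
    a genuine minority class (e.g. a 20% genotype with a distinct
    phenotype) from being swallowed whole by the screen.
    """
    X = profiles[variables].to_numpy(float)
    if np.isnan(X).any():
        # median-fill for screening only; imputation proper happens later
        med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), med, X)
    if n_components is not None and n_components < X.shape[1]:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        X = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    n, d = X.shape
    if n < d + 2:
        raise ValueError(
            f"need at least d+2={d + 2} cows for {d} variables, got {n}; "
            "reduce the variable set or use n_components"
        )
    mcd = MinCovDet(random_state=seed, support_fraction=support_fraction).fit(X)
    if np.linalg.matrix_rank(mcd.covariance_) < d:
        raise ValueError(
            "singular robust scatter; reduce the variable set or use n_components"
        )
    d2 = mcd.mahalanobis(X)
    # rescale so the distance median matches its chi-square median: corrects
    # the scale inflation of raw MCD distances in small samples
    med = np.median(d2)
    if med > 0:
        d2 = d2 * stats.chi2.ppf(0.5, d) / med
    cut = stats.chi2.ppf(1 - alpha, d)
    flagged = profiles["cow_id"].to_numpy()[d2 > cut]
    return list(flagged)


def screen_outliers_within_genotype(
    profiles: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.01,
    n_components: int | None = 5,
    seed: int | None = 0,
    support_fraction: float = 0.9,
) -> list[str]:
    """Outlier screen respecting the genotype x farm design structure.

    In a cohort where genotype differences (in location *and* scale - the
    quadratic-discriminant setting) are the signal under study, a single
    robust scatter mistakes genuinely distinct genotype clusters for
    contamination.  This screen therefore (1) removes the genotype x farm
    cell location (cell medians), then (2) runs the MCD distance screen of
    :func:`detect_multivariate_outliers` separately per genotype, so each
    cow is judged against its own genotype's scatter.
    """
    X = profiles[variables].to_numpy(float)
    med = np.nanmedian(X, axis=0)
    X = np.where(np.isnan(X), med, X)
    cells = (profiles["genotype"].astype(str) + "/" + profiles["farm_id"].astype(str)).to_numpy()
    R = X.copy()
    for cell in np.unique(cells):
        mask = cells == cell
        R[mask] = X[mask] - np.median(X[mask], axis=0)
    flagged: list[str] = []
    geno = profiles["genotype"].to_numpy()
    for g in np.unique(geno):
        mask = geno == g
        sub = pd.DataFrame(R[mask], columns=variables)
        sub.insert(0, "cow_id", profiles["cow_id"].to_numpy()[mask])
        flagged.extend(
            detect_multivariate_outliers(
                sub, variables, alpha=alpha, n_components=n_components,
                seed=seed, support_fraction=support_fraction,
            )
        )
    return sorted(flagged)


def build_training_set(
    profiles: pd.DataFrame,
    per_cell: int = 4,
    genotype_floor: float = 0.05,
    seed: int | None = 0,
    outliers: list[str] | None = None,
) -> CohortDesign:
    """Uniform random under-sample of ``per_cell`` cows per genotype x farm.

    Genotypes below ``genotype_floor`` frequency (over all profiled cows)
    are excluded before sampling; flagged outlier cows are never sampled.
    Raises with the list of deficient cells if any retained genotype x farm
    cell holds fewer than ``per_cell`` eligible cows.
    """
    outliers = set(outliers or [])
    freq = profiles["genotype"].value_counts(normalize=True)
    retained_genotypes = sorted(freq.index[freq > genotype_floor])
    eligible = profiles.loc[
        profiles["genotype"].isin(retained_genotypes)
        & ~profiles["cow_id"].isin(outliers)
    ]
    rng = np.random.default_rng(seed)
    picks = []
    deficient = []
    farms = sorted(eligible["farm_id"].unique())
    for g in retained_genotypes:
        for f in farms:
            cell = eligible.loc[
                (eligible["genotype"] == g) & (eligible["farm_id"] == f)
            ].sort_values("cow_id")
            if len(cell) < per_cell:
                deficient.append((g, f, len(cell)))
                continue
            idx = rng.choice(len(cell), size=per_cell, replace=False)
            picks.append(cell.iloc[np.sort(idx)])
    if deficient:
        raise ValueError(
            f"under-filled genotype x farm cells (need {per_cell}): {deficient}"
        )
    training = pd.concat(picks, ignore_index=True)
    return CohortDesign(training=training, outliers=sorted(outliers), seed=seed)


def build_testing_set(
    profiles: pd.DataFrame, design: CohortDesign
) -> CohortDesign:
    """All eligible cows not in training, restricted to retained genotypes.

    Genotypes absent from the remaining pool are reported in the design's
    ``missing_test_genotypes`` attribute rather than silently dropped.
    """
    train_ids = set(design.training["cow_id"])
    genotypes = sorted(design.training["genotype"].unique())
    outliers = set(design.outliers)
    testing = profiles.loc[
        profiles["genotype"].isin(genotypes)
        & ~profiles["cow_id"].isin(train_ids)
        & ~profiles["cow_id"].isin(outliers)
    ].reset_index(drop=True)
    design.testing = testing
    design.missing_test_genotypes = [
        g for g in genotypes if g not in set(testing["genotype"])
    ]
    return design


def impute_missing(
    profiles: pd.DataFrame,
    variables: list[str],
    max_rank: int = 5,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_missing_fraction: float = 0.2,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative low-rank (EM-PCA) imputation of missing profile cells.

    Columns are scaled, missing cells start at the column mean, and each
    sweep refits column means plus a rank-``r`` principal-component
    reconstruction of the centred matrix and refills the missing cells,
    until the filled values change by less than ``tol`` (RMS) or
    ``max_iter`` sweeps.  The rank is chosen by holding out 10% of the
    observed cells and picking the rank with the lowest reconstruction
    error.  Returns the completed table and a log of every imputed cell.
    """
    X = profiles[variables].to_numpy(float).copy()
    mask = np.isnan(X)
    if not mask.any():
        return profiles.copy(), pd.DataFrame(columns=["cow_id", "variable", "value"])
    frac = mask.mean(axis=0)
    if (frac >= 1.0).any():
        bad = [v for v, f in zip(variables, frac) if f >= 1.0]
        raise ValueError(f"variables entirely missing: {bad}")
    if (frac > max_missing_fraction).any():
        bad = [v for v, f in zip(variables, frac) if f > max_missing_fraction]
        raise ValueError(
            f"missingness above {max_missing_fraction:.0%} for: {bad}"
        )
    sd = np.nanstd(X, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = X / sd

    ranks = range(1, min(max_rank, min(Z.shape) - 1) + 1)
    rng = np.random.default_rng(seed)
    obs = np.flatnonzero(~mask.ravel())
    holdout = rng.choice(obs, size=max(1, obs.size // 10), replace=False)
    hold_mask = np.zeros(Z.size, dtype=bool)
    hold_mask[holdout] = True
    hold_mask = hold_mask.reshape(Z.shape)

    def _complete(Zin, miss, rank):
        W = Zin.copy()
        col_mean = np.nanmean(np.where(miss, np.nan, W), axis=0)
        W[miss] = np.broadcast_to(col_mean, W.shape)[miss]
        prev = W[miss]
        for _ in range(max_iter):
            mu_it = W.mean(axis=0)
            U, s, Vt = np.linalg.svd(W - mu_it, full_matrices=False)
            recon = (U[:, :rank] * s[:rank]) @ Vt[:rank] + mu_it
            W[miss] = recon[miss]
            delta = np.sqrt(np.mean((W[miss] - prev) ** 2)) if miss.any() else 0.0
            if delta < tol:
                break
            prev = W[miss].copy()
        return W

    errors = {}
    cv_miss = mask | hold_mask
    for r in ranks:
        Wr = _complete(Z, cv_miss, r)
        errors[r] = float(np.mean((Wr[hold_mask] - Z[hold_mask]) ** 2))
    best = min(errors, key=errors.get)
    Zfull = _complete(Z, mask, best)

    Xfull = Zfull * sd
    out = profiles.copy()
    log_rows = []
    cow_ids = profiles["cow_id"].to_numpy()
    for j, var in enumerate(variables):
        rows = np.flatnonzero(mask[:, j])
        if rows.size:
            out.loc[out.index[rows], var] = Xfull[rows, j]
            for i in rows:
                log_rows.append(
                    {"cow_id": cow_ids[i], "variable": var, "value": Xfull[i, j]}
                )
    log = pd.DataFrame(log_rows)
    log.attrs["rank"] = best
    return out, log
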