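"""Discriminant modelling of genotype classes from behaviour profiles.

The model-building procedure is: standardize the training variables
(centre/scale learned on training data only), rank variables by their pooled
canonical LDA scores in a backward stepwise elimination (a tentative drop of
the lowest-scoring variable is kept iff resubstitution accuracy does not
decrease), screen the survivors for multicollinearity (VIF < 10), test
covariance homogeneity with Box's M, and fit the final classifier - quadratic
discriminant analysis when Box's M rejects homogeneity (class-specific
Gaussian covariances), linear otherwise.

The public surface follows the statsmodels Model/Results convention:
:class:`GenotypeDiscriminant` is built from a profile table and
``fit()`` returns a :class:`DiscriminantResults` carrying the fitted
parameters, the selection trace, diagnostics, confusion matrices and a
``summary()`` table.

Notation: for class k with mean vector mu_k, covariance Sigma_k and prior
pi_k, the quadratic discriminant is

    delta_k(x) = -1/2 ln|Sigma_k| - 1/2 (x - mu_k)' Sigma_k^{-1} (x - mu_k)
                 + ln pi_k

and a point is assigned to the class with the largest delta_k (ties broken
toward the lowest class label).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "StandardizationParams",
    "standardize",
    "LdaFit",
    "fit_lda",
    "lda_classify",
    "compute_vif",
    "backward_stepwise_select",
    "boxm_test",
    "QdaModel",
    "fit_qda",
    "ConfusionMatrix",
    "evaluate",
    "GenotypeDiscriminant",
    "DiscriminantResults",
]


# ------------------------------------------------------------ standardization
@dataclass
class StandardizationParams:
    """Per-variable centre and scale learned on the training data."""

    variables: list
    centre: np.ndarray
    scale: np.ndarray

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [v for v in self.variables if v not in table.columns]
        if missing:
            raise ValueError(f"variables missing from table: {missing}")
        out = table.copy()
        out[self.variables] = (
            table[self.variables].to_numpy(float) - self.centre
        ) / self.scale
        return out


def standardize(
    train: pd.DataFrame,
    test: pd.DataFrame | None,
    variables: list[str],
    with_scale: bool = True,
):
    """Centre (and scale) training columns; transform test with the same
    parameters.  A zero-variance training column raises, naming it."""
    X = train[variables].to_numpy(float)
    centre = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sd) if not np.isfinite(s) or s == 0]
    if zero:
        raise ValueError(f"zero-variance training column(s): {zero}")
    scale = sd if with_scale else np.ones_like(sd)
    params = StandardizationParams(list(variables), centre, scale)
    return (
        params.transform(train),
        params.transform(test) if test is not None else None,
        params,
    )


# ----------------------------------------------------------------------- LDA
@dataclass
class LdaFit:
    """Canonical discriminant axes and per-variable pooled scores."""

    classes: list
    variables: list
    coefficients: np.ndarray   # (d, n_axes), within-class variance of scores = 1
    eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coefficients.shape[1]

    @property
    def pooled_scores(self) -> pd.Series:
        """Per variable: sum of absolute canonical coefficients over axes."""
        return pd.Series(
            np.abs(self.coefficients).sum(axis=1), index=self.variables
        )

    @property
    def proportion_of_variation(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    N, d = X.shape
    G = len(classes)
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        nc = len(Xc)
        if nc > 1:
            Sw += (nc - 1) * np.cov(Xc, rowvar=False)
        diff = (Xc.mean(axis=0) - grand)[:, None]
        Sb += nc * (diff @ diff.T)
    return Sw / (N - G), Sb / max(G - 1, 1), classes


def fit_lda(scaled: pd.DataFrame, labels, variables: list[str]) -> LdaFit:
    """Canonical LDA: generalized eigenproblem of between vs within scatter.

    Axes are ordered by decreasing eigenvalue; the axis count is
    ``min(G - 1, d)``.  Coefficients are scaled so the pooled within-class
    variance of each canonical score is 1, with the sign fixed so the first
    nonzero coefficient of each axis is positive.
    """
    X = scaled[list(variables)].to_numpy(float)
    y = np.asarray(labels)
    Sw, Sb, classes = _scatter_matrices(X, y)
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError:
        warnings.warn("singular within-class scatter; ridge-regularizing")
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
    return LdaFit(list(classes), list(variables), A, evals)


def lda_classify(
    scaled: pd.DataFrame,
    labels,
    variables: list[str],
    newdata: pd.DataFrame | None = None,
    priors: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian classification with a pooled covariance (linear rule)."""
    X = scaled[list(variables)].to_numpy(float)
    y = np.asarray(labels)
    Sw, _, classes = _scatter_matrices(X, y)
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    Xnew = (newdata if newdata is not None else scaled)[list(variables)].to_numpy(float)
    try:
        Swi = linalg.inv(Sw)
    except linalg.LinAlgError:
        Swi = linalg.pinv(Sw)
    scores = np.empty((len(Xnew), len(classes)))
    for k, c in enumerate(classes):
        mu = X[y == c].mean(axis=0)
        scores[:, k] = (
            Xnew @ Swi @ mu - 0.5 * mu @ Swi @ mu + np.log(priors[k])
        )
    return classes[np.argmax(scores, axis=1)]


# ----------------------------------------------------------------------- VIF
def compute_vif(scaled: pd.DataFrame, variables: list[str]) -> pd.Series:
    """Variance inflation factor per variable: 1 / (1 - R^2_j).

    Perfect collinearity is reported as ``inf`` rather than raising.
    """
    if len(variables) < 2:
        return pd.Series(1.0, index=list(variables))
    X = np.column_stack(
        [scaled[list(variables)].to_numpy(float), np.ones(len(scaled))]
    )
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(len(variables)):
            try:
                v = variance_inflation_factor(X, j)
            except Exception:
                v = np.inf
            vals.append(np.inf if not np.isfinite(v) else v)
    return pd.Series(vals, index=list(variables))


# ------------------------------------------------------------------ stepwise
def backward_stepwise_select(
    scaled: pd.DataFrame,
    labels,
    variables: list[str] | None = None,
    vif_max: float = 10.0,
    vif_overrides: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Backward stepwise variable selection guided by pooled LDA scores.

    Starting from all variables, repeatedly (1) fit the canonical LDA and
    compute pooled scores, (2) tentatively drop variables in ascending
    pooled-score order, (3) accept the first drop under which the
    resubstitution accuracy of the working (linear) classifier does not
    decrease - a tie favours parsimony; a variable whose removal costs
    accuracy is kept.  The round restarts after every accepted drop
    (scores are recomputed) and the score phase converges when no variable
    can be removed.  Then variables exceeding ``vif_max`` are
    removed highest-VIF-first (``vif_overrides`` lists analyst-accepted
    exceptions that are never dropped for VIF).  Pooled-score ties break by
    variable name order.  Returns ``(trace, final variable list)``.
    """
    if variables is None:
        variables = [c for c in scaled.columns if c not in ("cow_id", "farm_id", "genotype", "n_days")]
    current = list(variables)
    if not current:
        raise ValueError("no variables to select from")
    y = np.asarray(labels)
    overrides = set(vif_overrides or [])
    trace = []
    step = 0

    def _acc(vs):
        pred = lda_classify(scaled, y, vs)
        return float(np.mean(pred == y))

    acc = _acc(current)
    fit = fit_lda(scaled, y, current)
    trace.append(
        {"step": step, "action": "start", "variable": "", "n_variables": len(current),
         "accuracy": acc, "pooled_score": np.nan}
    )
    if len(current) == 1:
        return pd.DataFrame(trace), current
    while len(current) > 1:
        fit = fit_lda(scaled, y, current)
        scores = fit.pooled_scores
        # ascending pooled score; ties break by variable name order
        order = sorted(current, key=lambda v: (scores[v], v))
        dropped = False
        for cand_var in order:
            candidate = [v for v in current if v != cand_var]
            cand_acc = _acc(candidate)
            step += 1
            if cand_acc >= acc:
                current = candidate
                acc = cand_acc
                trace.append(
                    {"step": step, "action": "drop_score", "variable": cand_var,
                     "n_variables": len(current), "accuracy": acc,
                     "pooled_score": float(scores[cand_var])}
                )
                dropped = True
                break
            trace.append(
                {"step": step, "action": "keep", "variable": cand_var,
                 "n_variables": len(current), "accuracy": acc,
                 "pooled_score": float(scores[cand_var])}
            )
        if not dropped:
            break
    # multicollinearity stage
    while len(current) > 1:
        vif = compute_vif(scaled, current)
        candidates = vif.drop(index=[v for v in overrides if v in vif.index])
        if not len(candidates) or candidates.max() < vif_max:
            break
        worst = candidates.sort_index().idxmax()
        current = [v for v in current if v != worst]
        acc = _acc(current)
        step += 1
        trace.append(
            {"step": step, "action": "drop_vif", "variable": worst,
             "n_variables": len(current), "accuracy": acc,
             "pooled_score": float(candidates.max())}
        )
    if not current:
        raise ValueError("all variables eliminated; degenerate inputs")
    return pd.DataFrame(trace), current


# -------------------------------------------------------------------- Box M
def boxm_test(
    scaled: pd.DataFrame, labels, variables: list[str]
) -> tuple[float, int, float]:
    """Box's M test of covariance homogeneity across classes.

    M = (N - G) ln|S_pooled| - sum_k (n_k - 1) ln|S_k| with the standard
    chi-square approximation (Box's correction factor); returns
    ``(statistic, df, p_value)``.  The statistic is the corrected
    chi-square.  Requires every class to have more observations than
    variables.
    """
    X = scaled[list(variables)].to_numpy(float)
    y = np.asarray(labels)
    classes = np.unique(y)
    d = X.shape[1]
    N = len(X)
    G = len(classes)
    Sp = np.zeros((d, d))
    logdets = {}
    ns = {}
    for c in classes:
        Xc = X[y == c]
        if len(Xc) <= d:
            raise ValueError(
                f"class {c!r} has n={len(Xc)} <= d={d}; covariance not estimable"
            )
        S = np.cov(Xc, rowvar=False)
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError(f"singular covariance for class {c!r}")
        logdets[c] = ld
        ns[c] = len(Xc)
        Sp += (len(Xc) - 1) * S
    Sp /= N - G
    sign, ldp = np.linalg.slogdet(Sp)
    if sign <= 0:
        raise ValueError("singular pooled covariance")
    M = (N - G) * ldp - sum((ns[c] - 1) * logdets[c] for c in classes)
    c1 = (
        (sum(1.0 / (ns[c] - 1) for c in classes) - 1.0 / (N - G))
        * (2 * d**2 + 3 * d - 1)
        / (6.0 * (d + 1) * (G - 1))
    )
    chi2 = M * (1 - c1)
    df = d * (d + 1) * (G - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


# ----------------------------------------------------------------------- QDA
@dataclass
class QdaModel:
    """Per-class Gaussian parameters of a quadratic discriminant model."""

    classes: list
    variables: list
    means: dict
    covariances: dict
    priors: dict
    shrinkage: dict = field(default_factory=dict)
    pooled: bool = False  # True => linear rule (shared covariance)

    def discriminants(self, table: pd.DataFrame) -> pd.DataFrame:
        X = table[list(self.variables)].to_numpy(float)
        out = np.empty((len(X), len(self.classes)))
        if self.pooled:
            Sp = sum(
                (np.asarray(self.covariances[c]) for c in self.classes),
                start=np.zeros((len(self.variables),) * 2),
            ) / len(self.classes)
            cov = {c: Sp for c in self.classes}
        else:
            cov = {c: np.asarray(self.covariances[c]) for c in self.classes}
        for k, c in enumerate(self.classes):
            S = cov[c]
            mu = np.asarray(self.means[c])
            L = linalg.cholesky(S, lower=True)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            sol = linalg.solve_triangular(L, (X - mu).T, lower=True)
            maha = (sol**2).sum(axis=0)
            out[:, k] = -0.5 * logdet - 0.5 * maha + np.log(self.priors[c])
        return pd.DataFrame(out, columns=self.classes, index=table.index)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Class with the largest discriminant; ties go to the lowest label
        (classes are stored sorted, argmax returns the first maximum)."""
        d = self.discriminants(table)
        return d.columns.to_numpy()[np.argmax(d.to_numpy(), axis=1)]


def fit_qda(
    scaled: pd.DataFrame,
    labels,
    variables: list[str],
    priors: dict | None = None,
    max_condition: float = 1e10,
) -> QdaModel:
    """Fit per-class Gaussian parameters (class-specific covariances).

    Default priors are equal, matching a deliberately balanced training
    design.  An ill-conditioned class covariance is shrunk toward its
    diagonal until the condition number is acceptable (logged in
    ``shrinkage`` and warned about).
    """
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    if priors is None:
        priors = {c: 1.0 / len(classes) for c in classes}
    total = sum(priors.values())
    priors = {c: p / total for c, p in priors.items()}
    means, covs, shrink = {}, {}, {}
    for c in classes:
        Xc = scaled.loc[y == c, list(variables)].to_numpy(float)
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 observations")
        means[c] = Xc.mean(axis=0)
        S = np.cov(Xc, rowvar=False)
        S = np.atleast_2d(S)
        lam = 0.0
        while np.linalg.cond(S) > max_condition or np.any(
            np.linalg.eigvalsh(S) <= 0
        ):
            lam = max(2 * lam, 1e-4)
            S = (1 - lam) * np.atleast_2d(np.cov(Xc, rowvar=False)) + lam * np.diag(
                np.diag(np.atleast_2d(np.cov(Xc, rowvar=False)))
            ) + lam * 1e-8 * np.eye(S.shape[0])
            if lam >= 1:
                break
        if lam > 0:
            warnings.warn(f"ill-conditioned covariance for class {c!r}; shrunk (lambda={lam:g})")
            shrink[c] = lam
        covs[c] = S
    return QdaModel(classes, list(variables), means, covs, priors, shrink)


# ---------------------------------------------------------------- evaluation
@dataclass
class ConfusionMatrix:
    """G x G confusion counts with per-class recall and overall accuracy."""

    table: pd.DataFrame  # rows = true class, columns = predicted
    tag: str

    @property
    def accuracy(self) -> float:
        m = self.table.to_numpy()
        return float(np.trace(m) / m.sum())

    @property
    def per_class_recall(self) -> pd.Series:
        m = self.table.to_numpy(float)
        with np.errstate(invalid="ignore"):
            return pd.Series(np.diag(m) / m.sum(axis=1), index=self.table.index)


def _confusion(y_true, y_pred, classes, tag) -> ConfusionMatrix:
    table = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(y_true, y_pred):
        table.loc[t, p] += 1
    return ConfusionMatrix(table, tag)


def evaluate(
    model: QdaModel,
    train: pd.DataFrame,
    train_labels,
    test: pd.DataFrame | None = None,
    test_labels=None,
) -> tuple[ConfusionMatrix, ConfusionMatrix | None]:
    """Resubstitution confusion on train; prediction confusion on test.

    Test data must already be transformed with the training
    standardization parameters.
    """
    missing = [v for v in model.variables if v not in train.columns]
    if missing:
        raise ValueError(f"variables missing from training table: {missing}")
    resub = _confusion(
        np.asarray(train_labels), model.predict(train), model.classes, "train_resubstitution"
    )
    pred = None
    if test is not None:
        missing = [v for v in model.variables if v not in test.columns]
        if missing:
            raise ValueError(f"variables missing from test table: {missing}")
        pred = _confusion(
            np.asarray(test_labels), model.predict(test), model.classes, "test_prediction"
        )
    return resub, pred


# ------------------------------------------------------- Model/Results shape
class GenotypeDiscriminant:
    """Discriminant model of genotype classes from behaviour profiles.

    Parameters
    ----------
    data : DataFrame
        Training profile table; one row per cow with a label column and the
        candidate behaviour variables.
    variables : list of str, optional
        Candidate variables (default: every numeric column except
        bookkeeping columns).
    label : str
        Name of the class-label column (default ``"genotype"``).

    Examples
    --------
    >>> model = GenotypeDiscriminant.from_dataframe(profiles)
    >>> res = model.fit(select=True, seed=0)
    >>> res.confusion_train.accuracy          # doctest: +SKIP
    >>> print(res.summary())                  # doctest: +SKIP
    """

    _BOOKKEEPING = ("cow_id", "farm_id", "genotype", "role", "n_days")

    def __init__(self, data: pd.DataFrame, variables=None, label="genotype"):
        self.data = data.reset_index(drop=True)
        self.label = label
        if variables is None:
            variables = [
                c
                for c in data.columns
                if c not in self._BOOKKEEPING and pd.api.types.is_numeric_dtype(data[c])
            ]
        self.variables = list(variables)
        self.labels = self.data[label].to_numpy()
        if len(np.unique(self.labels)) < 2:
            raise ValueError("need at least two classes")

    @classmethod
    def from_dataframe(cls, data, variables=None, label="genotype"):
        return cls(data, variables=variables, label=label)

    def fit(
        self,
        select: bool = True,
        method: str = "auto",
        vif_max: float = 10.0,
        vif_overrides=None,
        priors: dict | None = None,
        boxm_alpha: float = 0.05,
    ) -> "DiscriminantResults":
        """Standardize, (optionally) select variables, route via Box's M
        and fit the final discriminant model.

        ``method='auto'`` fits QDA when Box's M rejects covariance
        homogeneity at ``boxm_alpha``, LDA otherwise; ``'qda'``/``'lda'``
        force the rule.
        """
        scaled, _, params = standardize(self.data, None, self.variables)
        if select:
            trace, selected = backward_stepwise_select(
                scaled, self.labels, self.variables, vif_max=vif_max,
                vif_overrides=vif_overrides,
            )
        else:
            trace, selected = None, list(self.variables)
        try:
            boxm = boxm_test(scaled, self.labels, selected)
        except ValueError:
            boxm = (np.nan, 0, np.nan)
        if method == "auto":
            use_qda = not np.isfinite(boxm[2]) or boxm[2] < boxm_alpha
        else:
            use_qda = method == "qda"
        qda = fit_qda(scaled, self.labels, selected, priors=priors)
        qda.pooled = not use_qda
        lda_fit = fit_lda(scaled, self.labels, selected)
        vif = compute_vif(scaled, selected)
        resub, _ = evaluate(qda, scaled, self.labels)
        return DiscriminantResults(
            model=self,
            standardization=params,
            selected_variables=selected,
            selection_trace=trace,
            boxm=boxm,
            method="qda" if use_qda else "lda",
            qda=qda,
            lda=lda_fit,
            vif=vif,
            confusion_train=resub,
            _scaled_train=scaled,
        )


@dataclass
class DiscriminantResults:
    """Fitted discriminant model with diagnostics and evaluation helpers."""

    model: GenotypeDiscriminant
    standardization: StandardizationParams
    selected_variables: list
    selection_trace: pd.DataFrame | None
    boxm: tuple
    method: str
    qda: QdaModel
    lda: LdaFit
    vif: pd.Series
    confusion_train: ConfusionMatrix
    _scaled_train: pd.DataFrame = None

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        """Predict class labels for raw (untransformed) profile rows."""
        return self.qda.predict(self.standardization.transform(newdata))

    def evaluate(self, test: pd.DataFrame) -> ConfusionMatrix:
        """Prediction confusion matrix on a raw test profile table."""
        scaled = self.standardization.transform(test)
        _, pred = evaluate(
            self.qda,
            self._scaled_train,
            self.model.labels,
            scaled,
            test[self.model.label].to_numpy(),
        )
        return pred

    def class_score_table(self) -> pd.DataFrame:
        """Per-genotype mean of each selected standardized variable.

        One row per selected behaviour, one column per genotype; the values
        are means of centred/scaled data, so each row contrasts the
        genotypes on that behaviour.
        """
        scaled = self._scaled_train
        out = {}
        for c in self.qda.classes:
            mask = self.model.labels == c
            out[c] = scaled.loc[mask, self.selected_variables].mean()
        return pd.DataFrame(out)

    def summary(self) -> str:
        chi2, df, p = self.boxm
        lines = [
            "Genotype discriminant model",
            "=" * 60,
            f"Observations:        {len(self.model.data)}",
            f"Classes:             {', '.join(map(str, self.qda.classes))}",
            f"Candidate variables: {len(self.model.variables)}",
            f"Selected variables:  {len(self.selected_variables)}",
            f"Box's M chi2:        {chi2:.3f} (df={df}, p={p:.4g})",
            f"Final rule:          {self.method.upper()}",
            f"Training accuracy:   {self.confusion_train.accuracy:.1%}",
            "-" * 60,
            f"{'variable':<22}{'pooled score':>14}{'VIF':>10}",
        ]
        scores = self.lda.pooled_scores
        for v in sorted(self.selected_variables, key=lambda v: -scores[v]):
            lines.append(f"{v:<22}{scores[v]:>14.3f}{self.vif[v]:>10.2f}")
        lines.append("=" * 60)
        return "\n".join(lines)

    # --------------------------------------------------------- serialization
    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "method": self.method,
            "classes": list(map(str, self.qda.classes)),
            "variables": list(self.selected_variables),
            "priors": {str(c): self.qda.priors[c] for c in self.qda.classes},
            "means": {str(c): np.asarray(self.qda.means[c]).tolist() for c in self.qda.classes},
            "covariances": {
                str(c): np.asarray(self.qda.covariances[c]).ravel().tolist()
                for c in self.qda.classes
            },
            "standardization": {
                "variables": list(self.standardization.variables),
                "centre": self.standardization.centre.tolist(),
                "scale": self.standardization.scale.tolist(),
            },
            "boxm": {"chi2": self.boxm[0], "df": self.boxm[1], "p": self.boxm[2]},
        }
        return json.dumps(payload, indent=2)

    @staticmethod
    def load_qda(text: str) -> tuple[QdaModel, StandardizationParams]:
        """Rebuild the classifier and standardization from ``to_json`` output."""
        data = json.loads(text)
        d = len(data["variables"])
        qda = QdaModel(
            classes=data["classes"],
            variables=data["variables"],
            means={c: np.asarray(m) for c, m in data["means"].items()},
            covariances={
                c: np.asarray(v).reshape(d, d) for c, v in data["covariances"].items()
            },
            priors=data["priors"],
            pooled=data["method"] == "lda",
        )
        sp = data["standardization"]
        params = StandardizationParams(
            sp["variables"], np.asarray(sp["centre"]), np.asarray(sp["scale"])
        )
        return qda, params
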