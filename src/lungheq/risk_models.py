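"""Logistic risk modelling of lung cancer from emphysema quantification.

Implements the statistical pipeline around the emphysema metrics: univariate
screening (Welch t-test / chi-squared with Yates correction), data-driven
choice of the best HU threshold, four nested logistic models —

* ``base``   — sex + age + smoking history (Brinkman index)
* ``laa``    — base + LAA% at the selected threshold
* ``heq``    — base + b1 at the selected threshold
* ``heq_b``  — base + b1 binarized at a cutoff (default 5100, strict ``>``)

— with AIC, Wald inference, odds ratios, ROC/AUC, DeLong's test for
correlated AUCs, and stratified k-fold cross-validation with pooled
out-of-fold predictions.

Logistic fits are maximum likelihood via iteratively reweighted least squares
(statsmodels GLM with a binomial family; tolerance 1e-8, ≤50 iterations);
standard errors come from the inverse observed information. DeLong's test is
implemented from placement values, as no installed package provides it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ConvergenceError, DegenerateInputError, SchemaError, ValidationError
from .imaging_io import THRESHOLDS, metric_col

MODEL_NAMES = ("base", "laa", "heq", "heq_b")
DEFAULT_B1_CUTOFF = 5100.0
_Z975 = 1.959964  # standard normal 97.5% quantile

_CONTINUOUS_VARS = (
    "age",
    "brinkman_index",
    "lung_area",
    *(metric_col("laa_pct", t) for t in THRESHOLDS),
    *(metric_col("b0", t) for t in THRESHOLDS),
    *(metric_col("b1", t) for t in THRESHOLDS),
)
_CATEGORICAL_VARS = ("sex", "malignant_tumor_history")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningResult:
    """Univariate screening table: one row per screened variable."""

    table: pd.DataFrame  # variable, test_name, p_value, detail, constant_flag

    def p(self, variable: str) -> float:
        rows = self.table.loc[self.table["variable"] == variable, "p_value"]
        if rows.empty:
            raise KeyError(f"variable {variable!r} not screened")
        return float(rows.iloc[0])


@dataclass(frozen=True)
class TermFit:
    name: str
    coefficient: float
    standard_error: float
    wald_p: float


@dataclass(frozen=True)
class ModelFit:
    """One fitted logistic model with everything needed downstream."""

    model_name: str
    terms: tuple[TermFit, ...]        # excludes the intercept
    intercept: TermFit
    aic: float
    log_likelihood: float
    fitted_probability: pd.Series     # indexed by patient_id
    n_used: int
    params: pd.Series = field(repr=False)  # incl. const, for prediction

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"term {name!r} not in model {self.model_name!r}")


@dataclass(frozen=True)
class RocComparison:
    auc_a: float
    auc_b: float
    delong_z: float
    delong_p: float
    covariance: np.ndarray = field(repr=False)  # 2x2 of (auc_a, auc_b)


@dataclass(frozen=True)
class CvResult:
    k: int
    seed: int
    fold_assignment: pd.Series        # patient_id -> fold id
    oof_probability: pd.Series        # pooled out-of-fold probabilities
    auc: float


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def _outcome01(outcome: pd.Series) -> np.ndarray:
    y = outcome.map({"cancer": 1, "benign": 0})
    if y.isna().any():
        raise ValidationError("outcome contains values other than cancer/benign")
    return y.to_numpy(dtype=float)


def screen_univariate(cohort: pd.DataFrame, continuous_test: str = "welch") -> ScreeningResult:
    """Compare every covariate between cancer and benign groups.

    Continuous variables use a two-sample t-test (Welch by default,
    ``continuous_test='student'`` for the pooled-variance variant);
    categorical variables use a chi-squared test with Yates continuity
    correction on the 2×2 table. A variable constant in both groups gets
    p = 1 with a flag rather than a NaN.
    """
    if continuous_test not in ("welch", "student"):
        raise ValidationError("continuous_test must be 'welch' or 'student'")
    y = _outcome01(cohort["outcome"]) == 1
    rows = []
    for var in _CONTINUOUS_VARS:
        if var not in cohort.columns:
            continue
        vals = pd.to_numeric(cohort[var], errors="coerce")
        a = vals[y].dropna()
        b = vals[~y].dropna()
        detail = {
            "mean_cancer": float(a.mean()), "sd_cancer": float(a.std(ddof=1)),
            "mean_benign": float(b.mean()), "sd_benign": float(b.std(ddof=1)),
        }
        constant = a.nunique() <= 1 and b.nunique() <= 1 and (
            a.empty or b.empty or a.iloc[0] == b.iloc[0]
        )
        if constant:
            p = 1.0
        else:
            _, p = stats.ttest_ind(a, b, equal_var=(continuous_test == "student"))
        rows.append((var, f"{continuous_test}_t", float(p), detail, constant))
    for var in _CATEGORICAL_VARS:
        if var not in cohort.columns:
            continue
        tab = pd.crosstab(cohort[var], cohort["outcome"])
        constant = tab.shape[0] < 2
        if constant:
            p = 1.0
        else:
            _, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=True)
        rows.append((var, "chi_squared", float(p), {"table": tab.to_dict()}, constant))
    table = pd.DataFrame(
        rows, columns=["variable", "test_name", "p_value", "detail", "constant_flag"]
    )
    return ScreeningResult(table=table)


def select_best_threshold(screening: ScreeningResult) -> int:
    """Pick the HU threshold whose b1 separates the groups best.

    Minimizes the b1 p-value; ties fall back to the LAA% p-value, then to the
    higher (less negative) HU threshold.
    """
    keys = []
    for t in THRESHOLDS:
        try:
            p_b1 = screening.p(metric_col("b1", t))
            p_laa = screening.p(metric_col("laa_pct", t))
        except KeyError as exc:
            raise SchemaError(f"screening lacks per-threshold columns: {exc}") from exc
        keys.append((p_b1, p_laa, -t))  # -t: higher HU (e.g. -880) wins ties
    best = min(range(len(THRESHOLDS)), key=lambda i: keys[i])
    return THRESHOLDS[best]


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------


def binarize_b1(value, cutoff: float = DEFAULT_B1_CUTOFF):
    """1 iff b1 is strictly larger than the cutoff (default 5100), else 0."""
    arr = np.asarray(value)
    if (arr < 0).any():
        raise ValidationError("b1 must be non-negative")
    out = (arr > cutoff).astype(int)
    return out if arr.ndim else int(out)


def model_terms(
    model_name: str, threshold_hu: int = -880, b1_cutoff: float = DEFAULT_B1_CUTOFF
) -> list[str]:
    base = ["sex_male", "age", "brinkman_index"]
    if model_name == "base":
        return base
    if model_name == "laa":
        return base + [metric_col("laa_pct", threshold_hu)]
    if model_name == "heq":
        return base + [metric_col("b1", threshold_hu)]
    if model_name == "heq_b":
        return base + [metric_col("b1", threshold_hu) + "_bin"]
    raise ValidationError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")


def _design(
    cohort: pd.DataFrame,
    model_name: str,
    threshold_hu: int,
    b1_cutoff: float,
) -> tuple[pd.DataFrame, np.ndarray, pd.Index]:
    """Design matrix (with const), outcome vector, and the patient_id index used."""
    terms = model_terms(model_name, threshold_hu, b1_cutoff)
    df = cohort.copy()
    df["sex_male"] = (df["sex"] == "male").astype(float)
    b1_col = metric_col("b1", threshold_hu)
    if model_name == "heq_b":
        if b1_col not in df.columns:
            raise SchemaError(f"cohort lacks column {b1_col}")
        df[b1_col + "_bin"] = binarize_b1(df[b1_col].to_numpy(), b1_cutoff)
    missing = [c for c in terms if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort lacks model columns: {missing}")
    usable = df["outcome"].notna()
    if "complete_for_modelling" in df.columns:
        usable &= df["complete_for_modelling"]
    for c in terms:
        usable &= pd.to_numeric(df[c], errors="coerce").notna()
    df = df[usable]
    X = sm.add_constant(df[terms].astype(float), has_constant="add")
    y = _outcome01(df["outcome"])
    return X, y, pd.Index(df["patient_id"])


def _irls_fit(X: pd.DataFrame, y: np.ndarray, model_name: str):
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome has a single class; cannot fit")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=50, tol=1e-8)
    except Exception as exc:
        raise ConvergenceError(f"{model_name}: IRLS failed: {exc}") from exc
    bse = np.asarray(res.bse)
    if not getattr(res, "converged", True) or not np.isfinite(bse).all():
        worst = res.params.abs().idxmax()
        raise ConvergenceError(
            f"{model_name}: fit did not converge (suspect term {worst!r}; "
            "possible separation)"
        )
    return res


def fit_logistic(
    cohort: pd.DataFrame,
    model_name: str,
    threshold_hu: int = -880,
    b1_cutoff: float = DEFAULT_B1_CUTOFF,
) -> ModelFit:
    """Fit one of the four risk models by maximum likelihood (IRLS).

    Rows with missing modelling covariates are excluded (they were flagged at
    ingestion); coefficients are reported on the natural scale, unstandardized,
    with an intercept always included.
    """
    X, y, ids = _design(cohort, model_name, threshold_hu, b1_cutoff)
    res = _irls_fit(X, y, model_name)
    terms = tuple(
        TermFit(name, float(res.params[name]), float(res.bse[name]), float(res.pvalues[name]))
        for name in X.columns
        if name != "const"
    )
    intercept = TermFit(
        "const", float(res.params["const"]), float(res.bse["const"]), float(res.pvalues["const"])
    )
    fitted = pd.Series(np.asarray(res.fittedvalues), index=ids, name="probability")
    return ModelFit(
        model_name=model_name,
        terms=terms,
        intercept=intercept,
        aic=float(res.aic),
        log_likelihood=float(res.llf),
        fitted_probability=fitted,
        n_used=len(y),
        params=res.params,
    )


def odds_ratio(fit: ModelFit, term: str) -> tuple[float, float, float]:
    """Odds ratio and 95% Wald CI for one model term: exp(coef ± 1.96·SE)."""
    t = fit.term(term)
    return (
        float(np.exp(t.coefficient)),
        float(np.exp(t.coefficient - _Z975 * t.standard_error)),
        float(np.exp(t.coefficient + _Z975 * t.standard_error)),
    )


def find_b1_cutoff(cohort: pd.DataFrame, threshold_hu: int = -880) -> float:
    """Exploratory grid search for a b1 cutoff maximizing Youden's J.

    Provided for sensitivity analyses only; reproduction runs use the fixed
    default cutoff.
    """
    col = metric_col("b1", threshold_hu)
    y = _outcome01(cohort["outcome"])
    fpr, tpr, thr = roc_curve(y, cohort[col].to_numpy())
    j = tpr - fpr
    best = int(np.argmax(j))
    return float(thr[best])


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


def roc_auc(probabilities, outcomes) -> float:
    """AUC by the Mann–Whitney estimator (ties count 1/2)."""
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("need at least one case and one control")
    return float(roc_auc_score(y, p))


def _placement_values(scores: np.ndarray, y: np.ndarray):
    x = scores[y == 1]
    w = scores[y == 0]
    psi = (x[:, None] > w[None, :]).astype(float) + 0.5 * (x[:, None] == w[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def delong_test(scores_a, scores_b, outcomes) -> RocComparison:
    """Paired DeLong test on two score vectors over the same patients."""
    y = np.asarray(outcomes, dtype=float)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise DegenerateInputError("score vectors and outcomes differ in length")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("need at least one case and one control")
    v10a, v01a, auc_a = _placement_values(a, y)
    v10b, v01b, auc_b = _placement_values(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 1e-15:
        z = 0.0
        p = 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = 2 * stats.norm.sf(abs(z))
    return RocComparison(
        auc_a=float(auc_a), auc_b=float(auc_b),
        delong_z=float(z), delong_p=float(p), covariance=cov,
    )


def delong_compare(fit_a: ModelFit, fit_b: ModelFit, outcomes: pd.Series) -> RocComparison:
    """DeLong comparison of two fitted models on their (shared) patients.

    ``outcomes`` is indexed by patient_id with values cancer/benign.
    """
    ids_a, ids_b = fit_a.fitted_probability.index, fit_b.fitted_probability.index
    if not ids_a.equals(ids_b):
        raise DegenerateInputError(
            f"models predict different patient sets "
            f"({fit_a.model_name}: n={len(ids_a)}, {fit_b.model_name}: n={len(ids_b)})"
        )
    y = _outcome01(outcomes.loc[ids_a])
    return delong_test(
        fit_a.fitted_probability.to_numpy(), fit_b.fitted_probability.to_numpy(), y
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def crossvalidate(
    cohort: pd.DataFrame,
    model_name: str,
    k: int = 10,
    seed: int = 0,
    threshold_hu: int = -880,
    b1_cutoff: float = DEFAULT_B1_CUTOFF,
) -> CvResult:
    """Stratified k-fold CV with pooled out-of-fold predictions.

    Folds are drawn stratified by outcome from ``seed``; each fold's model is
    refit on the remaining folds and predicts its held-out patients. A single
    ROC/AUC is computed from the pooled out-of-fold probabilities, which
    yields patient-level predictions suitable for DeLong comparisons.
    """
    if k < 2:
        raise ValidationError("k must be ≥ 2")
    X, y, ids = _design(cohort, model_name, threshold_hu, b1_cutoff)
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise DegenerateInputError("too few patients per class for the requested k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    folds = np.full(len(y), -1)
    for fold_id, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise DegenerateInputError(f"fold {fold_id}: training split has one class")
        res = _irls_fit(X.iloc[tr], y[tr], f"{model_name}[fold {fold_id}]")
        oof[te] = res.predict(X.iloc[te])
        folds[te] = fold_id
    return CvResult(
        k=k,
        seed=seed,
        fold_assignment=pd.Series(folds, index=ids, name="fold"),
        oof_probability=pd.Series(oof, index=ids, name="oof_probability"),
        auc=roc_auc(oof, y),
    )
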