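"""CVD risk prediction harness.

Implements the three predictor sets (Framingham, diet, food-preference
profile), k-nearest-neighbour multiple imputation, and the evaluation
protocol: per imputed dataset a stratified 70/30 train/test split,
10-fold stratified cross-validation on the training portion (used both
for fold-level metrics and to choose the classification threshold that
maximises accuracy), final metrics on the held-out 30%, and pooling of
metrics across imputations by averaging.

Model families are the four standard classifiers: logistic regression,
linear discriminant analysis, random forest and support vector machine
(with Platt-style probability calibration).  The fitted model exposes a
per-person CVD probability for the recommendation engine, and per-profile
logistic coefficients of the six level-2 nutrients feed the
required-change calculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import PROFILES

MODEL_FAMILIES = ("logreg", "lda", "rf", "svm")

#: Column groups used to assemble predictor sets.
_FRAMINGHAM_CONT = ["age", "sex", "sbp", "dbp", "total_chol", "hdl", "bmi", "wc"]
_DIET_CONT = ["energy_kj", "protein_g", "fat_g", "carbohydrate_g",
              "alcohol_g", "fiber_g", "age", "sex", "bmi", "wc"]
_FPP_CONT = ["age", "sex", "bmi", "wc"]
_BASE_CAT = ["smoking", "htn_treatment", "htn_history"]

LEVEL2_NUTRIENTS = ["energy_kj", "protein_g", "sfa_g", "tfa_g", "omega3_g", "omega6_g"]


@dataclass(frozen=True)
class PredictorSpec:
    """A named predictor set.  The Framingham set carries the clinical
    measurements; the diet set swaps blood/BP measures for average daily
    nutrient intakes; the FPP set uses only non-blood measures plus the
    food-preference profile."""

    name: str
    continuous: tuple[str, ...]
    categorical: tuple[str, ...]


PREDICTOR_SPECS: dict[str, PredictorSpec] = {
    "framingham": PredictorSpec("framingham", tuple(_FRAMINGHAM_CONT), tuple(_BASE_CAT)),
    "diet": PredictorSpec("diet", tuple(_DIET_CONT), tuple(_BASE_CAT)),
    "fpp": PredictorSpec("fpp", tuple(_FPP_CONT), tuple(_BASE_CAT) + ("profile",)),
}


def build_predictor_set(records: pd.DataFrame, spec: PredictorSpec | str) -> pd.DataFrame:
    """Assemble the design table for a predictor set.

    Categorical columns are one-hot encoded (all levels kept; downstream
    models are regularised or scale-invariant).  Raises a ``KeyError``
    naming the first missing required column.
    """
    if isinstance(spec, str):
        spec = PREDICTOR_SPECS[spec]
    required = list(spec.continuous) + list(spec.categorical)
    for col in required:
        if col not in records.columns:
            raise KeyError(f"required column '{col}' missing for predictor set "
                           f"'{spec.name}'")
    if len(records) == 0:
        cols = list(spec.continuous)
        return pd.DataFrame(columns=cols)
    table = records[list(spec.continuous)].astype(float).copy()
    for col in spec.categorical:
        series = records[col]
        if series.dropna().isin([0, 1]).all() and series.nunique() <= 2:
            table[col] = series.astype(float)
        else:
            dummies = pd.get_dummies(series, prefix=col, dtype=float)
            table = pd.concat([table, dummies], axis=1)
    return table


# ---------------------------------------------------------------------------
# k-NN multiple imputation
# ---------------------------------------------------------------------------

def impute_knn(table: pd.DataFrame, k: int = 5, m: int = 5,
               seed: int = 0) -> list[pd.DataFrame]:
    """Produce ``m`` completed copies of ``table`` by k-NN imputation.

    Distances are nan-aware Euclidean on standardised columns.  Each
    imputation fills a missing cell with the mean of a seeded bootstrap
    resample of the k nearest complete values, giving between-imputation
    variability while never altering observed cells.  With k=1 the unique
    nearest donor value is copied unchanged.
    """
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    X = table.to_numpy(dtype=float)
    mask = np.isnan(X)
    for j, col in enumerate(table.columns):
        if mask[:, j].all():
            raise ValueError(f"column '{col}' is entirely missing; cannot impute")
    if not mask.any():
        return [table.copy() for _ in range(m)]

    from sklearn.metrics.pairwise import nan_euclidean_distances

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    D = nan_euclidean_distances(Z, Z)
    np.fill_diagonal(D, np.inf)

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        filled = X.copy()
        for i, j in zip(*np.where(mask)):
            donors = np.where(~mask[:, j])[0]
            order = donors[np.argsort(D[i, donors], kind="stable")]
            nearest = order[:k]
            vals = X[nearest, j]
            if len(vals) == 1:
                filled[i, j] = vals[0]
            else:
                pick = rng.integers(0, len(vals), size=len(vals))
                filled[i, j] = vals[pick].mean()
        out.append(pd.DataFrame(filled, index=table.index, columns=table.columns))
    return out


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

def _make_estimator(family: str, seed: int) -> Pipeline:
    if family == "logreg":
        est = LogisticRegression(max_iter=2000, random_state=seed)
    elif family == "lda":
        est = LinearDiscriminantAnalysis()
    elif family == "rf":
        est = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    elif family == "svm":
        # probability=True fits a Platt sigmoid on internal CV of the
        # training data, giving calibrated-scale probabilities
        est = SVC(kernel="rbf", probability=True, random_state=seed)
    else:
        raise ValueError(f"unknown model family '{family}'; "
                         f"choose one of {MODEL_FAMILIES}")
    return Pipeline([("scale", StandardScaler()), ("model", est)])


@dataclass
class FittedRiskModel:
    """A fitted classifier plus the metadata needed to score new records."""

    family: str
    spec_name: str
    pipeline: Pipeline
    columns: list[str]
    threshold: float
    seed: int

    def predict_risk(self, records: pd.DataFrame) -> np.ndarray:
        """Per-person CVD probability in [0, 1]."""
        if self.pipeline is None:
            raise RuntimeError("model is not fitted")
        if set(self.columns) <= set(records.columns):
            X = records[self.columns]
        else:
            table = build_predictor_set(records, self.spec_name)
            missing = [c for c in self.columns if c not in table.columns]
            for c in missing:   # unseen one-hot levels
                table[c] = 0.0
            X = table[self.columns]
        return self.pipeline.predict_proba(X.to_numpy(dtype=float))[:, 1]


@dataclass
class HarnessResult:
    """Pooled and per-imputation evaluation metrics.

    ``metrics`` holds the across-imputation means of: accuracy (held-out
    test accuracy at the training-optimal threshold), auc (on pooled
    cross-validated training predictions), auprc (same predictions),
    c_statistic (concordance of predicted probability with the outcome on
    the held-out test split).  ``fold_auc`` are the per-fold training AUCs
    of the first imputation.
    """

    family: str
    spec_name: str
    metrics: dict[str, float]
    per_imputation: list[dict[str, float]]
    fold_auc: list[float]
    threshold: float
    model: FittedRiskModel
    n_folds: int = 10


def _choose_threshold(y: np.ndarray, p: np.ndarray) -> float:
    """Grid-search the probability cutoff maximising accuracy (step 0.01)."""
    grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    acc = [( (p >= t).astype(int) == y).mean() for t in grid]
    return float(grid[int(np.argmax(acc))])


def train_eval(tables: list[pd.DataFrame], outcome: pd.Series | np.ndarray,
               family: str = "lda", seed: int = 0,
               n_folds: int = 10, test_size: float = 0.30) -> HarnessResult:
    """Run the full evaluation protocol over the imputed tables.

    Per table: stratified 70/30 split; stratified ``n_folds``-fold CV on
    the training portion producing out-of-fold probabilities (AUC/AUPRC
    and threshold selection); refit on the full training portion; test
    metrics on the held-out 30%.  Metrics are pooled across imputations by
    averaging; the returned model is refitted on the full first imputation.
    """
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    split_seed, cv_seed = seed, seed + 1  # separate split and fold seeds

    per_imp, fold_auc_first = [], []
    thresholds = []
    for im, table in enumerate(tables):
        X = table.to_numpy(dtype=float)
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=test_size, stratify=y,
            random_state=split_seed)
        Xtr, ytr = X[idx_train], y[idx_train]
        Xte, yte = X[idx_test], y[idx_test]

        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)
        oof = np.full(len(ytr), np.nan)
        fold_aucs = []
        for tr, va in skf.split(Xtr, ytr):
            est = _make_estimator(family, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xtr[tr], ytr[tr])
            p = est.predict_proba(Xtr[va])[:, 1]
            oof[va] = p
            if len(np.unique(ytr[va])) == 2:
                fold_aucs.append(float(roc_auc_score(ytr[va], p)))
        threshold = _choose_threshold(ytr, oof)
        thresholds.append(threshold)

        final = _make_estimator(family, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(Xtr, ytr)
        p_test = final.predict_proba(Xte)[:, 1]

        metrics = {
            "accuracy": float(((p_test >= threshold).astype(int) == yte).mean()),
            "auc": float(roc_auc_score(ytr, oof)),
            "auprc": float(average_precision_score(ytr, oof)),
            "c_statistic": float(roc_auc_score(yte, p_test)),
        }
        per_imp.append(metrics)
        if im == 0:
            fold_auc_first = fold_aucs

    pooled = {k: float(np.mean([d[k] for d in per_imp])) for k in per_imp[0]}
    pooled_threshold = float(np.mean(thresholds))

    full = _make_estimator(family, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(tables[0].to_numpy(dtype=float), y)
    model = FittedRiskModel(family=family, spec_name="", pipeline=full,
                            columns=list(tables[0].columns),
                            threshold=pooled_threshold, seed=seed)
    return HarnessResult(family=family, spec_name="", metrics=pooled,
                         per_imputation=per_imp, fold_auc=fold_auc_first,
                         threshold=pooled_threshold, model=model,
                         n_folds=n_folds)


def run_harness(records: pd.DataFrame, outcome_col: str = "cvd",
                spec: str = "fpp", family: str = "lda",
                k: int = 5, m: int = 5, seed: int = 0) -> HarnessResult:
    """Convenience wrapper: predictor set -> imputation -> train_eval."""
    table = build_predictor_set(records, spec)
    tables = impute_knn(table, k=k, m=m, seed=seed)
    result = train_eval(tables, records[outcome_col], family=family, seed=seed)
    result.spec_name = spec
    result.model.spec_name = spec
    return result


# ---------------------------------------------------------------------------
# Per-profile nutrient coefficients (inputs to the required-change rule)
# ---------------------------------------------------------------------------

def profile_nutrient_coefficients(records: pd.DataFrame, profile: str,
                                  profile_col: str = "profile",
                                  nutrients: list[str] = LEVEL2_NUTRIENTS,
                                  ) -> dict[str, dict[str, float]]:
    """Log-odds coefficient of each level-2 nutrient for one profile.

    Fits a logistic model of CVD on the six nutrients plus the non-diet
    covariates of the FPP predictor set (age, sex, BMI, WC, smoking,
    hypertension flags), restricted to records of the given profile.
    Returns per nutrient: ``beta``, its standard error and 95% CI.
    Constant nutrient columns are flagged with a NaN coefficient.
    """
    sub = records[records[profile_col] == profile]
    if len(sub) == 0:
        raise ValueError(f"no records for profile '{profile}'")
    covars = build_predictor_set(sub, PredictorSpec(
        "nutrient_adjusted", tuple(_FPP_CONT), tuple(_BASE_CAT)))
    X = pd.concat([sub[nutrients].astype(float), covars], axis=1)
    degenerate = [n for n in nutrients if sub[n].nunique(dropna=True) <= 1]
    keep = [c for c in X.columns if X[c].nunique(dropna=True) > 1]
    X = sm.add_constant(X[keep], has_constant="add")
    y = sub["cvd"].astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    out: dict[str, dict[str, float]] = {}
    ci = fit.conf_int()
    for n in nutrients:
        if n in degenerate or n not in fit.params.index:
            out[n] = {"beta": float("nan"), "se": float("nan"),
                      "ci_low": float("nan"), "ci_high": float("nan"),
                      "flag": "degenerate"}
        else:
            out[n] = {"beta": float(fit.params[n]), "se": float(fit.bse[n]),
                      "ci_low": float(ci.loc[n, 0]), "ci_high": float(ci.loc[n, 1]),
                      "flag": ""}
    return out


def pooled_nutrient_coefficients(imputed_records: list[pd.DataFrame],
                                 profile: str, **kwargs) -> dict[str, dict[str, float]]:
    """Rubin's-rules mean of per-imputation nutrient coefficients."""
    runs = [profile_nutrient_coefficients(r, profile, **kwargs)
            for r in imputed_records]
    out = {}
    for n in runs[0]:
        betas = [r[n]["beta"] for r in runs]
        out[n] = dict(runs[0][n])
        out[n]["beta"] = float(np.mean(betas))
    return out


def estimate_profile_odds_ratios(records: pd.DataFrame,
                                 profile_col: str = "profile",
                                 outcome_col: str = "cvd") -> dict[str, dict[str, float]]:
    """Empirical per-profile odds ratios (each profile vs pooled others)
    from single-indicator logistic models, with 95% CIs."""
    out = {}
    y = records[outcome_col].astype(int)
    for prof in PROFILES:
        x = (records[profile_col] == prof).astype(float)
        X = sm.add_constant(x.to_frame("indicator"))
        fit = sm.Logit(y, X).fit(disp=0)
        beta = float(fit.params["indicator"])
        lo, hi = fit.conf_int().loc["indicator"]
        out[prof] = {"or": float(np.exp(beta)), "ci_low": float(np.exp(lo)),
                     "ci_high": float(np.exp(hi))}
    return out
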