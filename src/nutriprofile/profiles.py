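"""Food-preference profile modelling.

Two classifiers live here:

* the latent-profile (Gaussian-mixture) model fitted to the full 140-item
  liking matrix by expectation-maximization, with the number of profiles
  chosen by BIC among candidates whose smallest component holds at least
  10% of participants, and participants assigned to the profile with the
  highest posterior probability;

* the simplified questionnaire classifier — a shallow decision tree over a
  small item subset (14 items in the packaged canonical tree) that lets a
  user be profiled from a handful of liking questions instead of 140.

Also provided: one-vs-rest evaluation metrics and a three-method feature
importance analysis (random-forest importance, L1-penalised multinomial
coefficients, Monte-Carlo Shapley attributions) with a consensus ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-export for tests)
from sklearn.mixture import GaussianMixture
from sklearn.tree import DecisionTreeClassifier

from .cohort import (ITEM_CATALOG, ITEM_NAMES, LIKING_PREFIX, PROFILES,
                     items_in_group, liking_columns)

DEFAULT_SEED = 83988
MIN_PROFILE_FRACTION = 0.10


class FitError(RuntimeError):
    """Raised when no admissible mixture model can be selected."""


# ---------------------------------------------------------------------------
# Latent profile model
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Result of latent-profile fitting over a range of component counts.

    ``bic`` follows the model-selection convention where larger is better
    (2 log L minus the parameter penalty); ``selected`` flags the winning
    candidate among those satisfying the minimum-profile-size rule.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    bic: float
    posterior: np.ndarray
    columns: list[str]
    candidates: list[dict] = field(default_factory=list)
    converged: bool = True
    label_map: dict[int, str] | None = None


def _impute_liking(X: np.ndarray) -> np.ndarray:
    """Column-mean imputation used to initialise EM on incomplete matrices."""
    X = X.astype(float).copy()
    col_means = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = col_means[nan_cols]
    return X


def fit_latent_profiles(liking: pd.DataFrame,
                        k_range: range | list[int] = range(2, 10),
                        covariance_type: str = "full",
                        shared_shape: bool = False,
                        seed: int = DEFAULT_SEED,
                        max_iter: int = 200,
                        em_impute_rounds: int = 3) -> MixtureFit:
    """Fit Gaussian mixtures for each candidate k and select by BIC.

    Candidates whose smallest posterior-assigned component holds fewer than
    10% of participants are inadmissible.  Missing liking scores are
    imputed from component-conditional means, alternating imputation and
    EM refits (``em_impute_rounds`` outer rounds); complete matrices take
    a single fit.  ``shared_shape=True`` switches to a tied covariance
    (one shape/volume shared by all components), an approximation of the
    equal-volume equal-shape ellipsoidal family.
    """
    if len(liking) == 0:
        raise FitError("cannot fit a mixture on an empty liking matrix")
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 for k in ks):
        raise ValueError("component counts must be >= 1")
    if len(liking) < 10 * max(ks):
        raise FitError(f"need at least {10 * max(ks)} records to fit up to k={max(ks)}")
    cols = list(liking.columns)
    X_raw = liking.to_numpy(dtype=float)
    has_missing = np.isnan(X_raw).any()
    cov = "tied" if shared_shape else covariance_type

    candidates = []
    for k in ks:
        gm = GaussianMixture(n_components=k, covariance_type=cov,
                             random_state=seed, max_iter=max_iter,
                             reg_covar=1e-4, n_init=1)
        X = _impute_liking(X_raw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
            if has_missing:
                for _ in range(em_impute_rounds):
                    resp = gm.predict_proba(X)
                    # replace missing cells with posterior-weighted component means
                    filled = resp @ gm.means_
                    X = np.where(np.isnan(X_raw), filled, X_raw)
                    gm.fit(X)
        resp = gm.predict_proba(X)
        assigned = resp.argmax(axis=1)
        frac = np.bincount(assigned, minlength=k) / len(X)
        bic = -gm.bic(X)          # flip: larger is better
        candidates.append({
            "k": k, "bic": float(bic), "min_fraction": float(frac.min()),
            "admissible": bool(frac.min() >= MIN_PROFILE_FRACTION),
            "converged": bool(gm.converged_), "model": gm, "X": X,
        })

    admissible = [c for c in candidates if c["admissible"]]
    if not admissible:
        raise FitError(
            "no candidate satisfies the minimum-profile-size rule "
            f"(every component >= {MIN_PROFILE_FRACTION:.0%} of participants)")
    best = max(admissible, key=lambda c: c["bic"])
    gm, X = best["model"], best["X"]
    fit = MixtureFit(
        k=best["k"], weights=gm.weights_.copy(), means=gm.means_.copy(),
        covariances=np.asarray(gm.covariances_).copy(), bic=best["bic"],
        posterior=gm.predict_proba(X), columns=cols,
        candidates=[{k: v for k, v in c.items() if k not in ("model", "X")}
                    for c in candidates],
        converged=best["converged"],
    )
    for c in fit.candidates:
        c["selected"] = c["k"] == best["k"]
    fit.label_map = _label_components(fit)
    return fit


def _group_mean(means_row: np.ndarray, cols: list[str], group: str) -> float:
    wanted = {LIKING_PREFIX + n for n in items_in_group(group)}
    idx = [i for i, c in enumerate(cols) if c in wanted or c in
           {n for n in items_in_group(group)}]
    if not idx:
        return np.nan
    return float(means_row[idx].mean())


def _label_components(fit: MixtureFit) -> dict[int, str] | None:
    """Map mixture components to the three named profiles by their liking
    signature: highest fruit/veg mean -> health_conscious, highest sweet
    mean among the rest -> sweet_tooth, remainder -> omnivore.  Matrices
    without recognised liking items get no mapping (components keep their
    indices)."""
    k = fit.k
    fv = [_group_mean(fit.means[j], fit.columns, "fruit_veg") for j in range(k)]
    sw = [_group_mean(fit.means[j], fit.columns, "sweet") for j in range(k)]
    if np.isnan(fv).all() or np.isnan(sw).all():
        return None
    label_map: dict[int, str] = {}
    remaining = list(range(k))
    hc = int(np.nanargmax([fv[j] for j in remaining]))
    hc = remaining[hc]
    label_map[hc] = "health_conscious"
    remaining.remove(hc)
    if remaining:
        st = remaining[int(np.nanargmax([sw[j] for j in remaining]))]
        label_map[st] = "sweet_tooth"
        remaining.remove(st)
    for j in remaining:
        label_map[j] = "omnivore"
    return label_map


def assign_profiles(fit: MixtureFit, liking: pd.DataFrame) -> pd.Series:
    """Assign each record to the label of its maximum-posterior component.

    Posterior ties resolve to the lowest component index (argmax rule).
    """
    if list(liking.columns) != fit.columns:
        if set(liking.columns) >= set(fit.columns):
            liking = liking[fit.columns]
        else:
            missing = sorted(set(fit.columns) - set(liking.columns))
            raise ValueError(f"liking matrix missing fitted columns: {missing[:5]}")
    X = _impute_liking(liking.to_numpy(dtype=float))
    gm = GaussianMixture(n_components=fit.k)
    gm.weights_ = fit.weights
    gm.means_ = fit.means
    cov = fit.covariances
    gm.covariance_type = "full" if cov.ndim == 3 else "tied"
    gm.covariances_ = cov
    from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky
    gm.precisions_cholesky_ = _compute_precision_cholesky(cov, gm.covariance_type)
    post = gm.predict_proba(X)
    comp = post.argmax(axis=1)
    label_map = fit.label_map or _label_components(fit)
    if label_map is None:
        label_map = {j: f"component_{j}" for j in range(fit.k)}
    return pd.Series([label_map[int(c)] for c in comp], index=liking.index,
                     name="profile")


# ---------------------------------------------------------------------------
# Simplified decision-tree classifier
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    id: int
    item: str | None          # None for leaves
    threshold: float | None   # split: go left when score < threshold
    left: int | None
    right: int | None
    predicted_class: str
    class_distribution: dict[str, float]


@dataclass
class SimplifiedTree:
    """A binary decision tree over a small liking-item subset."""

    nodes: list[TreeNode]
    item_subset: list[str]

    def classify(self, liking: dict[str, float]) -> str:
        node = self.nodes[0]
        by_id = {n.id: n for n in self.nodes}
        while node.item is not None:
            if node.item not in liking or liking[node.item] is None:
                raise ValueError(f"liking score for '{node.item}' required")
            node = by_id[node.left] if liking[node.item] < node.threshold else by_id[node.right]
        return node.predicted_class

    def classify_frame(self, liking: pd.DataFrame) -> pd.Series:
        cols = {c[len(LIKING_PREFIX):] if c.startswith(LIKING_PREFIX) else c: c
                for c in liking.columns}
        out = []
        for _, row in liking.iterrows():
            out.append(self.classify({k: row[v] for k, v in cols.items()
                                      if pd.notna(row[v])}))
        return pd.Series(out, index=liking.index, name="profile")

    def to_json(self) -> dict:
        return {
            "nodes": [{"id": n.id, "item": n.item, "threshold": n.threshold,
                       "left": n.left, "right": n.right,
                       "class": n.predicted_class,
                       "dist": n.class_distribution} for n in self.nodes],
            "item_subset": list(self.item_subset),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SimplifiedTree":
        nodes = [TreeNode(d["id"], d["item"], d["threshold"], d["left"],
                          d["right"], d["class"], d.get("dist", {}))
                 for d in obj["nodes"]]
        return cls(nodes, list(obj["item_subset"]))


#: The 14 questionnaire items retained by the canonical simplified classifier.
CANONICAL_ITEM_SUBSET = [
    "tea_with_sugar", "vegetables", "roast_chicken", "ham", "tomatoes",
    "strawberries", "green_olives", "banana", "sweet_coffee_drinks",
    "coffee_with_sugar", "fruit", "mushroom", "spinach", "potatoes",
]


def canonical_tree() -> SimplifiedTree:
    """The packaged canonical simplified classifier.

    Root splits on tea-with-sugar at 3 (scores < 3 go left); the left
    branch splits on vegetables at 8 (>= 8 -> health-conscious); the right
    branch splits on roast chicken at 7 (>= 7 -> omnivore, < 7 ->
    sweet-tooth).  Threshold directions are exact: "< 3" strict, ">= 8"
    and ">= 7" inclusive.
    """
    with resources.files("nutriprofile.data").joinpath("canonical_tree.json").open() as fh:
        return SimplifiedTree.from_json(json.load(fh))


def train_simplified_tree(liking: pd.DataFrame, labels: pd.Series,
                          max_items: int = 14, max_depth: int = 5,
                          seed: int = DEFAULT_SEED) -> SimplifiedTree:
    """Train a CART tree and restrict it to its top-importance items.

    A first tree fitted on all columns ranks items by impurity importance;
    the final tree is refitted on the top ``max_items`` items so the
    questionnaire needs at most that many questions.  Single-class input
    yields a degenerate one-leaf tree with a warning.
    """
    if max_items < 1:
        raise ValueError("max_items must be >= 1")
    y = np.asarray(labels)
    X = _impute_liking(liking.to_numpy(dtype=float))
    classes = np.unique(y)
    cols = [c[len(LIKING_PREFIX):] if c.startswith(LIKING_PREFIX) else c
            for c in liking.columns]
    if len(classes) == 1:
        warnings.warn("single-class input: returning a one-leaf tree")
        leaf = TreeNode(0, None, None, None, None, str(classes[0]),
                        {str(classes[0]): 1.0})
        return SimplifiedTree([leaf], [])

    probe = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    probe.fit(X, y)
    importance = probe.feature_importances_
    top = np.argsort(importance)[::-1][:max_items]
    top = np.array([i for i in top if importance[i] > 0] or [int(top[0])])
    final = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    final.fit(X[:, top], y)
    return _sklearn_tree_to_simplified(final, [cols[i] for i in top])


def _sklearn_tree_to_simplified(clf: DecisionTreeClassifier,
                                item_names: list[str]) -> SimplifiedTree:
    t = clf.tree_
    classes = [str(c) for c in clf.classes_]
    nodes = []
    used: set[str] = set()
    for i in range(t.node_count):
        counts = t.value[i][0]
        dist = {c: float(v) / float(counts.sum()) for c, v in zip(classes, counts)}
        pred = classes[int(np.argmax(counts))]
        if t.children_left[i] == -1:
            nodes.append(TreeNode(i, None, None, None, None, pred, dist))
        else:
            item = item_names[t.feature[i]]
            used.add(item)
            # sklearn sends x <= thr left; we store "go left when x < thr"
            # with an equivalent threshold for integer-valued scores
            thr = float(t.threshold[i])
            nodes.append(TreeNode(i, item, thr, int(t.children_left[i]),
                                  int(t.children_right[i]), pred, dist))
    # rewrite split rule: x <= thr  <=>  x < thr' where thr' = thr (continuous)
    return SimplifiedTree(nodes, sorted(used))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    """One-vs-rest sensitivity, specificity and F1 per class.  Metrics that
    are undefined (class absent from the truth) are NaN and flagged."""

    per_class: dict[str, dict[str, float]]
    undefined: list[str]

    def __getitem__(self, cls: str) -> dict[str, float]:
        return self.per_class[cls]


def evaluate_classifier(true: pd.Series | list, predicted: pd.Series | list,
                        classes: list[str] | None = None) -> ClassMetrics:
    t = np.asarray(true, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if len(t) != len(p):
        raise ValueError("true and predicted must have equal length")
    if len(t) == 0:
        raise ValueError("need at least one record")
    if classes is None:
        classes = sorted(set(t) | set(p))
    per_class, undefined = {}, []
    for c in classes:
        tp = int(((t == c) & (p == c)).sum())
        fn = int(((t == c) & (p != c)).sum())
        fp = int(((t != c) & (p == c)).sum())
        tn = int(((t != c) & (p != c)).sum())
        if tp + fn == 0:
            undefined.append(c)
            sens = np.nan
        else:
            sens = tp / (tp + fn)
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else np.nan
        per_class[c] = {"sensitivity": sens, "specificity": spec, "f1": f1}
    return ClassMetrics(per_class, undefined)


# ---------------------------------------------------------------------------
# Feature importance (three methods + consensus)
# ---------------------------------------------------------------------------

def _shapley_attribution(model, X: np.ndarray, n_samples: int, rng) -> np.ndarray:
    """Monte-Carlo Shapley attribution of mean predicted class probability.

    For each sampled (instance, feature permutation) pair, features are
    switched one at a time from a background value (the column mean) to the
    instance's value; the marginal change in the predicted probability of
    the instance's predicted class is credited to the switched feature.
    Averaging over permutations estimates the Shapley value; we report the
    mean absolute attribution per feature.
    """
    n, d = X.shape
    background = X.mean(axis=0)
    attrib = np.zeros(d)
    pred_class = model.predict(X)
    class_index = {c: i for i, c in enumerate(model.classes_)}
    rows = rng.choice(n, size=min(n_samples, n), replace=False)
    for i in rows:
        order = rng.permutation(d)
        x = background.copy()
        ci = class_index[pred_class[i]]
        prev = model.predict_proba(x[None, :])[0, ci]
        for j in order:
            x[j] = X[i, j]
            cur = model.predict_proba(x[None, :])[0, ci]
            attrib[j] += abs(cur - prev)
            prev = cur
    return attrib / len(rows)


def feature_importance(liking: pd.DataFrame, labels: pd.Series,
                       seed: int = DEFAULT_SEED,
                       shap_samples: int = 40) -> pd.DataFrame:
    """Rank liking items by three importance methods and their consensus.

    Columns: ``rf`` (random-forest impurity importance), ``lasso`` (mean
    absolute L1-penalised multinomial coefficient over classes, on
    standardised features), ``shapley`` (Monte-Carlo Shapley attribution of
    the random forest's predicted probabilities) and ``consensus_rank``
    (mean of the three per-method ranks; 1 = most important).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes for importance analysis")
    X = _impute_liking(liking.to_numpy(dtype=float))
    cols = list(liking.columns)
    rng = np.random.default_rng(seed)

    rf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    rf_imp = rf.feature_importances_

    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    lasso = LogisticRegression(penalty="l1", solver="saga", C=0.5,
                               max_iter=2000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso.fit(Xs, y)
    lasso_imp = np.abs(lasso.coef_).mean(axis=0)

    shap_imp = _shapley_attribution(rf, X, shap_samples, rng)

    out = pd.DataFrame({"rf": rf_imp, "lasso": lasso_imp, "shapley": shap_imp},
                       index=cols)
    ranks = out.rank(ascending=False, method="average")
    out["consensus_rank"] = ranks.mean(axis=1)
    return out.sort_values("consensus_rank")
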