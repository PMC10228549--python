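"""Functional-group assignment of genomes: rule-based and machine-learned.

The four groups are *Ferment to Intermediates* (carbohydrates to lactic
acid / ethanol, no chain elongation), *Intermediate Chain Elongators*
(intermediates to medium-chain fatty acids), *Carbohydrate Chain
Elongators* (carbohydrates directly to MCFAs) and *uninvolved*.

Rule scheme (thresholds high = 60%, low = 40% of pathway roster detected,
evaluated in order, first match wins):

* Ferment to Intermediates — any carbohydrate-fermentation pathway
  (homolactic, phosphoketolase or bifid shunt) high, while lactic-acid
  utilization (LAU) and reverse beta-oxidation (RBO) are low.
* Intermediate Chain Elongators — heterolactic pathways low, LAU and RBO
  both high.
* Carbohydrate Chain Elongators — heterolactic pathways and LAU low, RBO
  high.
* otherwise uninvolved.

The ML route is a pluggable multiclass-probability contract; the default
in-repo model is multinomial softmax regression with an L2 penalty trained
by full-batch gradient descent (deterministic under seed).  A LightGBM
adapter satisfies the same contract when that library is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .profiling import PathwayProfile
from .records import GROUPS

_FERMENT_PATHWAYS = ("homolactic", "phosphoketolase", "bifid_shunt")
_HETEROLACTIC = ("phosphoketolase", "bifid_shunt")
_LAU = "lactic_acid_utilization"
_RBO = "reverse_beta_oxidation"


@dataclass
class RuleThresholds:
    high: float = 60.0
    low: float = 40.0

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high <= 100:
            raise ValueError("need 0 <= low < high <= 100")


@dataclass
class FunctionalCall:
    genome_id: str
    group: str
    method: str  # "rule" | "ml"
    probabilities: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.probabilities is not None:
            total = sum(self.probabilities.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities sum to {total}, not 1")


def rule_classify(profile: PathwayProfile, t: RuleThresholds | None = None) -> FunctionalCall:
    """Deterministic, total rule assignment from pathway percentages."""
    t = t or RuleThresholds()
    pct = profile.per_pathway_percent
    ferment = max(pct[p] for p in _FERMENT_PATHWAYS)
    hetero = max(pct[p] for p in _HETEROLACTIC)
    lau, rbo = pct[_LAU], pct[_RBO]
    if ferment >= t.high and lau <= t.low and rbo <= t.low:
        group = "ferment_to_intermediates"
    elif hetero <= t.low and lau >= t.high and rbo >= t.high:
        group = "intermediate_ce"
    elif hetero <= t.low and lau <= t.low and rbo >= t.high:
        group = "carbohydrate_ce"
    else:
        group = "uninvolved"
    return FunctionalCall(profile.genome_id, group, "rule")


# -- metrics ----------------------------------------------------------------

def logloss(probabilities: np.ndarray, true_idx: np.ndarray) -> float:
    """Mean -ln p(true class), probabilities clipped to [1e-15, 1-1e-15]."""
    p = np.clip(np.asarray(probabilities, float), 1e-15, 1 - 1e-15)
    true_idx = np.asarray(true_idx, int)
    return float(np.mean(-np.log(p[np.arange(len(true_idx)), true_idx])))


def baseline_logloss(labels: np.ndarray, n_classes: int | None = None) -> float:
    """Logloss of the class-frequency predictor on the same labels."""
    labels = np.asarray(labels, int)
    k = n_classes or labels.max() + 1
    freq = np.bincount(labels, minlength=k) / labels.size
    probs = np.tile(freq, (labels.size, 1))
    return logloss(probs, labels)


def baseline_improvement(model_logloss: float, baseline: float) -> float:
    """Percent decrease in logloss relative to the baseline predictor."""
    return 100.0 * (baseline - model_logloss) / baseline


# -- classifier contract ----------------------------------------------------

class SoftmaxRegression:
    """Multinomial logistic (softmax) regression, L2-penalized, trained by
    full-batch gradient descent.  Deterministic: zero-initialized weights,
    fixed iteration count and learning rate."""

    def __init__(self, l2: float = 1e-3, learning_rate: float = 0.5,
                 n_iter: int = 500, seed: int = 0):
        self.l2 = l2
        self.learning_rate = learning_rate
        self.n_iter = n_iter
        self.seed = seed
        self.classes_: np.ndarray | None = None

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftmaxRegression":
        X = np.asarray(X, float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = self.classes_.size
        n, d = X.shape
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        Xs = (X - self._mu) / self._sd
        W = np.zeros((d, k))
        b = np.zeros(k)
        onehot = np.eye(k)[y_idx]
        for _ in range(self.n_iter):
            P = self._softmax(Xs @ W + b)
            G = Xs.T @ (P - onehot) / n + self.l2 * W
            gb = (P - onehot).mean(axis=0)
            W -= self.learning_rate * G
            b -= self.learning_rate * gb
        self.W_, self.b_ = W, b
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self._mu) / self._sd
        return self._softmax(Xs @ self.W_ + self.b_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class LightGBMClassifier:
    """Optional gradient-boosting plug-in behind the same contract."""

    def __init__(self, seed: int = 0, **kwargs):
        import lightgbm as lgb  # deferred: optional dependency

        self._model = lgb.LGBMClassifier(
            random_state=seed, deterministic=True, verbose=-1, **kwargs
        )
        self.classes_ = None

    def fit(self, X, y):
        self._model.fit(np.asarray(X, float), np.asarray(y))
        self.classes_ = self._model.classes_
        return self

    def predict_proba(self, X):
        return self._model.predict_proba(np.asarray(X, float))

    def predict(self, X):
        return self._model.predict(np.asarray(X, float))


ALGORITHMS = {
    "softmax": SoftmaxRegression,
    "lightgbm": LightGBMClassifier,
}


@dataclass
class TrainingReport:
    cv_logloss: float
    baseline_logloss: float
    improvement_percent: float
    average_precision: dict[str, float]
    roc_auc: dict[str, float]
    n_examples: int
    n_features: int
    algorithm: str


def train_classifier(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    algorithm: str = "softmax",
    seed: int = 0,
    n_splits: int = 5,
):
    """Fit a multiclass classifier and report cross-validated metrics.

    ``features`` is a profile matrix (pathway percentages + enzyme bits);
    ``labels`` the functional group per row.  Returns (fitted classifier,
    TrainingReport) with CV logloss, per-class average precision and
    one-vs-rest ROC AUC, and the improvement over the class-frequency
    baseline.
    """
    X = features.values.astype(float)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    counts = np.bincount(y_idx)
    n_splits = min(n_splits, counts.min())
    if n_splits < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(
            f"classes with a single example cannot be cross-validated: {small}; "
            "provide at least 2 examples per class"
        )
    factory = ALGORITHMS[algorithm]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    oof = np.zeros((len(y), classes.size))
    for train_idx, test_idx in skf.split(X, y_idx):
        model = factory(seed=seed).fit(X[train_idx], y[train_idx])
        proba = model.predict_proba(X[test_idx])
        # align fold class order to global order
        col = {c: i for i, c in enumerate(model.classes_)}
        for gi, c in enumerate(classes):
            if c in col:
                oof[test_idx, gi] = proba[:, col[c]]
    cv_ll = logloss(oof, y_idx)
    base_ll = baseline_logloss(y_idx, classes.size)
    ap, auc = {}, {}
    for gi, c in enumerate(classes):
        truth = (y_idx == gi).astype(int)
        ap[str(c)] = float(average_precision_score(truth, oof[:, gi]))
        auc[str(c)] = float(roc_auc_score(truth, oof[:, gi]))
    final = factory(seed=seed).fit(X, y)
    report = TrainingReport(
        cv_logloss=cv_ll,
        baseline_logloss=base_ll,
        improvement_percent=baseline_improvement(cv_ll, base_ll),
        average_precision=ap,
        roc_auc=auc,
        n_examples=len(y),
        n_features=X.shape[1],
        algorithm=algorithm,
    )
    return final, report


def ml_classify(classifier, features: pd.DataFrame) -> list[FunctionalCall]:
    proba = classifier.predict_proba(features.values.astype(float))
    calls = []
    for i, gid in enumerate(features.index):
        probs = {str(c): float(p) for c, p in zip(classifier.classes_, proba[i])}
        total = sum(probs.values())
        probs = {c: p / total for c, p in probs.items()}
        group = max(probs, key=probs.get)
        calls.append(FunctionalCall(str(gid), group, "ml", probs))
    return calls


def classify_cohort(
    classifier,
    features: pd.DataFrame,
    high_abundance: set[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[list[FunctionalCall], pd.DataFrame]:
    """ML calls restricted to the high-abundance set, with group counts.

    Returns (calls, counts table).  When sample ``metadata`` carrying a
    genome->experiment mapping (columns genome_id, experiment) is given, a
    per-experiment breakdown is included.
    """
    if high_abundance is not None:
        wanted = sorted(high_abundance)
        missing = [g for g in wanted if g not in features.index]
        if missing:
            raise ValueError(f"profiles missing for requested genomes: {missing}")
        features = features.loc[wanted]
    if features.empty:
        return [], pd.DataFrame(columns=["group", "count"])
    calls = ml_classify(classifier, features)
    counts = (
        pd.Series([c.group for c in calls]).value_counts()
        .reindex(list(GROUPS), fill_value=0)
        .rename_axis("group").reset_index(name="count")
    )
    if metadata is not None and "experiment" in metadata.columns:
        meta = metadata.set_index("genome_id")
        rows = []
        for c in calls:
            if c.genome_id in meta.index:
                rows.append({"experiment": meta.loc[c.genome_id, "experiment"],
                             "group": c.group})
        if rows:
            breakdown = pd.DataFrame(rows).value_counts().reset_index(name="count")
            counts = counts.merge(
                breakdown.pivot(index="group", columns="experiment", values="count")
                .fillna(0).astype(int).reset_index(),
                on="group", how="left",
            ).fillna(0)
    return calls, counts


def compare_methods(
    rule_calls: list[FunctionalCall], ml_calls: list[FunctionalCall]
) -> dict[str, dict[str, int]]:
    """Venn counts (rule-only / ml-only / both) for the three productive
    groups."""
    out = {}
    rule_by_group = {g: {c.genome_id for c in rule_calls if c.group == g} for g in GROUPS}
    ml_by_group = {g: {c.genome_id for c in ml_calls if c.group == g} for g in GROUPS}
    for g in GROUPS[:3]:
        r, m = rule_by_group[g], ml_by_group[g]
        out[g] = {
            "rule_only": len(r - m),
            "ml_only": len(m - r),
            "both": len(r & m),
        }
    return out


def calls_to_frame(calls: list[FunctionalCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"genome_id": c.genome_id, "method": c.method, "group": c.group}
        if c.probabilities:
            for g in GROUPS:
                row[f"p_{g}"] = round(c.probabilities.get(g, 0.0), 6)
        rows.append(row)
    return pd.DataFrame(rows)
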