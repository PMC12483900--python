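"""Classifier training, wrapper feature selection and subject-wise evaluation.

The pipeline scores feature subsets by the 5-fold cross-validated
misclassification rate of a classifier (SVM, KNN, naive Bayes or decision
tree), selects features by greedy forward sequential search, optionally
tunes hyperparameters with a Gaussian-process sequential model-based
optimizer, and evaluates with leave-one-subject-out cross-validation
(LOSOCV): each subject's cycles form the test set in turn and the average
accuracy over subjects is the headline number.

Two leakage modes are supported. ``paper`` normalizes and SMOTE-balances
the whole table before splitting (the classic ordering, which leaks test
information into training); ``strict`` fits normalization scales and SMOTE
inside each training fold only, so held-out subjects are scored on rows
never touched by preprocessing. The user-facing entry point is
:class:`SaddleHeightModel`, whose ``fit`` returns a
:class:`SaddleHeightResults` with a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from scipy.stats import norm

from saddlefit.dataset import LabeledDataset, smote_balance
from saddlefit.features import FeatureTable, normalize_columns

log = logging.getLogger(__name__)

__all__ = [
    "MODEL_KINDS",
    "ClassifierSpec",
    "SelectionResult",
    "EvaluationReport",
    "TuningResult",
    "cv_misclassification",
    "forward_sfs",
    "tune_hyperparameters",
    "losocv_evaluate",
    "single_feature_accuracy_ranking",
    "SaddleHeightModel",
    "SaddleHeightResults",
]

MODEL_KINDS = ("svm", "knn", "nb", "dt")

_DEFAULT_PARAMS: dict[str, dict] = {
    "svm": {"C": 1.0, "gamma": "scale"},
    "knn": {"n_neighbors": 5, "metric": "euclidean"},
    "nb": {"var_smoothing": 1e-9},
    "dt": {"max_depth": 10, "criterion": "gini"},
}

# name -> (type, low, high) or (categorical, choices); log-scaled where noted
SEARCH_SPACES: dict[str, list[tuple]] = {
    "svm": [("C", "log", 1e-3, 1e3), ("gamma", "log", 1e-3, 1e3)],
    "knn": [("n_neighbors", "logint", 1, 50),
            ("metric", "cat", ["euclidean", "cityblock"])],
    "nb": [("var_smoothing", "log", 1e-12, 1e-6)],
    "dt": [("max_depth", "int", 1, 30), ("criterion", "cat", ["gini", "entropy"])],
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration; ``build()`` yields a fresh sklearn
    estimator."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; "
                             f"choose from {MODEL_KINDS}")

    def build(self):
        p = {**_DEFAULT_PARAMS[self.kind], **self.params}
        if self.kind == "svm":
            return SVC(kernel="rbf", C=p["C"], gamma=p["gamma"],
                       random_state=self.seed)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=int(p["n_neighbors"]),
                                        metric=p["metric"])
        if self.kind == "nb":
            return GaussianNB(var_smoothing=p["var_smoothing"])
        return DecisionTreeClassifier(
            max_depth=p["max_depth"], criterion=p["criterion"],
            random_state=self.seed)


@dataclass
class SelectionResult:
    """Outcome of forward sequential feature selection: the ordered selected
    feature names, the CV-misclassification trace after each addition, and
    why the search stopped (``tolerance`` or ``exhausted``)."""

    selected: list[str]
    trace: list[float]
    stop_reason: str


@dataclass
class TuningResult:
    spec: ClassifierSpec
    score: float          # best CV misclassification rate found
    history: list[tuple[dict, float]]
    exhausted: bool = True


def _as_xy(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)


def cv_misclassification(X, y, spec: ClassifierSpec, folds: int = 5,
                         seed: int = 0, return_folds: bool = False):
    """Stratified k-fold CV misclassification rate: total errors over all
    held-out folds divided by n. Optionally returns the fold assignment."""
    Xa, ya = _as_xy(X), np.asarray(y)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    n = len(ya)
    if n < folds:
        raise ValueError(f"n={n} smaller than folds={folds}")
    _, counts = np.unique(ya, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()} rows) cannot be stratified "
            f"into {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = 0
    assignment = np.empty(n, dtype=int)
    for k, (tr, te) in enumerate(skf.split(Xa, ya)):
        clf = spec.build()
        clf.fit(Xa[tr], ya[tr])
        errors += int(np.sum(clf.predict(Xa[te]) != ya[te]))
        assignment[te] = k
    rate = errors / n
    return (rate, assignment) if return_folds else rate


def forward_sfs(X, y, spec: ClassifierSpec | None = None, folds: int = 5,
                tol: float = 1e-4, max_features: int | None = None,
                seed: int = 0) -> SelectionResult:
    """Greedy wrapper forward selection.

    Starting from the empty set, each step evaluates the CV
    misclassification of the current set plus each unused feature and adds
    the best one (ties break to the lowest column index). The search stops
    when the best improvement falls below ``tol`` or ``max_features`` is
    reached. The first step is measured against the majority-class error
    rate.
    """
    spec = spec or ClassifierSpec("knn")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    names = list(Xdf.columns)
    ya = np.asarray(y)
    max_features = max_features or len(names)

    _, counts = np.unique(ya, return_counts=True)
    current_rate = 1.0 - counts.max() / len(ya)   # no-feature baseline
    selected: list[str] = []
    trace: list[float] = []
    stop_reason = "exhausted"
    remaining = list(range(len(names)))

    while remaining and len(selected) < max_features:
        rates = np.array([
            cv_misclassification(
                Xdf[selected + [names[j]]], ya, spec, folds=folds, seed=seed)
            for j in remaining])
        best_pos = int(np.argmin(rates))          # ties -> lowest column index
        best_rate = float(rates[best_pos])
        if current_rate - best_rate < tol:
            stop_reason = "tolerance"
            break
        selected.append(names[remaining[best_pos]])
        trace.append(best_rate)
        current_rate = best_rate
        del remaining[best_pos]
    return SelectionResult(selected=selected, trace=trace,
                           stop_reason=stop_reason)


# ---------------------------------------------------------------------------
# sequential model-based hyperparameter optimization

def _encode(space: list[tuple], params: dict) -> np.ndarray:
    u = []
    for dim in space:
        name, kind = dim[0], dim[1]
        if kind == "cat":
            choices = dim[2]
            u.append(choices.index(params[name]) / max(len(choices) - 1, 1))
        elif kind in ("log", "logint"):
            lo, hi = np.log(dim[2]), np.log(dim[3])
            u.append((np.log(params[name]) - lo) / (hi - lo))
        else:  # int / float linear
            lo, hi = dim[2], dim[3]
            u.append((params[name] - lo) / (hi - lo))
    return np.array(u)


def _decode(space: list[tuple], u: np.ndarray) -> dict:
    params = {}
    for val, dim in zip(u, space):
        name, kind = dim[0], dim[1]
        if kind == "cat":
            choices = dim[2]
            params[name] = choices[int(round(val * (len(choices) - 1)))]
        elif kind == "log":
            lo, hi = np.log(dim[2]), np.log(dim[3])
            params[name] = float(np.exp(lo + val * (hi - lo)))
        elif kind == "logint":
            lo, hi = np.log(dim[2]), np.log(dim[3])
            params[name] = int(round(np.exp(lo + val * (hi - lo))))
        else:
            lo, hi = dim[2], dim[3]
            params[name] = int(round(lo + val * (hi - lo)))
    return params


def tune_hyperparameters(X, y, kind: str, budget: int = 30, seed: int = 0,
                         folds: int = 5) -> TuningResult:
    """Bayesian (GP expected-improvement) search for the classifier
    hyperparameters minimizing the CV misclassification rate.

    A third of the budget seeds the surrogate with random draws from the
    bounded space; the rest greedily evaluates the expected-improvement
    maximizer over a random candidate set. Deterministic for a fixed seed.
    """
    if budget < 5:
        raise ValueError("budget must be >= 5")
    if len(np.unique(np.asarray(y))) < 2:
        raise ValueError("need at least two classes to tune against")
    space = SEARCH_SPACES[kind]
    rng = np.random.default_rng(seed)

    def objective(u: np.ndarray) -> float:
        spec = ClassifierSpec(kind, _decode(space, u), seed=seed)
        return cv_misclassification(X, y, spec, folds=folds, seed=seed)

    n_init = max(5, budget // 3)
    U = [rng.uniform(0, 1, len(space)) for _ in range(min(n_init, budget))]
    scores = [objective(u) for u in U]
    kernel = ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
    while len(U) < budget:
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                      normalize_y=True,
                                      random_state=seed)
        gp.fit(np.array(U), np.array(scores))
        u_best = U[int(np.argmin(scores))]
        local = np.clip(u_best + rng.normal(0, 0.05, size=(64, len(space))),
                        0, 1)
        cand = np.vstack([rng.uniform(0, 1, size=(448, len(space))), local])
        mu, sd = gp.predict(cand, return_std=True)
        best = min(scores)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (best - mu) / sd
            ei = np.where(sd > 0, (best - mu) * norm.cdf(z) + sd * norm.pdf(z), 0.0)
        u_next = cand[int(np.argmax(ei))]
        U.append(u_next)
        scores.append(objective(u_next))

    i_best = int(np.argmin(scores))
    history = [(_decode(space, u), s) for u, s in zip(U, scores)]
    return TuningResult(
        spec=ClassifierSpec(kind, _decode(space, U[i_best]), seed=seed),
        score=float(scores[i_best]), history=history, exhausted=True)


# ---------------------------------------------------------------------------
# leave-one-subject-out evaluation

CLASSES = (1, 2, 3)


@dataclass
class EvaluationReport:
    """Per-model LOSOCV outcome: per-class accuracies (%) pooled over all
    held-out predictions, average accuracy (%) = mean of the per-subject
    accuracies, and one confusion matrix per held-out subject."""

    models: dict[str, dict]
    settings: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.models.items():
            rows.append({
                "model": name,
                "low_acc_pct": m["per_class"][1],
                "moderate_acc_pct": m["per_class"][2],
                "high_acc_pct": m["per_class"][3],
                "average_acc_pct": m["average"],
            })
        return pd.DataFrame(rows).set_index("model")

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        Path(path).write_text(json.dumps(
            {"models": self.models, "settings": self.settings},
            indent=2, default=default))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    m = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[int(t) - 1, int(p) - 1] += 1
    return m


def losocv_evaluate(table: FeatureTable, specs: list[ClassifierSpec],
                    feature_subset: list[str] | None = None,
                    leakage_mode: str = "paper", k_neighbors: int = 5,
                    seed: int = 0, smote: bool = True) -> EvaluationReport:
    """Leave-one-subject-out evaluation of one or more classifiers.

    ``table`` is the raw (unnormalized, unbalanced) cycle-level feature
    table. In ``paper`` mode the whole table is normalized and
    SMOTE-balanced before splitting by subject (synthetic rows inherit their
    base row's subject and are evaluated with it). In ``strict`` mode
    normalization scales and SMOTE are fitted on each training fold only and
    the held-out subject is scored on its real rows.
    """
    if leakage_mode not in ("paper", "strict"):
        raise ValueError("leakage_mode must be 'paper' or 'strict'")
    subjects = np.unique(table.subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for LOSOCV")
    cols = feature_subset or list(table.X.columns)
    missing = set(cols) - set(table.X.columns)
    if missing:
        raise ValueError(f"unknown features: {sorted(missing)}")

    if leakage_mode == "paper":
        normed = normalize_columns(table)
        data = LabeledDataset.from_feature_table(normed)
        if smote:
            data = smote_balance(data, k_neighbors=k_neighbors, seed=seed)

    models: dict[str, dict] = {}
    for spec in specs:
        per_subject_acc = []
        confusions = {}
        pooled_true, pooled_pred = [], []
        for s in subjects:
            if leakage_mode == "paper":
                tr = data.subjects != s
                te = ~tr
                X_tr, y_tr = data.X.loc[tr, cols], data.y[tr]
                X_te, y_te = data.X.loc[te, cols], data.y[te]
            else:
                tr_mask = table.subjects != s
                train_raw = FeatureTable(
                    X=table.X.loc[tr_mask].reset_index(drop=True),
                    y=table.y[tr_mask], subjects=table.subjects[tr_mask])
                train = normalize_columns(train_raw)
                test_raw = FeatureTable(
                    X=table.X.loc[~tr_mask].reset_index(drop=True),
                    y=table.y[~tr_mask], subjects=table.subjects[~tr_mask])
                test = normalize_columns(test_raw, reference=train)
                tdata = LabeledDataset.from_feature_table(train)
                if smote:
                    tdata = smote_balance(tdata, k_neighbors=k_neighbors,
                                          seed=seed)
                X_tr, y_tr = tdata.X[cols], tdata.y
                X_te, y_te = test.X[cols], test.y

            present = np.unique(y_te)
            if len(present) < 3:
                log.warning("subject %s is missing class(es) %s in test",
                            s, sorted(set(CLASSES) - set(present.tolist())))
            clf = spec.build()
            clf.fit(X_tr.to_numpy(float), y_tr)
            pred = clf.predict(X_te.to_numpy(float))
            per_subject_acc.append(float(np.mean(pred == y_te)))
            confusions[int(s)] = _confusion(y_te, pred)
            pooled_true.append(y_te)
            pooled_pred.append(pred)

        y_all = np.concatenate(pooled_true)
        p_all = np.concatenate(pooled_pred)
        per_class = {}
        for c in CLASSES:
            mask = y_all == c
            per_class[c] = (100.0 * float(np.mean(p_all[mask] == c))
                            if mask.any() else float("nan"))
        models[spec.kind] = {
            "per_class": per_class,
            "average": 100.0 * float(np.mean(per_subject_acc)),
            "per_subject_accuracy": {int(s): 100.0 * a for s, a
                                     in zip(subjects, per_subject_acc)},
            "confusions": {s: m for s, m in confusions.items()},
        }
    return EvaluationReport(models=models, settings={
        "leakage_mode": leakage_mode, "seed": seed,
        "features": cols, "smote": smote, "k_neighbors": k_neighbors,
    })


def single_feature_accuracy_ranking(X, y, spec: ClassifierSpec | None = None,
                                    folds: int = 5, seed: int = 0,
                                    ) -> list[tuple[str, float]]:
    """Accuracy (%) of the classifier using each feature alone, sorted
    descending; ties break alphabetically by feature name."""
    spec = spec or ClassifierSpec("knn")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    out = []
    for name in Xdf.columns:
        rate = cv_misclassification(Xdf[[name]], y, spec, folds=folds, seed=seed)
        out.append((str(name), 100.0 * (1.0 - rate)))
    return sorted(out, key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# model / results front end

class SaddleHeightModel:
    """Saddle-height level classifier built from a cycle-level feature table.

    Parameters
    ----------
    table : FeatureTable
        Raw (unnormalized) 81-column feature table with labels 1/2/3 and
        subject ids.

    ``fit()`` runs the full estimation pipeline — normalization, SMOTE,
    wrapper forward feature selection, optional hyperparameter tuning and
    leave-one-subject-out evaluation — and returns a
    :class:`SaddleHeightResults`.
    """

    def __init__(self, table: FeatureTable):
        if table.is_normalized:
            raise ValueError("pass the raw feature table; normalization is "
                             "part of fit()")
        self.table = table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SaddleHeightModel":
        from saddlefit.features import FEATURE_NAMES
        return cls(FeatureTable(X=df[FEATURE_NAMES],
                                y=df["label"].to_numpy(),
                                subjects=df["subject_id"].to_numpy()))

    def fit(self, models: tuple[str, ...] = MODEL_KINDS,
            selection_model: str = "knn", folds: int = 5, tol: float = 1e-4,
            max_features: int | None = 20, leakage_mode: str = "paper",
            tune: bool = False, budget: int = 30, k_neighbors: int = 5,
            seed: int = 0, smote: bool = True) -> "SaddleHeightResults":
        table = self.table
        normed = normalize_columns(table)
        data = LabeledDataset.from_feature_table(normed)
        if smote:
            data = smote_balance(data, k_neighbors=k_neighbors, seed=seed)

        selection = forward_sfs(
            data.X, data.y, ClassifierSpec(selection_model, seed=seed),
            folds=folds, tol=tol, max_features=max_features, seed=seed)
        subset = selection.selected or list(table.X.columns)

        specs = []
        tuning: dict[str, TuningResult] = {}
        for kind in models:
            if tune:
                res = tune_hyperparameters(
                    data.X[subset], data.y, kind, budget=budget, seed=seed,
                    folds=folds)
                tuning[kind] = res
                specs.append(res.spec)
            else:
                specs.append(ClassifierSpec(kind, seed=seed))

        report = losocv_evaluate(
            table, specs, feature_subset=subset, leakage_mode=leakage_mode,
            k_neighbors=k_neighbors, seed=seed, smote=smote)
        ranking = single_feature_accuracy_ranking(
            data.X[subset], data.y, ClassifierSpec(selection_model, seed=seed),
            folds=folds, seed=seed)
        return SaddleHeightResults(model=self, selection=selection,
                                   report=report, ranking=ranking,
                                   tuning=tuning, seed=seed)


@dataclass
class SaddleHeightResults:
    """Fitted-pipeline results: the selected feature set with its search
    trace, LOSOCV accuracies per model, and the single-feature accuracy
    ranking of the selected set."""

    model: SaddleHeightModel
    selection: SelectionResult
    report: EvaluationReport
    ranking: list[tuple[str, float]]
    tuning: dict[str, TuningResult]
    seed: int

    def summary(self) -> str:
        lines = []
        lines.append("Saddle-height classification (LOSOCV)")
        lines.append("=" * 61)
        n = len(self.model.table)
        subs = len(np.unique(self.model.table.subjects))
        lines.append(f"cycles: {n:>6d}    subjects: {subs:>3d}    "
                     f"mode: {self.report.settings['leakage_mode']}")
        lines.append(f"selected features ({len(self.selection.selected)}, "
                     f"stop: {self.selection.stop_reason}):")
        for name, rate in zip(self.selection.selected, self.selection.trace):
            lines.append(f"  {name:<28s} cv misclassification {rate:8.4f}")
        lines.append("-" * 61)
        lines.append(f"{'model':<8s}{'low %':>10s}{'moderate %':>12s}"
                     f"{'high %':>10s}{'average %':>12s}")
        for name, m in self.report.models.items():
            lines.append(
                f"{name:<8s}{m['per_class'][1]:>10.2f}"
                f"{m['per_class'][2]:>12.2f}{m['per_class'][3]:>10.2f}"
                f"{m['average']:>12.2f}")
        lines.append("-" * 61)
        top = self.ranking[0]
        lines.append(f"best single feature: {top[0]} ({top[1]:.2f}% accurate "
                     f"alone)")
        return "\n".join(lines)
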