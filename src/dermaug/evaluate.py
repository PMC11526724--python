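"""Experimental harness: cross-validated model search and the IR sweep.

The study design this harness implements: for each of several repeated
stratified 80/20 train/test splits, fit ensemble feature selection on the
training rows only, oversample the training minority class to each target
balance ratio r, choose hyperparameters by stratified 5-fold cross-validation
on the (augmented) training set with AUCROC as the figure of merit, then
evaluate on the untouched real test rows.  Reported numbers are mean +/- std
over the repeats (not over CV folds).

Four classifier families are searched:

* ``lasso`` -- L1-penalised logistic regression scored by predicted
  probability, C over 10 log-spaced points in [10^-1.5, 10^0.4];
* ``knn``  -- K in 1..11;
* ``svm``  -- RBF kernel, gamma in {1e-2, 1e-3, 1e-4, 1e-5} and C over 10
  log-spaced points in [10^-0.9, 10^0.9];
* ``dt``   -- max depth 2..8, minimum samples per split scaled to the
  training-set size.

Grid ties are broken toward the smaller-complexity setting (more
regularisation, smaller K, smaller depth).  Features are z-scored with
training statistics inside every fit.  Sensitivity/specificity use the 0.5
probability threshold (the model's ``predict``); melanoma (label 1) is the
positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .augment import augment_to_ratio
from .datatypes import SOURCE_REAL, FeatureTable
from .errors import ValidationError
from .selection import BootstrapConfig, ensemble_select

MODELS = ("lasso", "knn", "svm", "dt")
METRICS = ("aucroc", "sensitivity", "specificity", "accuracy", "f1")

_N_CONTINUOUS = 10  # log-spaced points per continuous range


def model_grid(model_id: str, n_train: int | None = None) -> list[dict]:
    """Hyperparameter grid in complexity order (most regularised first)."""
    if model_id == "lasso":
        return [{"C": c} for c in np.logspace(-1.5, 0.4, _N_CONTINUOUS)]
    if model_id == "knn":
        # smaller K preferred on ties -> K ascending
        return [{"K": k} for k in range(1, 12)]
    if model_id == "svm":
        return [{"C": c, "gamma": g}
                for c in np.logspace(-0.9, 0.9, _N_CONTINUOUS)
                for g in (1e-2, 1e-3, 1e-4, 1e-5)]
    if model_id == "dt":
        mss = 2 if n_train is None else max(2, n_train // 50)
        return [{"max_depth": d, "min_samples_split": mss} for d in range(2, 9)]
    raise ValidationError(f"model: unknown model id {model_id!r}")


def build_model(model_id: str, params: dict, seed: int = 0):
    """Instantiate one grid point; distance-based models get a z-scaler."""
    if model_id == "lasso":
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                 C=params["C"], max_iter=2000, random_state=seed)
    elif model_id == "knn":
        clf = KNeighborsClassifier(n_neighbors=params["K"])
    elif model_id == "svm":
        clf = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                  random_state=seed)
    elif model_id == "dt":
        return DecisionTreeClassifier(max_depth=params["max_depth"],
                                      min_samples_split=params["min_samples_split"],
                                      random_state=seed)
    else:
        raise ValidationError(f"model: unknown model id {model_id!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def cv_search(model_id: str, X_train, y_train, k: int = 5, seed: int = 0) -> dict:
    """Best grid point by mean validation AUCROC over stratified k folds.

    Ties keep the earlier (smaller-complexity) grid point.  Raises when a
    class has fewer than ``k`` samples.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2:
        raise ValidationError("y: cv_search needs both classes")
    if counts.min() < k:
        raise ValidationError(
            f"y: smallest class has {counts.min()} samples < k={k}; use a smaller k")

    folds = list(StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                 .split(X, y))
    best_params, best_auc = None, -np.inf
    for params in model_grid(model_id, n_train=len(X)):
        aucs = []
        for tr, va in folds:
            model = build_model(model_id, params, seed=seed)
            model.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[va], _scores(model, X[va])))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc + 1e-12:  # strict improvement keeps first max
            best_auc, best_params = mean_auc, params
    return dict(best_params)


def evaluate_split(model, X_test, y_test) -> dict[str, float]:
    """AUCROC, sensitivity, specificity, accuracy, F1 on one test set.

    Melanoma (label 1) is the positive class; sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).
    """
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test)
    if len(np.unique(y)) < 2:
        raise ValidationError("y_test: both classes required to evaluate")
    scores = _scores(model, X)
    pred = np.asarray(model.predict(X))
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "aucroc": float(roc_auc_score(y, scores)),
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": float((pred == y).mean()),
        "f1": f1,
    }


@dataclass
class ExperimentResult:
    """Per (model, oversampler, r): metric mean/std over repeats + bookkeeping."""

    records: list[dict] = field(default_factory=list)

    def add(self, model: str, method: str, r: float, per_repeat: list[dict],
            chosen: list[dict], seeds: list[int]) -> None:
        entry = {"model": model, "method": method, "r": r,
                 "chosen_hyperparameters": chosen, "seeds": seeds}
        for metric in METRICS:
            vals = np.array([rep[metric] for rep in per_repeat])
            entry[f"{metric}_mean"] = float(vals.mean())
            entry[f"{metric}_std"] = float(vals.std())
        self.records.append(entry)

    def lookup(self, model: str, method: str, r: float) -> dict:
        for rec in self.records:
            if rec["model"] == model and rec["method"] == method \
                    and abs(rec["r"] - r) < 1e-9:
                return rec
        raise KeyError((model, method, r))

    def to_dict(self) -> dict:
        return {"records": self.records}


def ir_sweep_experiment(table: FeatureTable, models=("lasso",),
                        oversampler: str = "smote",
                        r_values=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
                        repeats: int = 5, cv_k: int = 5,
                        fs_config: BootstrapConfig | None = None,
                        top_t: int | None = None, k_final: int | None = None,
                        seed: int = 0, test_fraction: float = 0.2
                        ) -> ExperimentResult:
    """The full repeated train/test IR sweep; see module docstring.

    Feature selection runs before augmentation and only on training rows; test
    metrics are computed on real rows only.  The whole result is reproducible
    from ``seed``.
    """
    if any(src != SOURCE_REAL for src in table.source):
        raise ValidationError("source: the input table must contain only real rows")
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31))
                    for s in np.random.SeedSequence(seed).spawn(repeats)]

    X_all = table.features.to_numpy(dtype=float)
    y_all = table.labels.to_numpy()
    names = table.feature_names

    # collect per (model, r) lists over repeats
    collected: dict[tuple[str, float], list[dict]] = {}
    chosen_log: dict[tuple[str, float], list[dict]] = {}
    for rep_seed in repeat_seeds:
        idx_train, idx_test = train_test_split(
            np.arange(len(y_all)), test_size=test_fraction, stratify=y_all,
            random_state=rep_seed)
        X_tr, y_tr = X_all[idx_train], y_all[idx_train]
        X_te, y_te = X_all[idx_test], y_all[idx_test]

        if k_final is not None:
            cfg = fs_config or BootstrapConfig(M=50, seed=rep_seed)
            selected, _ = ensemble_select(X_tr, y_tr, cfg, top_t=top_t,
                                          k_final=k_final, feature_names=names)
            cols = [names.index(f) for f in selected]
        else:
            cols = list(range(len(names)))
        sel_names = [names[c] for c in cols]

        train_table = FeatureTable(
            dict(zip(sel_names, X_tr[:, cols].T)), y_tr,
            sample_ids=[f"r{rep_seed}_t{i}" for i in range(len(y_tr))])

        for r in r_values:
            augmented = augment_to_ratio(train_table, method=oversampler, r=r,
                                         seed=rep_seed)
            X_aug = augmented.features.to_numpy(dtype=float)
            y_aug = augmented.labels.to_numpy()
            for model_id in models:
                params = cv_search(model_id, X_aug, y_aug, k=cv_k, seed=rep_seed)
                model = build_model(model_id, params, seed=rep_seed)
                model.fit(X_aug, y_aug)
                metrics = evaluate_split(model, X_te[:, cols], y_te)
                collected.setdefault((model_id, r), []).append(metrics)
                chosen_log.setdefault((model_id, r), []).append(params)

    result = ExperimentResult()
    for (model_id, r), reps in collected.items():
        result.add(model_id, oversampler, r, reps,
                   chosen_log[(model_id, r)], repeat_seeds)
    return result
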