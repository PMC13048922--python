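"""Occurrence classifiers and their bootstrap evaluation protocol.

Two model families score a pixel/waypoint feature vector for buffel-grass
presence:

* a logistic regression built by forward stepwise selection under the
  Bayesian Information Criterion (the mapping model: parsimonious, and its
  coefficients transfer directly to the per-pixel probability surface), and
* a small neural network (one hidden layer of three tanh nodes over all 24
  features) used as a nonlinearity check.

Evaluation repeats a stratified two-thirds/one-third train/validation split
``n_boot`` times (ten by default) and reports mean +/- standard error of
sensitivity, specificity, accuracy and ROC-AUC for both roles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.exceptions import ConvergenceWarning


# ---------------------------------------------------------------------------
# logistic model container

@dataclass
class LogisticModel:
    """Fitted logistic model: P(presence) = 1 / (1 + exp(-(b0 + sum b_i x_i)))."""

    intercept: float
    coefficients: dict
    selected_features: list
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("logistic coefficients must be finite")

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ValueError(f"feature column(s) missing from table: {missing}")
        lin = np.full(len(X), self.intercept, dtype=float)
        for f in self.selected_features:
            lin += self.coefficients[f] * X[f].to_numpy(dtype=float)
        return lin

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Presence probability per row (standard rising-logistic convention)."""
        lin = self.linear_predictor(X)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-lin))

    def to_json(self) -> str:
        return json.dumps({
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "selected_features": self.selected_features,
            "fit_metadata": self.fit_metadata,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        return cls(d["intercept"], d["coefficients"], d["selected_features"],
                   d.get("fit_metadata", {}))


def _bic(llf: float, n_params: int, n_obs: int) -> float:
    return n_params * np.log(n_obs) - 2.0 * llf


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit with a ridge fallback on separation.

    X excludes the constant column.  Returns (params, llf, ridged) with
    params = [intercept, coefs...].
    """
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 1e8:
            return params, float(res.llf), False
    except Exception:
        pass
    # (quasi-)separation: refit with a small L2 penalty
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
    clf.fit(X if X.shape[1] else np.zeros((len(y), 1)), y)
    if X.shape[1]:
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        p = clf.predict_proba(X)[:, 1]
    else:
        params = np.array([clf.intercept_[0], 0.0][:1])
        p = np.full(len(y), np.mean(y))
    eps = 1e-12
    llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return params, llf, True


def _intercept_only(y: np.ndarray):
    n, n1 = len(y), int(np.sum(y))
    if n1 == 0 or n1 == n:
        raise ValueError("need both classes present to fit a logistic model")
    p = n1 / n
    llf = n1 * np.log(p) + (n - n1) * np.log(1 - p)
    return float(np.log(p / (1 - p))), float(llf)


def stepwise_logistic(features: pd.DataFrame, labels, criterion: str = "bic") -> LogisticModel:
    """Forward stepwise logistic regression under BIC.

    Starting from the intercept-only model, the candidate feature whose
    addition gives the lowest BIC enters at each round; selection stops as
    soon as no addition strictly lowers BIC.  Ties resolve to the first
    feature in column order.  Constant-valued candidates are dropped with a
    warning; (quasi-)separated fits fall back to a lightly ridged refit and
    are flagged in the metadata.
    """
    if criterion.lower() != "bic":
        raise ValueError("only BIC-guided selection is supported")
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y[~np.isnan(y)])) != 2 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1 with both classes present")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 observations per class")

    candidates = list(features.columns)
    const = [c for c in candidates if features[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant feature(s): {const}", stacklevel=2)
        candidates = [c for c in candidates if c not in const]

    n = len(y)
    b0, llf0 = _intercept_only(y)
    current_bic = _bic(llf0, 1, n)
    selected: list = []
    trajectory = [{"added": None, "bic": current_bic}]
    ridged = False

    while candidates:
        bics = np.empty(len(candidates))
        fits = []
        for i, cand in enumerate(candidates):
            X = features[selected + [cand]].to_numpy(dtype=float)
            params, llf, rd = _fit_logit(X, y)
            bics[i] = _bic(llf, len(params), n)
            fits.append((params, rd))
        best = int(np.argmin(bics))
        if bics[best] < current_bic - 1e-9:
            cand = candidates.pop(best)
            selected.append(cand)
            current_bic = float(bics[best])
            best_params, rd = fits[best]
            ridged = ridged or rd
            trajectory.append({"added": cand, "bic": current_bic})
        else:
            break

    if selected:
        params, _, rd = _fit_logit(features[selected].to_numpy(dtype=float), y)
        ridged = ridged or rd
        intercept = float(params[0])
        coefs = {f: float(b) for f, b in zip(selected, params[1:])}
    else:
        intercept, coefs = b0, {}
    return LogisticModel(
        intercept=intercept,
        coefficients=coefs,
        selected_features=selected,
        fit_metadata={"criterion": "bic", "bic_trajectory": trajectory,
                      "ridge_fallback": ridged, "dropped_constant": const},
    )


# ---------------------------------------------------------------------------
# neural-net comparator

@dataclass(frozen=True)
class NeuralNetSpec:
    """Architecture of the comparator network: 24 -> 3 (tanh) -> 1 (sigmoid)."""

    hidden_layers: int = 1
    hidden_nodes: int = 3
    activation: str = "tanh"

    def __post_init__(self):
        if self.hidden_layers != 1:
            warnings.warn("reference architecture uses a single hidden layer",
                          stacklevel=2)


@dataclass
class NeuralNetModel:
    pipeline: object
    feature_names: list
    converged: bool
    spec: NeuralNetSpec

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict_proba(X[self.feature_names].to_numpy(dtype=float))[:, 1]


def fit_neural_net(features: pd.DataFrame, labels, spec: NeuralNetSpec | None = None,
                   seed: int = 0) -> NeuralNetModel:
    """Train the tanh-hidden-layer network on all supplied features.

    Inputs are standardised; training is full-batch L-BFGS to tolerance
    1e-6 with a seeded initialisation, so refits with the same seed are
    identical.  Non-convergence is flagged on the returned model (the best
    iterate is still returned).
    """
    spec = spec or NeuralNetSpec()
    y = np.asarray(labels, dtype=int)
    net = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_nodes,) * spec.hidden_layers,
        activation=spec.activation, solver="lbfgs",
        alpha=1e-4, max_iter=5000, tol=1e-6, random_state=seed,
    )
    pipe = make_pipeline(StandardScaler(), net)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            pipe.fit(features.to_numpy(dtype=float), y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                pipe.fit(features.to_numpy(dtype=float), y)
    return NeuralNetModel(pipeline=pipe, feature_names=list(features.columns),
                          converged=converged, spec=spec)


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity/specificity/accuracy; a metric is None when its
    denominator is empty (e.g. sensitivity with no true positives in truth)."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_metrics(predicted, labels) -> ConfusionMetrics:
    yhat = np.asarray(predicted).astype(bool)
    y = np.asarray(labels).astype(bool)
    if yhat.shape != y.shape:
        raise ValueError("predicted and labels differ in length")
    tp = int(np.sum(yhat & y))
    fp = int(np.sum(yhat & ~y))
    tn = int(np.sum(~yhat & ~y))
    fn = int(np.sum(~yhat & y))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    acc = (tp + tn) / y.size if y.size else None
    return ConfusionMetrics(sens, spec, acc, tp, fp, tn, fn)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random presence scores above a random
    absence, with half credit for ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def select_threshold(scores, labels, objective: str = "youden") -> float:
    """Probability cut-point optimising the presence/absence trade-off.

    ``youden`` maximises J = sensitivity + specificity - 1 over the observed
    scores used as >=-thresholds; ``min_error`` minimises FP + FN.  Exact
    ties resolve to the candidate nearest 0.5.  Degenerate all-equal scores
    return 0.5 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("select_threshold requires both classes present")
    cuts = np.unique(s)
    if cuts.size == 1:
        warnings.warn("all scores identical; returning threshold 0.5", stacklevel=2)
        return 0.5
    best_obj, best_t = -np.inf, None
    for t in cuts:
        m = confusion_metrics(s >= t, y)
        if objective == "youden":
            obj = (m.sensitivity or 0.0) + (m.specificity or 0.0) - 1.0
        elif objective == "min_error":
            obj = -(m.fp + m.fn)
        else:
            raise ValueError(f"unknown objective {objective!r}")
        if obj > best_obj + 1e-12 or (abs(obj - best_obj) <= 1e-12
                                      and abs(t - 0.5) < abs(best_t - 0.5)):
            best_obj, best_t = obj, float(t)
    return best_t


# ---------------------------------------------------------------------------
# bootstrap protocol

@dataclass
class EvaluationReport:
    """Mean +/- SE of each metric per split role over the bootstraps.

    ``metrics`` maps role ('training'/'validation') -> metric name ->
    (mean, se); SE is the bootstrap standard deviation / sqrt(n_boot).
    """

    metrics: dict
    per_boot: pd.DataFrame
    n_boot: int
    train_fraction: float
    n_resplits: int = 0
    model_name: str = "model"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, md in self.metrics.items():
            row = {"model": self.model_name, "role": role}
            for metric, (mean, se) in md.items():
                row[f"{metric}_mean"] = mean
                row[f"{metric}_se"] = se
            rows.append(row)
        return pd.DataFrame(rows)


_METRICS = ("sensitivity", "specificity", "accuracy", "auc")


def bootstrap_evaluate(fitter, features: pd.DataFrame, labels, n_boot: int = 10,
                       train_fraction: float = 2.0 / 3.0, seed: int = 0,
                       threshold: float = 0.5, model_name: str = "model") -> EvaluationReport:
    """Repeated stratified split evaluation.

    Each bootstrap draws a fresh stratified train/validation split
    (two-thirds/one-third by default), refits the model via ``fitter(X, y)``
    and scores both roles at the given probability threshold.  A split whose
    validation set collapses to one class is redrawn (counted in
    ``n_resplits``).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    records = []
    n_resplits = 0
    for b in range(n_boot):
        for _attempt in range(100):
            split_seed = int(rng.integers(0, 2**31 - 1))
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)), train_size=train_fraction,
                stratify=y, random_state=split_seed)
            if len(np.unique(y[idx_va])) == 2 and len(np.unique(y[idx_tr])) == 2:
                break
            n_resplits += 1
        else:
            raise RuntimeError("could not draw a two-class validation split")
        model = fitter(features.iloc[idx_tr], y[idx_tr])
        for role, idx in (("training", idx_tr), ("validation", idx_va)):
            scores = np.asarray(model.predict(features.iloc[idx]), dtype=float)
            cm = confusion_metrics(scores >= threshold, y[idx])
            records.append({
                "bootstrap": b, "role": role,
                "sensitivity": cm.sensitivity, "specificity": cm.specificity,
                "accuracy": cm.accuracy, "auc": roc_auc(scores, y[idx]),
            })
    per_boot = pd.DataFrame(records)
    metrics = {}
    for role in ("training", "validation"):
        sub = per_boot[per_boot["role"] == role]
        md = {}
        for m in _METRICS:
            vals = sub[m].to_numpy(dtype=float)
            mean = float(np.nanmean(vals))
            sd = float(np.nanstd(vals, ddof=1)) if n_boot > 1 else 0.0
            md[m] = (mean, sd / np.sqrt(n_boot))
        metrics[role] = md
    return EvaluationReport(metrics=metrics, per_boot=per_boot, n_boot=n_boot,
                            train_fraction=train_fraction,
                            n_resplits=n_resplits, model_name=model_name)
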