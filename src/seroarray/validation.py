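"""ELISA-panel group tests and the multi-antigen logistic classifier.

The validation cohort measures serum IgG binding to each candidate antigen
as OD at 405 nm.  Per-antigen group differences use the unpaired t-test;
the diagnostic panel is evaluated with a logistic regression over all
antigens (features standardized internally, maximum likelihood by
Newton-Raphson IRLS) and reported as an ROC/AUC plus the full confusion
matrix and derived metrics.  Evaluation is in-sample — apparent
performance, not cross-validated transfer.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .differential import ttest_unpaired
from .errors import SeparationWarning, ValidationError

_GROUP_POSITIVE = "case"


@dataclass
class ElisaPanel:
    """Samples x antigens OD(405 nm) matrix with sample metadata.

    ``od`` is indexed by sample_id with one column per antigen; ``samples``
    is indexed by sample_id and carries ``group`` (case/control) plus
    optional covariates such as ``sex``.
    """

    od: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.od.index.equals(self.samples.index):
            raise ValidationError("od rows do not match the sample table")
        if (self.od.to_numpy() < 0).any():
            raise ValidationError("OD values must be >= 0")
        groups = set(self.samples["group"])
        if not groups <= {"case", "control"}:
            raise ValidationError(f"group labels must be case/control, got {sorted(groups)}")

    @property
    def antigens(self) -> list[str]:
        return list(self.od.columns)

    @property
    def labels(self) -> np.ndarray:
        return (self.samples["group"] == _GROUP_POSITIVE).to_numpy(dtype=int)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElisaPanel":
        frame = pd.read_csv(path)
        meta_cols = [c for c in ("sample_id", "group", "sex") if c in frame.columns]
        if "sample_id" not in meta_cols or "group" not in meta_cols:
            raise ValidationError("ELISA CSV needs 'sample_id' and 'group' columns")
        frame = frame.set_index("sample_id")
        antigens = [c for c in frame.columns if c not in ("group", "sex")]
        return cls(od=frame[antigens].astype(float), samples=frame[[c for c in ("group", "sex") if c in frame.columns]])

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.samples, self.od], axis=1)
        out.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def elisa_group_test(panel: ElisaPanel, antigen: str, welch: bool = True) -> float:
    """Two-sided unpaired t-test of one antigen's OD between case and control."""
    if antigen not in panel.od.columns:
        raise ValidationError(f"unknown antigen {antigen!r}")
    values = panel.od[antigen]
    case = values[panel.samples["group"] == "case"]
    ctrl = values[panel.samples["group"] == "control"]
    return ttest_unpaired(case, ctrl, welch=welch)


def covariate_check(
    panel: ElisaPanel, covariate: str = "sex", welch: bool = True
) -> pd.Series:
    """Per-antigen unpaired t of OD across the two levels of a covariate."""
    if covariate not in panel.samples.columns:
        raise ValidationError(f"covariate {covariate!r} missing from sample table")
    values = panel.samples[covariate].dropna()
    levels = sorted(values.unique())
    if len(levels) != 2:
        raise ValidationError(
            f"covariate {covariate!r} must have exactly 2 levels, found {levels}"
        )
    a_ids = values.index[values == levels[0]]
    b_ids = values.index[values == levels[1]]
    return pd.Series(
        {
            antigen: ttest_unpaired(
                panel.od.loc[a_ids, antigen], panel.od.loc[b_ids, antigen], welch=welch
            )
            for antigen in panel.antigens
        },
        name=f"p_{covariate}",
    )


# ---------------------------------------------------------------------------
# logistic classifier
# ---------------------------------------------------------------------------

def _newton_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, bool, bool, int]:
    """Newton-Raphson IRLS for logistic MLE.

    Convergence when max |score| < tol.  Complete separation shows up as
    coefficient-norm divergence; it is flagged and iteration continues to
    the cap so a (boundary-chasing) fit is still returned.
    """
    n, p = X.shape
    beta = np.zeros(p)
    separation = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = X.T @ (w[:, None] * X) + 1e-10 * np.eye(p)
        beta = beta + np.linalg.solve(H, score)
        # on standardized features a coefficient this size means the fitted
        # probabilities have saturated: the MLE is off at infinity
        if np.max(np.abs(beta)) > 15.0:
            separation = True
    return beta, converged, separation, it


@dataclass
class LogisticFit:
    """Standardized-scale coefficients plus what is needed to predict."""

    coef: pd.Series  # index: ['intercept', antigen...]
    feature_means: pd.Series
    feature_sds: pd.Series
    dropped: list[str]
    converged: bool
    separation: bool
    n_iter: int

    def predict_proba(self, od: pd.DataFrame) -> np.ndarray:
        cols = [c for c in self.feature_means.index]
        Z = (od[cols] - self.feature_means) / self.feature_sds
        eta = self.coef["intercept"] + Z.to_numpy() @ self.coef[cols].to_numpy()
        return expit(eta)


def logistic_fit(
    panel: ElisaPanel, tol: float = 1e-8, max_iter: int = 100
) -> LogisticFit:
    """Fit the all-antigen logistic model (features standardized to mean 0, sd 1)."""
    y = panel.labels
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValidationError("logistic fit needs >= 2 samples per class")
    od = panel.od
    sds = od.std(axis=0, ddof=1)
    dropped = list(sds.index[sds <= 0])
    if dropped:
        warnings.warn(
            f"constant feature(s) dropped from logistic fit: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    keep = [c for c in od.columns if c not in dropped]
    means = od[keep].mean(axis=0)
    sd = sds[keep]
    Z = ((od[keep] - means) / sd).to_numpy()
    X = np.column_stack([np.ones(len(y)), Z])
    beta, converged, separation, n_iter = _newton_logistic(X, y.astype(float), tol, max_iter)
    if separation:
        warnings.warn(
            "complete separation detected; coefficients diverge",
            SeparationWarning,
            stacklevel=2,
        )
    coef = pd.Series(beta, index=["intercept"] + keep, name="coef")
    return LogisticFit(
        coef=coef,
        feature_means=means,
        feature_sds=sd,
        dropped=dropped,
        converged=converged,
        separation=separation,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# ROC / diagnostic metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney, ties half-credited)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, labels) -> pd.DataFrame:
    """Empirical ROC points (fpr, tpr, threshold), thresholds descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = labels.sum()
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(labels[order])
    fps = np.cumsum(1 - labels[order])
    # keep the last point of each tie block
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    thr = np.r_[np.inf, sorted_scores[distinct]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass
class DiagnosticMetrics:
    """Confusion counts plus exact-fraction and display-percent metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)
    accuracy: float | None = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"count {name} must be >= 0")
        self.sensitivity = _ratio(self.tp, self.tp + self.fn)
        self.specificity = _ratio(self.tn, self.tn + self.fp)
        self.ppv = _ratio(self.tp, self.tp + self.fp)
        self.npv = _ratio(self.tn, self.tn + self.fn)
        self.accuracy = _ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    def display(self) -> dict[str, int | None]:
        """Whole-percent metrics, rounded half away from zero; None when undefined."""
        return {
            name: None if value is None else _round_half_away(100.0 * value)
            for name, value in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("accuracy", self.accuracy),
            )
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from confusion counts."""
    return DiagnosticMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# whole-panel evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    """In-sample evaluation of the fitted antigen-panel classifier."""

    fit: LogisticFit
    threshold: float
    probabilities: pd.Series
    labels: np.ndarray
    auc: float
    metrics: DiagnosticMetrics

    @property
    def coefficients(self) -> pd.Series:
        return self.fit.coef

    def roc_points(self) -> pd.DataFrame:
        return roc_curve(self.probabilities.to_numpy(), self.labels)

    def summary(self) -> str:
        disp = self.metrics.display()
        lines = [
            "Antigen-panel logistic classifier (in-sample)",
            f"  AUC = {self.auc:.2f}   threshold = {self.threshold:g}",
            f"  confusion: tp={self.metrics.tp} fp={self.metrics.fp} "
            f"tn={self.metrics.tn} fn={self.metrics.fn}",
            "  sensitivity {sensitivity}%  specificity {specificity}%  "
            "PPV {ppv}%  NPV {npv}%  accuracy {accuracy}%".format(**disp),
        ]
        if self.fit.separation:
            lines.append("  WARNING: complete separation; coefficients not identifiable")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coefficients": {k: float(v) for k, v in self.fit.coef.items()},
            "auc": self.auc,
            "threshold": self.threshold,
            "counts": {
                "tp": self.metrics.tp,
                "fp": self.metrics.fp,
                "tn": self.metrics.tn,
                "fn": self.metrics.fn,
            },
            "metrics": {
                "sensitivity": self.metrics.sensitivity,
                "specificity": self.metrics.specificity,
                "ppv": self.metrics.ppv,
                "npv": self.metrics.npv,
                "accuracy": self.metrics.accuracy,
            },
            "metrics_percent": self.metrics.display(),
            "converged": self.fit.converged,
            "separation": self.fit.separation,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot_roc(self, ax=None):
        """Plot the empirical ROC curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        pts = self.roc_points()
        ax.plot(pts["fpr"], pts["tpr"], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {self.auc:.2f}")
        return ax


class ElisaClassifier:
    """Model object: logistic panel classifier over an :class:`ElisaPanel`."""

    def __init__(self, panel: ElisaPanel, threshold: float = 0.5) -> None:
        self.panel = panel
        self.threshold = float(threshold)

    def fit(self) -> ClassifierReport:
        fit = logistic_fit(self.panel)
        probs = fit.predict_proba(self.panel.od)
        y = self.panel.labels
        pred = probs >= self.threshold
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tn = int(np.sum(~pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        return ClassifierReport(
            fit=fit,
            threshold=self.threshold,
            probabilities=pd.Series(probs, index=self.panel.od.index, name="p_case"),
            labels=y,
            auc=roc_auc(probs, y),
            metrics=confusion_metrics(tp, fp, tn, fn),
        )


def classify(panel: ElisaPanel, threshold: float = 0.5) -> ClassifierReport:
    """Fit and evaluate the panel classifier in-sample."""
    return ElisaClassifier(panel, threshold=threshold).fit()


def cross_validated_auc(panel: ElisaPanel, k: int = 5, seed: int = 0) -> float:
    """Stratified k-fold out-of-sample AUC of the panel classifier.

    An honest generalization estimate; expect it below the in-sample AUC.
    """
    y = panel.labels
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValidationError(f"class {cls} has fewer than k={k} samples")
        folds[rng.permutation(idx)] = np.arange(idx.size) % k
    probs = np.empty(len(y))
    for fold in range(k):
        train = folds != fold
        sub = ElisaPanel(od=panel.od.loc[train], samples=panel.samples.loc[train])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = logistic_fit(sub)
        probs[~train] = fit.predict_proba(panel.od.loc[~train])
    return roc_auc(probs, y)
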