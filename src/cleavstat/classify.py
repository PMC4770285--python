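"""Decision layer: ROC analysis, stepwise logistic regression, stepwise LDA.

A single cleavage rule is used as a classifier by thresholding its K_stat
value; sweeping the threshold yields the ROC curve whose area (AUC) measures
predictor efficacy.  Rules whose K_stat runs *smaller* in the positive group
produce curves below the diagonal; their decision rule is inverted, which in
the combined logistic model happens automatically through negative
coefficient signs.  The combined model is built stepwise: a Mann–Whitney
prescreen removes rules with no significant group difference, survivors
enter in descending single-predictor Wald order, and entry stops when the
training AUC no longer improves appreciably.  Non-binary classifications use
stepwise linear discriminant analysis, entering at each round the predictor
that maximizes the Mahalanobis distance between the two closest groups.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

logger = logging.getLogger("cleavstat")

_COEF_CAP = 30.0        # |coefficient| bound flagged as complete separation
_IRLS_TOL = 1e-8
_IRLS_MAXITER = 100


# ---------------------------------------------------------------------------
# Rank statistics and ROC
# ---------------------------------------------------------------------------

def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U (A-side, midranks for ties) and two-sided p-value.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return a.size * b.size / 2.0, 1.0
    method = "exact" if (a.size * b.size <= 400
                         and np.unique(combined).size == combined.size) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve from sweeping a decision threshold over the scores."""

    points: np.ndarray   # (n_thresholds, 2): (false_alarm_rate, hit_rate)
    auc: float

    @property
    def orientation(self) -> str:
        return "below_diagonal" if self.auc < 0.5 else "above_diagonal"

    @property
    def efficacy(self) -> float:
        """Predictor efficacy irrespective of decision-rule direction."""
        return max(self.auc, 1.0 - self.auc)


def roc(scores_negative, scores_positive) -> RocCurve:
    """ROC curve and AUC for "score > threshold => positive".

    The AUC equals the tie-corrected fraction of (positive, negative) pairs
    with positive > negative (the Mann–Whitney rank identity).  A curve
    below the diagonal (AUC < 0.5) flags an inverted-rule predictor, whose
    efficacy is the area *above* the curve, ``1 - auc``.
    """
    neg = np.asarray(scores_negative, dtype=float)
    pos = np.asarray(scores_positive, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    thresholds = np.unique(np.concatenate([neg, pos]))
    # threshold below all scores first -> (1, 1); at the max -> (0, 0)
    fa = np.concatenate([[1.0], (neg[None, :] > thresholds[:, None]).mean(axis=1)])
    hit = np.concatenate([[1.0], (pos[None, :] > thresholds[:, None]).mean(axis=1)])
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    u_pos = ranks[neg.size:].sum() - pos.size * (pos.size + 1) / 2.0
    auc = u_pos / (neg.size * pos.size)
    return RocCurve(np.column_stack([fa, hit]), float(auc))


# ---------------------------------------------------------------------------
# Binary logistic regression
# ---------------------------------------------------------------------------

@dataclass
class BinaryLogisticModel:
    """Logistic model p = 1 / (1 + exp(-z)), z = b0 + sum_i b_i * K_i."""

    intercept: float
    coefficients: dict[str, float]          # rule notation -> b_i
    included_rules: list[str]               # ordered by entry
    p_threshold: float = 0.5
    wald: dict[str, float] = field(default_factory=dict)
    nagelkerke_r2: float = 0.0
    kstat_mode: str = "signed"
    separation: bool = False
    log_likelihood: float = 0.0

    def linear_score(self, row: Mapping[str, float]) -> float:
        try:
            return self.intercept + sum(
                self.coefficients[r] * float(row[r]) for r in self.included_rules
            )
        except KeyError as exc:
            raise KeyError(f"feature row lacks rule {exc.args[0]!r}") from None

    def to_json(self) -> str:
        return json.dumps({
            "type": "logistic",
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "included_rules": self.included_rules,
            "p_threshold": self.p_threshold,
            "wald": self.wald,
            "nagelkerke_r2": self.nagelkerke_r2,
            "kstat_mode": self.kstat_mode,
            "separation": self.separation,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BinaryLogisticModel":
        d = json.loads(text)
        if d.get("type") != "logistic":
            raise ValueError("not a logistic model file")
        return cls(
            intercept=d["intercept"], coefficients=d["coefficients"],
            included_rules=d["included_rules"], p_threshold=d["p_threshold"],
            wald=d.get("wald", {}), nagelkerke_r2=d.get("nagelkerke_r2", 0.0),
            kstat_mode=d.get("kstat_mode", "signed"),
            separation=d.get("separation", False),
        )


def _log_likelihood(y: np.ndarray, z: np.ndarray) -> float:
    # numerically stable: -log(1 + exp(-z)) for y=1, -log(1 + exp(z)) for y=0
    s = np.where(y == 1, z, -z)
    return float(-np.logaddexp(0.0, -s).sum())


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Returns (beta, standard errors, separation flag, log-likelihood).
    Diverging coefficients (complete separation) are capped at +-30 on the
    linear scale and flagged.
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = _log_likelihood(y, X @ beta)
    separation = False
    for _ in range(_IRLS_MAXITER):
        z = X @ beta
        p = expit(z)
        w = p * (1.0 - p)
        # ridge floor keeps the normal equations solvable near separation
        H = X.T @ (X * w[:, None]) + 1e-10 * np.eye(k)
        g = X.T @ (y - p)
        beta = beta + np.linalg.solve(H, g)
        if np.any(np.abs(beta) > _COEF_CAP):
            separation = True
            beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
            warnings.warn("complete separation detected; coefficients capped",
                          stacklevel=3)
            break
        ll = _log_likelihood(y, X @ beta)
        if abs(ll - ll_old) < _IRLS_TOL:
            ll_old = ll
            break
        ll_old = ll
    z = X @ beta
    ll = _log_likelihood(y, z)
    if not separation and ll > -1e-8:
        # likelihood at its supremum: the classes are perfectly separated and
        # the MLE does not exist; coefficients are left where IRLS stalled
        separation = True
        warnings.warn("complete separation detected; coefficients capped",
                      stacklevel=3)
    p = expit(z)
    w = p * (1.0 - p)
    H = X.T @ (X * w[:, None]) + 1e-10 * np.eye(k)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se, separation, ll


def _as_matrix(features: pd.DataFrame | Mapping | np.ndarray,
               rules: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        cols = list(features.columns) if rules is None else list(rules)
        return features[cols].to_numpy(dtype=float), cols
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = list(rules) if rules is not None else [f"x{i}" for i in range(arr.shape[1])]
    return arr, cols


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    y_raw = np.asarray(list(labels))
    classes = sorted(set(y_raw.tolist()))
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    return (y_raw == classes[1]).astype(float), classes


def fit_logistic(features, labels, rules: Sequence[str] | None = None,
                 p_threshold: float = 0.5,
                 kstat_mode: str = "signed") -> BinaryLogisticModel:
    """Fit a binary logistic model on the given feature columns.

    The second label in sorted order is the positive class.  Wald statistics
    are (b / SE)^2 per coefficient; Nagelkerke R^2 is computed against the
    intercept-only fit on the same data.
    """
    X0, cols = _as_matrix(features, rules)
    y, classes = _encode_labels(labels)
    if X0.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    for c, n_c in zip(*np.unique(y, return_counts=True)):
        if n_c < 2:
            raise ValueError("need at least 2 rows per class")
    X = np.column_stack([np.ones(len(y)), X0])
    beta, se, separation, ll1 = _irls(X, y)
    # intercept-only reference for Nagelkerke R^2
    ll0 = _intercept_only_ll(y)
    n = y.size
    r2_cs = 1.0 - math.exp((2.0 / n) * (ll0 - ll1))
    r2_max = 1.0 - math.exp((2.0 / n) * ll0)
    r2_n = float(np.clip(r2_cs / r2_max, 0.0, 1.0)) if r2_max > 0 else 0.0
    wald = {c: float((b / s) ** 2) if s > 0 else float("inf")
            for c, b, s in zip(["(intercept)"] + cols, beta, se)}
    return BinaryLogisticModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(cols, beta[1:])},
        included_rules=cols,
        p_threshold=p_threshold,
        wald=wald,
        nagelkerke_r2=r2_n,
        kstat_mode=kstat_mode,
        separation=separation,
        log_likelihood=ll1,
    )


def _intercept_only_ll(y: np.ndarray) -> float:
    p1 = y.mean()
    if p1 in (0.0, 1.0):
        return 0.0
    n1 = y.sum()
    n0 = y.size - n1
    return float(n1 * math.log(p1) + n0 * math.log(1 - p1))


def nagelkerke_r2(model: BinaryLogisticModel, features, labels) -> float:
    """Nagelkerke coefficient of determination of a fitted model.

    ``R2_CS = 1 - (L0 / L1)^(2/n)`` rescaled by its maximum
    ``1 - L0^(2/n)``, where ``L0`` is the intercept-only likelihood.
    """
    X0, cols = _as_matrix(features, model.included_rules)
    y, _ = _encode_labels(labels)
    z = model.intercept + X0 @ np.array([model.coefficients[c] for c in cols])
    ll1 = _log_likelihood(y, z)
    ll0 = _intercept_only_ll(y)
    n = y.size
    r2_cs = 1.0 - math.exp((2.0 / n) * (ll0 - ll1))
    r2_max = 1.0 - math.exp((2.0 / n) * ll0)
    return float(np.clip(r2_cs / r2_max, 0.0, 1.0)) if r2_max > 0 else 0.0


def predict_binary(model: BinaryLogisticModel, row: Mapping[str, float],
                   p_thr: float | None = None) -> tuple[float, bool]:
    """Class probability and decision for one feature row.

    Returns ``(p, decision)`` with ``decision = p > p_thr`` (positive class).
    """
    thr = model.p_threshold if p_thr is None else p_thr
    p = float(expit(model.linear_score(row)))
    return p, p > thr


def predict_proba(model: BinaryLogisticModel, features: pd.DataFrame) -> np.ndarray:
    X0, cols = _as_matrix(features, model.included_rules)
    z = model.intercept + X0 @ np.array([model.coefficients[c] for c in cols])
    return expit(z)


# ---------------------------------------------------------------------------
# Stepwise logistic model building
# ---------------------------------------------------------------------------

def stepwise_logistic(
    features: pd.DataFrame,
    labels,
    alpha_screen: float = 0.05,
    auc_gain_min: float = 0.005,
    max_predictors: int = 4,
    kstat_mode: str = "signed",
) -> tuple[BinaryLogisticModel, list[RocCurve]]:
    """Stepwise construction of the combined logistic model.

    1. Discard rules whose two-group Mann–Whitney p-value is >=
       ``alpha_screen`` (no significant single-rule difference).
    2. Rank survivors by their single-predictor Wald statistic, descending.
    3. Enter predictors in that order, refitting after each entry and
       computing the training ROC of the fitted probabilities; stop when the
       AUC gain drops below ``auc_gain_min`` or ``max_predictors`` is
       reached.  Inverted-direction rules need no manual handling — their
       coefficients come out negative.

    Returns the final model and the ROC curve after each accepted entry.
    """
    y, classes = _encode_labels(labels)
    cand = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        _, p = mann_whitney(vals[y == 0], vals[y == 1])
        if p < alpha_screen:
            cand.append(col)
    if not cand:
        warnings.warn("no predictor survived the Mann-Whitney screen; "
                      "returning intercept-only model", stacklevel=2)
        X = np.ones((len(y), 1))
        beta, se, _, ll = _irls(X, y)
        model = BinaryLogisticModel(float(beta[0]), {}, [],
                                    kstat_mode=kstat_mode, log_likelihood=ll)
        return model, []

    def single_wald(col: str) -> float:
        m = fit_logistic(features, labels, rules=[col], kstat_mode=kstat_mode)
        return m.wald[col]

    order = sorted(cand, key=single_wald, reverse=True)
    included: list[str] = []
    curves: list[RocCurve] = []
    best_auc = 0.5
    model: BinaryLogisticModel | None = None
    for col in order:
        if len(included) >= max_predictors:
            break
        trial = included + [col]
        m = fit_logistic(features, labels, rules=trial, kstat_mode=kstat_mode)
        p_hat = predict_proba(m, features)
        curve = roc(p_hat[y == 0], p_hat[y == 1])
        if curve.auc - best_auc < auc_gain_min and included:
            logger.info("stepwise_logistic: stop before %r (AUC gain %.4f)",
                        col, curve.auc - best_auc)
            break
        included = trial
        model = m
        curves.append(curve)
        best_auc = curve.auc
    assert model is not None
    return model, curves


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    train: tuple
    test: tuple
    fraction: float
    seed: int


def split_stratified(labels: Mapping, fraction: float = 0.7,
                     seed: int = 0) -> SplitPlan:
    """Per-label random train/test split at the given training fraction.

    ``labels`` maps each id to its group label.  A label with a single
    member goes to the training set with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for pid, lab in labels.items():
        by_label.setdefault(lab, []).append(pid)
    train: list = []
    test: list = []
    for lab in sorted(by_label, key=str):
        ids = by_label[lab]
        if len(ids) == 1:
            warnings.warn(f"label {lab!r} has a single member; assigned to train",
                          stacklevel=2)
            train.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    if not test:
        warnings.warn("empty test set", stacklevel=2)
    return SplitPlan(tuple(train), tuple(test), fraction, seed)


# ---------------------------------------------------------------------------
# Stepwise linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Linear discriminant model with equal priors over >= 2 classes."""

    classes: list
    means: dict                      # class -> mean vector over included predictors
    pooled_cov: np.ndarray           # pooled within-class covariance
    included_predictors: list[str]   # ordered by entry

    def scores(self, row: Mapping[str, float]) -> np.ndarray:
        try:
            x = np.array([float(row[p]) for p in self.included_predictors])
        except KeyError as exc:
            raise KeyError(f"feature row lacks predictor {exc.args[0]!r}") from None
        inv = np.linalg.inv(self.pooled_cov)
        out = []
        for c in self.classes:
            mu = np.asarray(self.means[c])
            out.append(x @ inv @ mu - 0.5 * mu @ inv @ mu)
        return np.array(out)


def _pooled_cov(X: np.ndarray, y: np.ndarray, classes) -> np.ndarray:
    k = X.shape[1]
    S = np.zeros((k, k))
    n_total = 0
    for c in classes:
        Xc = X[y == c]
        S += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
        n_total += len(Xc)
    S /= max(n_total - len(classes), 1)
    if np.linalg.matrix_rank(S) < k or np.linalg.cond(S) > 1e12:
        warnings.warn("singular pooled covariance; applying ridge jitter",
                      stacklevel=3)
        S = S + 1e-8 * np.trace(S) * np.eye(k)
    return S


def _min_pairwise_mahalanobis(X: np.ndarray, y: np.ndarray, classes) -> float:
    S = _pooled_cov(X, y, classes)
    inv = np.linalg.inv(S)
    means = {c: X[y == c].mean(axis=0) for c in classes}
    dmin = np.inf
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            d = means[a] - means[b]
            dmin = min(dmin, float(d @ inv @ d))
    return dmin


def stepwise_lda(features: pd.DataFrame, labels,
                 max_predictors: int = 4,
                 accuracy_gain_min: float = 0.005) -> DiscriminantModel:
    """Stepwise LDA entering the predictor that best separates the two
    closest groups (maximum of the minimum pairwise Mahalanobis distance,
    pooled within-class covariance); entry stops when the training-accuracy
    gain falls below ``accuracy_gain_min`` or ``max_predictors`` is reached.
    """
    y = np.asarray(list(labels))
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("need at least 2 rows per class")
    remaining = list(features.columns)
    included: list[str] = []
    prev_acc = 1.0 / len(classes)
    model: DiscriminantModel | None = None
    while remaining and len(included) < max_predictors:
        best_col, best_d = None, -np.inf
        for col in remaining:
            X = features[included + [col]].to_numpy(dtype=float)
            d = _min_pairwise_mahalanobis(X, y, classes)
            if d > best_d:
                best_col, best_d = col, d
        trial = included + [best_col]
        cand = _fit_lda(features, y, classes, trial)
        acc = _training_accuracy(cand, features, y)
        if model is not None and acc - prev_acc < accuracy_gain_min:
            break
        included = trial
        remaining.remove(best_col)
        model = cand
        prev_acc = acc
    assert model is not None
    return model


def _fit_lda(features: pd.DataFrame, y: np.ndarray, classes,
             predictors: list[str]) -> DiscriminantModel:
    X = features[predictors].to_numpy(dtype=float)
    S = _pooled_cov(X, y, classes)
    means = {c: X[y == c].mean(axis=0) for c in classes}
    return DiscriminantModel(list(classes), means, S, list(predictors))


def _training_accuracy(model: DiscriminantModel, features: pd.DataFrame,
                       y: np.ndarray) -> float:
    correct = 0
    for i, (_, row) in enumerate(features.iterrows()):
        if classify_lda(model, row) == y[i]:
            correct += 1
    return correct / len(y)


def classify_lda(model: DiscriminantModel, row: Mapping[str, float]):
    """Assign a feature row to the class with maximal discriminant score.

    Exact ties break deterministically to the first class in declared order.
    """
    s = model.scores(row)
    return model.classes[int(np.argmax(s))]
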