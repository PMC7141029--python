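"""Discretized stepwise logistic classifiers for promoter coverage.

The training path follows the three-stage design: promoter RPKM values are
discretized at the cutoff maximizing balanced accuracy (sensitivity +
specificity)/2 in the training cohort, the indicator is 1 when the value is
strictly larger than the cutoff, a bidirectional AIC stepwise search over
the binary indicators selects the feature set, coefficients come from
maximum-likelihood logistic regression (IRLS), robustness is assessed by
leave-one-out cross-validation, and performance by ROC analysis with
DeLong confidence intervals and paired AUC comparison.

The published 12-gene macrosomia classifier (set-A) is available via
:func:`published_ma_classifier`; its log-odds are

    logit p = 2.180 + 0.605*SMC3 - 1.204*MASTL + 1.366*CREM
              - 1.295*C1QTNF12 - 0.471*MLXIP - 0.811*MAP3K9
              - 1.284*IGSF6 - 1.347*APC2 - 0.504*GPM6A
              + 1.048*TMEM128 - 0.057*NIPBL - 1.652*TMEM184A

over 0/1 promoter indicators.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

logger = logging.getLogger("promoterfoot")

__all__ = [
    "DiscretizationRule",
    "PromoterClassifier",
    "LogisticFit",
    "RocResult",
    "optimal_cutoff",
    "learn_discretization",
    "binarize",
    "fit_logistic",
    "stepwise_select",
    "loocv_probabilities",
    "roc_analysis",
    "compare_auc",
    "predict",
    "published_ma_classifier",
]

#: coefficient magnitude cap applied when complete separation is detected
_BETA_CAP = 15.0
_SCORE_TOL = 1e-8
_MAX_ITER = 100


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationRule:
    """Indicator rule: feature value is encoded 1 iff value > cutoff."""

    feature: str
    cutoff: float

    def apply(self, values):
        return (np.asarray(values, dtype=float) > self.cutoff).astype(float)


def _cutoff_candidates(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def optimal_cutoff(
    values: Sequence[float], labels: Sequence[int] | Sequence[bool]
) -> tuple[float, float]:
    """Cutoff maximizing direction-agnostic balanced accuracy.

    Candidates are midpoints between consecutive sorted unique values plus
    one point below the minimum and one above the maximum.  For each
    candidate, balanced accuracy BA = (sensitivity + specificity)/2 is
    computed with "positive = case" and "indicator = value > cutoff"; the
    candidate's score is max(BA, 1 - BA) so that a promoter informative in
    either direction scores equally (the logistic coefficient sign absorbs
    the orientation).  The smallest candidate achieving the maximal score
    is returned, with its score.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    candidates = _cutoff_candidates(values)
    n_case = y.sum()
    n_control = (~y).sum()
    best_cutoff, best_score = candidates[0], -np.inf
    for c in candidates:
        ind = values > c
        sens = (ind & y).sum() / n_case
        spec = (~ind & ~y).sum() / n_control
        ba = (sens + spec) / 2.0
        score = max(ba, 1.0 - ba)
        if score > best_score + 1e-12:
            best_cutoff, best_score = c, score
    return float(best_cutoff), float(best_score)


def learn_discretization(
    values: pd.DataFrame, labels: Sequence[int] | Sequence[bool]
) -> dict[str, float]:
    """Per-column optimal cutoffs for a samples × features RPKM frame."""
    return {
        col: optimal_cutoff(values[col].to_numpy(), labels)[0]
        for col in values.columns
    }


def binarize(
    matrix: pd.DataFrame, rules: Mapping[str, float] | Sequence[DiscretizationRule]
) -> pd.DataFrame:
    """Apply indicator rules columnwise: entry = 1 iff value > cutoff (strict)."""
    if not isinstance(rules, Mapping):
        rules = {r.feature: r.cutoff for r in rules}
    missing = [c for c in matrix.columns if c not in rules]
    if missing:
        raise ConfigurationError(
            f"no discretization rule for feature(s): {', '.join(map(str, missing))}"
        )
    out = {c: (matrix[c].to_numpy(dtype=float) > rules[c]).astype(float) for c in matrix.columns}
    return pd.DataFrame(out, index=matrix.index)


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    intercept: float
    coefficients: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    n_params: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    binary_design: np.ndarray | pd.DataFrame,
    labels: Sequence[int] | Sequence[bool],
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Converges when the maximal absolute score (gradient) component drops
    below 1e-8, with at most 100 iterations.  Constant columns are dropped
    (coefficient reported as 0) with a warning.  Complete separation —
    diagnosed by coefficients diverging past |beta| = 15 — raises the
    ``separation`` flag and caps the offending coefficients at +/-15.
    """
    X = np.asarray(binary_design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(float)
    if y.min() == y.max():
        raise ValueError("labels must contain both classes")
    n, p = X.shape
    keep = np.array([len(np.unique(X[:, j])) > 1 for j in range(p)], dtype=bool)
    if not keep.all():
        logger.warning(
            "fit_logistic: dropped %d constant feature(s)", int((~keep).sum())
        )
    Xk = X[:, keep]
    design = np.column_stack([np.ones(n), Xk])
    beta = np.zeros(design.shape[1])
    beta[0] = logit(np.clip(y.mean(), 1e-9, 1 - 1e-9))
    converged = False
    separation = False
    for _ in range(_MAX_ITER):
        eta = design @ beta
        mu = expit(eta)
        score = design.T @ (y - mu)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        hess = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > _BETA_CAP:
            # diverging fit: stop at first detection so the other
            # coefficients keep their last finite (decisive) values
            separation = True
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            break
    if separation:
        logger.warning(
            "fit_logistic: complete separation detected; coefficients capped at |beta| <= %g",
            _BETA_CAP,
        )
    coef = np.zeros(p)
    coef[keep] = beta[1:]
    ll = _loglik(design @ beta, y)
    return LogisticFit(
        intercept=float(beta[0]),
        coefficients=coef,
        loglik=ll,
        converged=converged,
        separation=separation,
        n_params=1 + int(keep.sum()),
    )


def stepwise_select(
    binary_design: pd.DataFrame | np.ndarray,
    labels: Sequence[int] | Sequence[bool],
    max_features: int = 15,
) -> list:
    """Bidirectional stepwise feature selection minimizing AIC.

    Starts from the intercept-only model; at each step the single add or
    drop move with the largest AIC decrease is taken (adds evaluated in
    candidate column order, then drops — ties go to the earlier move);
    stops when no move improves the AIC or ``max_features`` is reached
    (drops remain allowed at the cap).  Deterministic given input order.
    """
    if isinstance(binary_design, pd.DataFrame):
        columns = list(binary_design.columns)
        X = binary_design.to_numpy(dtype=float)
    else:
        X = np.asarray(binary_design, dtype=float)
        columns = list(range(X.shape[1]))
    y = np.asarray(labels).astype(float)
    if max_features <= 0 or not columns:
        return []

    selected: list[int] = []

    def model_aic(idx: list[int]) -> float:
        if not idx:
            p0 = np.clip(y.mean(), 1e-9, 1 - 1e-9)
            ll = float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
            return 2.0 - 2.0 * ll
        return fit_logistic(X[:, idx], y).aic

    current = model_aic(selected)
    while True:
        best_move: tuple[str, int] | None = None
        best_aic = current
        if len(selected) < max_features:
            for j in range(len(columns)):
                if j in selected:
                    continue
                aic = model_aic(selected + [j])
                if aic < best_aic - 1e-10:
                    best_aic, best_move = aic, ("add", j)
        for j in selected:
            aic = model_aic([k for k in selected if k != j])
            if aic < best_aic - 1e-10:
                best_aic, best_move = aic, ("drop", j)
        if best_move is None:
            break
        action, j = best_move
        if action == "add":
            selected.append(j)
        else:
            selected.remove(j)
        current = best_aic
    return [columns[j] for j in selected]


def loocv_probabilities(
    binary_design: pd.DataFrame,
    labels: Sequence[int] | Sequence[bool],
    feature_subset: Sequence,
) -> np.ndarray:
    """Out-of-fold probabilities: refit coefficients on n-1 samples per fold.

    The feature subset and discretization cutoffs are fixed from the full
    training cohort; only the logistic coefficients are refit in each fold.
    A fold whose training part lacks a class reuses the full-data fit with
    a warning.
    """
    y = np.asarray(labels).astype(float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3 samples")
    if y.min() == y.max():
        raise ValueError("labels must contain both classes")
    X = (
        binary_design[list(feature_subset)].to_numpy(dtype=float)
        if len(feature_subset)
        else np.empty((n, 0))
    )
    full_fit = _fit_or_null(X, y)
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if y_tr.min() == y_tr.max():
            logger.warning(
                "loocv_probabilities: fold %d has a single class; reusing full fit", i
            )
            fit = full_fit
        else:
            fit = _fit_or_null(X[mask], y_tr)
        eta = fit.intercept + (X[i] @ fit.coefficients if X.shape[1] else 0.0)
        probs[i] = expit(eta)
    return probs


def _fit_or_null(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    if X.shape[1] == 0:
        p0 = np.clip(y.mean(), 1e-9, 1 - 1e-9)
        ll = float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
        return LogisticFit(float(logit(p0)), np.zeros(0), ll, True, False, 1)
    return fit_logistic(X, y)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    probabilities: np.ndarray
    labels: np.ndarray

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
        }


def _delong_placements(probs: np.ndarray, y: np.ndarray):
    """AUC and per-sample placement values (ties count 1/2)."""
    cases = probs[y]
    controls = probs[~y]
    n1, n0 = len(cases), len(controls)
    # V10[i] = fraction of controls below case i (ties 1/2), and symmetrically
    order = np.sort(controls)
    below = np.searchsorted(order, cases, side="left")
    eq = np.searchsorted(order, cases, side="right") - below
    v10 = (below + 0.5 * eq) / n0
    order1 = np.sort(cases)
    above = n1 - np.searchsorted(order1, controls, side="right")
    eq0 = np.searchsorted(order1, controls, side="right") - np.searchsorted(
        order1, controls, side="left"
    )
    v01 = (above + 0.5 * eq0) / n1
    auc = float(v10.mean())
    return auc, v10, v01


def roc_analysis(
    probabilities: Sequence[float], labels: Sequence[int] | Sequence[bool]
) -> RocResult:
    """ROC summary: AUC (Mann–Whitney identity), DeLong 95% CI, and the
    operating point maximizing (sensitivity + specificity)/2.

    The operating threshold is the smallest candidate (midpoints between
    consecutive unique probabilities, plus one below the minimum and one
    above the maximum) achieving the maximal balanced accuracy; a sample is
    called positive when its probability is strictly above the threshold.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc, v10, v01 = _delong_placements(probs, y)
    n1, n0 = int(y.sum()), int((~y).sum())
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    se = float(np.sqrt(s10 / n1 + s01 / n0))
    ci_low = max(0.0, auc - 1.959963984540054 * se)
    ci_high = min(1.0, auc + 1.959963984540054 * se)

    best_thr, best_ba, best_stats = None, -np.inf, (0.0, 0.0, 0.0)
    for thr in _cutoff_candidates(probs):
        pred = probs > thr
        sens = float((pred & y).sum() / n1)
        spec = float((~pred & ~y).sum() / n0)
        ba = (sens + spec) / 2.0
        if ba > best_ba + 1e-12:
            acc = float((pred == y).mean())
            best_thr, best_ba, best_stats = float(thr), ba, (acc, sens, spec)
    acc, sens, spec = best_stats
    return RocResult(
        auc=auc,
        auc_ci_low=ci_low,
        auc_ci_high=ci_high,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        threshold=best_thr,
        probabilities=probs,
        labels=y,
    )


def compare_auc(roc_a: RocResult, roc_b: RocResult) -> float:
    """DeLong paired two-sided test for correlated AUCs on the same samples."""
    if len(roc_a.labels) != len(roc_b.labels) or not np.array_equal(
        roc_a.labels, roc_b.labels
    ):
        raise ValueError("ROC results must be computed on the same samples")
    y = roc_a.labels
    auc_a, v10_a, v01_a = _delong_placements(roc_a.probabilities, y)
    auc_b, v10_b, v01_b = _delong_placements(roc_b.probabilities, y)
    n1, n0 = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / n1 + s10[1, 1] / n1 - 2 * s10[0, 1] / n1
        + s01[0, 0] / n0 + s01[1, 1] / n0 - 2 * s01[0, 1] / n0
    )
    diff = auc_a - auc_b
    if var <= 1e-16:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# classifier object, prediction, published model
# ---------------------------------------------------------------------------

@dataclass
class PromoterClassifier:
    """Ordered features with discretization rules and logistic coefficients.

    Promoter features are discretized with their rule before entering the
    linear predictor; features without a rule (e.g. ``bmi``) enter raw.
    """

    name: str
    features: list[str]
    cutoffs: dict[str, float]
    coefficients: dict[str, float]
    intercept: float
    probability_threshold: float = 0.5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in self.features if f not in self.coefficients]
        if missing:
            raise ConfigurationError(
                f"no coefficient for feature(s): {', '.join(missing)}"
            )
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must lie in (0, 1)")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "features": self.features,
            "cutoffs": self.cutoffs,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "probability_threshold": self.probability_threshold,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PromoterClassifier":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return cls(
            name=payload["name"],
            features=list(payload["features"]),
            cutoffs={k: float(v) for k, v in payload["cutoffs"].items()},
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            intercept=float(payload["intercept"]),
            probability_threshold=float(payload["probability_threshold"]),
            provenance=payload.get("provenance", {}),
        )


def predict(
    classifier: PromoterClassifier,
    feature_values: Mapping[str, float] | pd.Series,
) -> tuple[float, float, bool]:
    """Linear predictor, probability, and call for one sample.

    ``feature_values`` may hold raw RPKM (discretized through the
    classifier's rules) or pre-discretized 0/1 indicators for features
    without a rule.  All classifier features must be present.
    """
    missing = [f for f in classifier.features if f not in feature_values]
    if missing:
        raise ConfigurationError(f"missing feature(s): {', '.join(missing)}")
    eta = classifier.intercept
    for f in classifier.features:
        x = float(feature_values[f])
        if f in classifier.cutoffs:
            x = 1.0 if x > classifier.cutoffs[f] else 0.0
        eta += classifier.coefficients[f] * x
    prob = float(expit(eta))
    return float(eta), prob, prob > classifier.probability_threshold


def predict_table(
    classifier: PromoterClassifier, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized :func:`predict` over a samples × features frame."""
    rows = [predict(classifier, matrix.loc[i]) for i in matrix.index]
    return pd.DataFrame(
        rows, index=matrix.index, columns=["linear_predictor", "probability", "call"]
    )


#: Eq.-style coefficients of the published 12-gene macrosomia classifier
_MA_COEFFICIENTS = {
    "SMC3": 0.605,
    "MASTL": -1.204,
    "CREM": 1.366,
    "C1QTNF12": -1.295,
    "MLXIP": -0.471,
    "MAP3K9": -0.811,
    "IGSF6": -1.284,
    "APC2": -1.347,
    "GPM6A": -0.504,
    "TMEM128": 1.048,
    "NIPBL": -0.057,
    "TMEM184A": -1.652,
}
_MA_INTERCEPT = 2.180


def published_ma_classifier(
    cutoffs: Mapping[str, float] | None = None,
    probability_threshold: float | None = None,
) -> PromoterClassifier:
    """The published 12-gene macrosomia (set-A) classifier.

    Intercept and coefficients are fixed; the per-gene discretization
    cutoffs and the probability threshold were published only in
    supplementary material and must be supplied by the user — when the
    threshold is omitted it defaults to 0.5 with a warning, and without
    cutoffs the features are taken as pre-discretized 0/1 indicators.
    """
    if probability_threshold is None:
        probability_threshold = 0.5
        logger.warning(
            "published_ma_classifier: probability threshold not supplied; "
            "defaulting to 0.5"
        )
    return PromoterClassifier(
        name="C_MA-A",
        features=list(_MA_COEFFICIENTS),
        cutoffs=dict(cutoffs) if cutoffs else {},
        coefficients=dict(_MA_COEFFICIENTS),
        intercept=_MA_INTERCEPT,
        probability_threshold=probability_threshold,
        provenance={"source": "published macrosomia set-A equation"},
    )
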