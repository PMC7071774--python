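"""Response classification, discriminant analysis, and descriptive tests.

Implements the cohort-level prognostic analysis: the pathologic-response
rules (pCR / PR / NR and the binary responder flag), linear discriminant
analysis with equal-covariance Gaussian class densities and empirical
priors, stratified five-fold cross-validated ROC curves built by sweeping
every posterior-probability threshold, and the two descriptive tests
(Wilcoxon rank sum for continuous characteristics, two-proportion z-test
for categorical ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PathologicResponse",
    "LDAModel",
    "ROCResult",
    "classify_response",
    "lda_fit",
    "roc_from_scores",
    "crossval_roc",
    "rank_sum_test",
    "two_proportion_ztest",
]


@dataclass(frozen=True)
class PathologicResponse:
    """Tertiary pathologic response and the derived binary responder flag."""

    label: str  # "pCR" | "PR" | "NR"
    responder: bool

    def __post_init__(self) -> None:
        if self.label not in ("pCR", "PR", "NR"):
            raise ValueError(f"label must be pCR/PR/NR, got {self.label}")
        if self.responder != (self.label in ("pCR", "PR")):
            raise ValueError("responder flag inconsistent with label")


def classify_response(
    baseline_cm: float, resection_cm: float, residual_invasive: bool
) -> PathologicResponse:
    """Pathologic response from largest tumor dimensions at diagnosis/resection.

    pCR: no residual invasive disease.  PR: shrinkage of the largest
    dimension by strictly more than 50%.  NR otherwise — including exactly
    50%, which the printed rules leave unassigned; this package classifies
    the boundary as NR.
    """
    if baseline_cm < 0 or resection_cm < 0:
        raise ValueError("tumor dimensions must be >= 0")
    if not residual_invasive:
        return PathologicResponse("pCR", True)
    if baseline_cm == 0:
        raise ValueError("residual disease with zero baseline dimension")
    reduction = (baseline_cm - resection_cm) / baseline_cm
    label = "PR" if reduction > 0.5 else "NR"
    return PathologicResponse(label, label == "PR")


@dataclass
class LDAModel:
    """Two-class LDA with multivariate-normal equal-covariance densities."""

    means: np.ndarray  # (2, d): row 0 = class 0, row 1 = class 1
    pooled_cov: np.ndarray  # (d, d)
    priors: np.ndarray  # (2,), empirical by default, sums to 1
    ridge_applied: bool = False

    def posterior(self, X) -> np.ndarray:
        """P(class 1 | x) by Bayes' rule for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            X = X.reshape(-1, self.means.shape[1])
        prec = np.linalg.inv(self.pooled_cov)
        logp = np.empty((X.shape[0], 2))
        for k in range(2):
            mu = self.means[k]
            logp[:, k] = X @ prec @ mu - 0.5 * mu @ prec @ mu + np.log(self.priors[k])
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p[:, 1] / p.sum(axis=1)


def lda_fit(features, labels) -> LDAModel:
    """Fit two-class LDA: class means, pooled within-class covariance, empirical priors.

    A singular pooled covariance is ridge-regularized (1e-8 of its trace)
    with a warning.  1-D features are accepted as a vector.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    n, d = X.shape
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 samples in each class")
    means = np.vstack([X[y == k].mean(axis=0) for k in (0, 1)])
    scatter = sum(
        (X[y == k] - means[k]).T @ (X[y == k] - means[k]) for k in (0, 1)
    )
    cov = np.atleast_2d(scatter / (n - 2))
    priors = np.array([(y == 0).mean(), (y == 1).mean()])
    ridge = False
    if np.linalg.cond(cov) > 1e12 or np.any(np.diag(cov) <= 0):
        warnings.warn("singular pooled covariance: applying ridge regularization")
        cov = cov + 1e-8 * max(np.trace(cov), 1.0) / d * np.eye(d)
        ridge = True
    return LDAModel(means=means, pooled_cov=cov, priors=priors, ridge_applied=ridge)


@dataclass
class ROCResult:
    """ROC curve from posterior scores: staircase, AUC, and optimal point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal: dict = field(default_factory=dict)  # threshold, sens, spec, ppv, npv
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None


def roc_from_scores(scores, labels) -> ROCResult:
    """ROC by iterating through every distinct score as a decision threshold.

    A sample is called positive when its score is >= the threshold; AUC is
    the trapezoidal area in (1 - specificity, sensitivity) space.  The
    optimal operating point maximizes Youden's J = sensitivity +
    specificity - 1 (ties to the higher threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    thr = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.array([(s[y == 1] >= t).mean() for t in thr])
    spec = np.array([(s[y == 0] < t).mean() for t in thr])
    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    j = sens + spec - 1
    i = int(np.argmax(j))  # argmax takes the first (highest threshold) on ties
    t = thr[i]
    tp = int((s[y == 1] >= t).sum())
    fp = int((s[y == 0] >= t).sum())
    fn, tn = n1 - tp, n0 - fp
    optimal = {
        "threshold": float(t),
        "sensitivity": float(sens[i]),
        "specificity": float(spec[i]),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }
    return ROCResult(thr, sens, spec, auc, optimal, scores=s, labels=y)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Seeded stratified k-fold assignment: fold index per sample."""
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def crossval_roc(features, labels, k: int = 5, seed: int = 0) -> ROCResult:
    """Stratified k-fold cross-validated LDA ROC.

    Each fold's samples are scored by an LDA trained on the other folds; the
    pooled out-of-fold posterior probabilities feed :func:`roc_from_scores`.
    Stratification guarantees both classes in every training fold provided
    ``k <= min class count``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if k > min(n1, n0):
        raise ValueError(f"k={k} exceeds the smaller class count {min(n1, n0)}")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, k, rng)
    post = np.empty(len(y))
    for f in range(k):
        train, test = fold != f, fold == f
        model = lda_fit(X[train], y[train])
        post[test] = model.posterior(X[test])
    return roc_from_scores(post, y)


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank sum (Mann-Whitney) p value.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction and continuity correction otherwise (scipy's "auto"
    convention).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided z-test for equality of two proportions (pooled variance).

    No continuity correction; identical proportions give p = 1.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= successes <= trials and nonzero trials")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))
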