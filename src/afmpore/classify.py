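"""Binary pore-size classification: logistic regression, ROC, AUC, Youden.

Membrane pairs are classified from the single covariate pore radius x via
the binomial link ``logit(p) = beta0 + beta1 * x``.  Discrimination is
summarised by the ROC curve (sensitivity vs 1 - specificity over score
cutoffs), its trapezoidal AUC, the Youden index in the halved convention
``Yi = max (Se + Sp - 1)/2`` (so a perfect classifier scores 0.5), and
classification accuracy ``(TP + TN)/N`` at a chosen cutoff.  The positive
class is, by convention, the larger-MWCO membrane of the pair, so the
fitted slope is expected positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

COEF_CAP = 50.0


@dataclass(frozen=True)
class LogisticModel:
    beta0: float
    beta1: float
    iterations: int
    grad_norm: float
    converged: bool
    separated: bool = False

    def predict_proba(self, x) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(x, dtype=float))

    def log_likelihood(self, x, y) -> float:
        eta = self.beta0 + self.beta1 * np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # log(1+exp(eta)) computed stably
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass(frozen=True)
class ROCCurve:
    """Per-cutoff operating points, sorted by ascending cutoff.

    Cutoffs are the midpoints between consecutive distinct scores plus
    -inf/+inf sentinels; a point is called positive when its score is >=
    the cutoff, so the curve runs from (1, 1) at -inf to (0, 0) at +inf.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden: float
    optimal_cutoff: float


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_total


def _check_two_class(y: np.ndarray) -> None:
    u = np.unique(y)
    if not np.array_equal(u, [0, 1]):
        raise ValueError("labels must contain both classes, coded 0 and 1")


def fit_logistic(
    x, labels, max_iter: int = 100, tol: float = 1e-8, cap: float = COEF_CAP
) -> LogisticModel:
    """Newton–Raphson maximum-likelihood fit of the univariate logistic model.

    Converges when the gradient norm falls below ``tol``.  Under complete
    separation the likelihood has no finite maximiser; the iteration is
    stopped once a coefficient magnitude exceeds ``cap``, coefficients are
    clipped to ``±cap`` and the model is flagged ``separated`` (scores
    remain monotone in x, so downstream ROC analysis is unaffected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and labels must have equal length")
    _check_two_class(y)
    # with a single covariate, complete separation is exactly a gap between
    # the class ranges; the likelihood then has no finite maximiser
    separated = (x[y == 0].max() < x[y == 1].min()) or (x[y == 1].max() < x[y == 0].min())
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol or np.max(np.abs(beta)) > cap:
            beta = np.clip(beta, -cap, cap)
            return LogisticModel(
                float(beta[0]), float(beta[1]), it, grad_norm,
                converged=grad_norm < tol and not separated,
                separated=separated,
            )
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X + 1e-12 * np.eye(2)
        beta = beta + np.linalg.solve(H, grad)
    beta = np.clip(beta, -cap, cap)
    return LogisticModel(
        float(beta[0]), float(beta[1]), max_iter, grad_norm, False, separated=separated
    )


def roc_curve(scores, labels, halved_youden: bool = True) -> ROCCurve:
    """ROC curve with cutoffs at midpoints between distinct scores.

    AUC is the trapezoidal integral of sensitivity over 1 - specificity,
    identical to the midrank Mann–Whitney statistic U/(n1*n2).  The Youden
    index is maximised over cutoffs (ties broken toward the lower cutoff).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_class(y)
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    # positive call: score >= cutoff
    pred = s[None, :] >= cutoffs[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    se = tp / n_pos
    sp = (n_neg - fp) / n_neg
    # descending cutoff runs (0,0) -> (1,1) monotonically in both coordinates
    auc_val = float(np.trapezoid(se[::-1], (1.0 - sp)[::-1]))
    j = (se + sp - 1.0) / (2.0 if halved_youden else 1.0)
    i_best = int(np.argmax(j))  # first max = lowest cutoff on ties
    return ROCCurve(
        cutoffs=cutoffs,
        sensitivity=se,
        specificity=sp,
        auc=auc_val,
        youden=float(j[i_best]),
        optimal_cutoff=float(cutoffs[i_best]),
    )


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under the (1 - Sp, Se) curve."""
    fpr = 1.0 - roc.specificity
    return float(np.trapezoid(roc.sensitivity[::-1], fpr[::-1]))


def youden(roc: ROCCurve, halved: bool = True) -> tuple[float, float]:
    """(Yi, maximising cutoff); Yi = max (Se+Sp-1)/2 by default (range [0, 0.5])."""
    j = (roc.sensitivity + roc.specificity - 1.0) / (2.0 if halved else 1.0)
    i = int(np.argmax(j))
    return float(j[i]), float(roc.cutoffs[i])


def accuracy_at_cutoff(scores, labels, cutoff: float) -> ClassificationMetrics:
    """Confusion counts and accuracy with positive call at score >= cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.size == 0:
        raise ValueError("cannot compute accuracy on an empty sample")
    pred = s >= cutoff
    pos = y == 1
    return ClassificationMetrics(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def auc_category(auc_value: float) -> str:
    """Categorical discrimination strength: high (>=0.8), medium ([0.7, 0.8)), low (<0.7)."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc_value}")
    if auc_value >= 0.8:
        return "high"
    if auc_value >= 0.7:
        return "medium"
    return "low"


def holdout_split(labels, eval_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Stratified hold-out partition; returns (train_idx, eval_idx).

    Per class, the evaluation count is ``round(eval_fraction * n_class)``
    (round-half-to-even); the remainder trains.  Raises if any class's
    partition would be empty.  ``rng`` may be a seed or a Generator.
    """
    if not 0.0 < eval_fraction < 1.0:
        raise ValueError("eval_fraction must be in (0, 1)")
    y = np.asarray(labels)
    rng = np.random.default_rng(rng)
    train, evaluate = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_eval = int(np.round(eval_fraction * idx.size))
        if n_eval == 0 or n_eval == idx.size:
            raise ValueError(
                f"eval_fraction {eval_fraction} leaves an empty partition for class {cls} "
                f"(n={idx.size})"
            )
        perm = rng.permutation(idx)
        evaluate.append(perm[:n_eval])
        train.append(perm[n_eval:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(evaluate))
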