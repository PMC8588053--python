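"""Parametric-bootstrap classification pipeline and test-size optimisation.

The headline analysis: from the Gamma parameters of two membrane classes,
generate Monte-Carlo replicate datasets, hold out part of each for
evaluation, fit the logistic classifier on the training partition, and
aggregate AUC / accuracy / Youden / coefficients over replicates.  A sweep
over the bootstrapped dataset size (10%..100% of the experimental design)
then locates the smallest test size whose mean AUC has plateaued while
``mean - SD`` stays above the acceptability floor, from which the
projected AFM scan-time saving follows directly.

Split-direction convention: ``eval_fraction`` (default 0.8) is the share
of each class held out for ROC evaluation; the classifier trains on the
remaining 20%.  At fraction 0.7 of the tapping design (n = 60) this gives
the 34:8 evaluation:training partition per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .classify import (
    accuracy_at_cutoff,
    fit_logistic,
    holdout_split,
    roc_curve,
)
from .distributions import GammaParams

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass(frozen=True)
class PairConfig:
    """One two-class bootstrap experiment.

    ``gamma_a``/``n_a`` describe the negative class (smaller MWCO),
    ``gamma_b``/``n_b`` the positive class (larger MWCO).
    """

    gamma_a: GammaParams
    gamma_b: GammaParams
    n_a: int
    n_b: int
    n_datasets: int = 10
    eval_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 2:
            raise ValueError("n_datasets must be >= 2")
        if min(self.n_a, self.n_b) < 10:
            raise ValueError("class sample sizes must be >= 10")
        if not 0.0 < self.eval_fraction < 1.0:
            raise ValueError("eval_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ReplicateResult:
    auc: float
    accuracy: float
    youden: float
    optimal_cutoff: float
    beta0: float
    beta1: float
    separated: bool


@dataclass(frozen=True)
class PairSummary:
    """Mean ± SD aggregates over bootstrap replicates."""

    auc_mean: float
    auc_sd: float
    acc_mean: float
    acc_sd: float
    youden_mean: float
    youden_sd: float
    beta0_mean: float
    beta0_sd: float
    beta1_mean: float
    beta1_sd: float
    n_replicates: int
    n_separated: int
    replicates: Tuple[ReplicateResult, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class SweepResult:
    """Aggregates at one test-size fraction (NaN statistics when invalid)."""

    fraction: float
    valid: bool
    summary: PairSummary | None

    @property
    def auc_mean(self) -> float:
        return self.summary.auc_mean if self.valid else float("nan")

    @property
    def auc_sd(self) -> float:
        return self.summary.auc_sd if self.valid else float("nan")


def _substream(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


def generate_mc_datasets(config: PairConfig) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Independent Monte-Carlo two-class datasets as (values, labels) pairs.

    Replicate r uses the dedicated substream (seed, r), so datasets are
    reproducible individually and mutually independent.
    """
    out = []
    for r in range(config.n_datasets):
        rng = _substream(config.seed, r)
        xa = rng.gamma(config.gamma_a.shape_a, config.gamma_a.scale_b, config.n_a)
        xb = rng.gamma(config.gamma_b.shape_a, config.gamma_b.scale_b, config.n_b)
        x = np.concatenate([xa, xb])
        y = np.concatenate([np.zeros(config.n_a), np.ones(config.n_b)])
        out.append((x, y))
    return out


def _classify_replicate(
    config: PairConfig, n_a: int, n_b: int, rng: np.random.Generator
) -> ReplicateResult:
    xa = rng.gamma(config.gamma_a.shape_a, config.gamma_a.scale_b, n_a)
    xb = rng.gamma(config.gamma_b.shape_a, config.gamma_b.scale_b, n_b)
    x = np.concatenate([xa, xb])
    y = np.concatenate([np.zeros(n_a), np.ones(n_b)])
    train_idx, eval_idx = holdout_split(y, config.eval_fraction, rng)
    model = fit_logistic(x[train_idx], y[train_idx])
    scores = model.predict_proba(x[eval_idx])
    roc = roc_curve(scores, y[eval_idx])
    metrics = accuracy_at_cutoff(scores, y[eval_idx], roc.optimal_cutoff)
    return ReplicateResult(
        auc=roc.auc,
        accuracy=metrics.accuracy,
        youden=roc.youden,
        optimal_cutoff=roc.optimal_cutoff,
        beta0=model.beta0,
        beta1=model.beta1,
        separated=model.separated,
    )


def _aggregate(reps: Sequence[ReplicateResult]) -> PairSummary:
    def ms(attr):
        v = np.array([getattr(r, attr) for r in reps], dtype=float)
        return float(v.mean()), float(v.std(ddof=1))

    auc_m, auc_s = ms("auc")
    acc_m, acc_s = ms("accuracy")
    yi_m, yi_s = ms("youden")
    b0_m, b0_s = ms("beta0")
    b1_m, b1_s = ms("beta1")
    return PairSummary(
        auc_mean=auc_m, auc_sd=auc_s,
        acc_mean=acc_m, acc_sd=acc_s,
        youden_mean=yi_m, youden_sd=yi_s,
        beta0_mean=b0_m, beta0_sd=b0_s,
        beta1_mean=b1_m, beta1_sd=b1_s,
        n_replicates=len(reps),
        n_separated=sum(r.separated for r in reps),
        replicates=tuple(reps),
    )


def run_pair_classification(config: PairConfig) -> PairSummary:
    """Hold-out classification aggregated over Monte-Carlo replicates.

    Per replicate: draw both classes from their Gammas, split each class
    by ``eval_fraction`` (evaluation share), fit the logistic model on the
    training partition, and score the evaluation partition (ROC, AUC,
    Youden index, accuracy at the Youden-optimal cutoff).  Complete
    separation in a replicate is flagged, not fatal.
    """
    reps = [
        _classify_replicate(config, config.n_a, config.n_b, _substream(config.seed, r))
        for r in range(config.n_datasets)
    ]
    return _aggregate(reps)


def partition_sizes(n_class: int, fraction: float, eval_fraction: float = 0.8):
    """(scaled class size, evaluation count, training count) at one sweep fraction.

    The fraction scales the whole bootstrapped class (``m = round(f * n)``)
    which is then split ``eval_fraction`` : rest; rounding is
    round-half-to-even on the evaluation count.
    """
    m = int(np.round(fraction * n_class))
    n_eval = int(np.round(eval_fraction * m))
    return m, n_eval, m - n_eval


def sweep_test_size(
    config: PairConfig, fractions: Sequence[float] = DEFAULT_FRACTIONS
) -> List[SweepResult]:
    """Replicate classification at a ladder of bootstrapped dataset sizes.

    At each fraction f the per-class dataset size is ``round(f * n)`` and
    datasets are regenerated independently (substream (seed, fraction
    index, replicate)).  Fractions whose scaled size leaves an empty
    train or evaluation partition are reported invalid and skipped.
    """
    results: List[SweepResult] = []
    for fi, f in enumerate(fractions):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
        m_a, eval_a, train_a = partition_sizes(config.n_a, f, config.eval_fraction)
        m_b, eval_b, train_b = partition_sizes(config.n_b, f, config.eval_fraction)
        if min(eval_a, train_a, eval_b, train_b) < 1:
            results.append(SweepResult(fraction=float(f), valid=False, summary=None))
            continue
        reps = [
            _classify_replicate(config, m_a, m_b, _substream(config.seed, fi, r))
            for r in range(config.n_datasets)
        ]
        results.append(SweepResult(fraction=float(f), valid=True, summary=_aggregate(reps)))
    return results


def select_optimal_fraction(
    sweep: Sequence[SweepResult],
    auc_floor: float = 0.7,
    slope_tol: float = 0.01,
) -> float | None:
    """Smallest fraction meeting the two-fold optimisation criterion.

    Qualification requires (i) a plateaued mean AUC — the change to the
    next fraction is at most ``slope_tol`` (the last fraction has no next
    and qualifies on this clause) — and (ii) ``auc_mean - auc_sd`` above
    ``auc_floor``.  Returns None when no fraction qualifies.
    """
    valid = [s for s in sweep if s.valid]
    if len(valid) < 2:
        raise ValueError("sweep must contain at least two valid fractions")
    valid = sorted(valid, key=lambda s: s.fraction)
    for i, s in enumerate(valid):
        plateau = (
            i == len(valid) - 1
            or abs(s.auc_mean - valid[i + 1].auc_mean) <= slope_tol
        )
        if plateau and (s.auc_mean - s.auc_sd) > auc_floor:
            return s.fraction
    return None


def scan_time_reduction(optimal_fraction: float) -> float:
    """Projected % reduction of AFM usage time, assuming time linear in sample count."""
    if not 0.0 < optimal_fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return 100.0 * (1.0 - optimal_fraction)


def agreement_check(
    raw_auc: float, algo_mean: float, algo_sd: float, k: float = 2.0
) -> bool:
    """True iff the raw-data AUC lies within k standard deviations of the bootstrap mean."""
    if algo_sd < 0:
        raise ValueError("standard deviation must be >= 0")
    return abs(raw_auc - algo_mean) <= k * algo_sd
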