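"""Instrument-drift and environmental-shift QC.

Periodic stage drift during an AFM scan shows up as a sinusoidal trend in
pore radii taken in acquisition order.  A truncated Fourier series

    y(t) = a0 + sum_k [ a_k cos(k w t) + b_k sin(k w t) ],  t = 1..n

is fitted by least squares over both the coefficients and the fundamental
frequency ``w``; the adjusted coefficient of determination of the fit is
the drift indicator (near 1: strong periodicity; well below 1: negligible
drift).  Environmental shifts between scan locations are screened with
the Kruskal–Wallis test on values grouped by location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datasets import PoreMeasurementSet
from .distributions import KWResult, kruskal_wallis

#: Default decision threshold on adjusted R^2 separating "negligible
#: periodicity" (raw-data values of ~0.02-0.45) from near-unity fits that
#: signal real drift.
DEFAULT_DRIFT_THRESHOLD = 0.8

_BISQUARE_C = 4.685


@dataclass(frozen=True)
class DriftFitResult:
    fundamental_frequency: float  # cycles per acquisition index
    coefficients: np.ndarray  # [a0, a1, b1, ..., aH, bH]
    r2: float
    r2_adjusted: float
    robust: bool
    drift_flag: bool
    threshold: float


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1), p = predictor count."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 requires n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _design(t: np.ndarray, freq: float, harmonics: int) -> np.ndarray:
    cols = [np.ones_like(t)]
    for k in range(1, harmonics + 1):
        w = 2.0 * np.pi * k * freq
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


def _sse_at(freq: float, t: np.ndarray, y: np.ndarray, harmonics: int):
    X = _design(t, freq, harmonics)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _robust_coefficients(t, y, freq, harmonics, iterations=10):
    """IRLS with bisquare weights at fixed frequency."""
    X = _design(t, freq, harmonics)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(iterations):
        resid = y - X @ beta
        s = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if s <= 0:
            break
        u = resid / (_BISQUARE_C * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def fit_fourier(
    series,
    harmonics: int = 2,
    robust: bool = False,
    threshold: float = DEFAULT_DRIFT_THRESHOLD,
    n_freq_starts: int = 20,
) -> DriftFitResult:
    """Fit the truncated Fourier model over coefficients and fundamental frequency.

    The frequency is optimised by a multistart search: ``n_freq_starts``
    log-spaced fundamentals spanning (1/n, 1/2) cycles per index are each
    solved as a linear least-squares problem, and the best is refined by
    bounded scalar minimisation of the profile SSE.  With ``robust=True``
    the coefficients at the selected frequency are re-estimated by
    iteratively reweighted least squares with bisquare weights (tuning
    constant 4.685, 10 iterations); R^2 is always reported on unweighted
    residuals.

    The number of fitted parameters is ``2*harmonics + 2`` (constant, the
    harmonic amplitude pairs, and the frequency); the adjusted R^2 uses
    ``p = 2*harmonics + 1`` predictors beyond the constant.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    n_params = 2 * harmonics + 2
    if n <= n_params:
        raise ValueError(f"need more than {n_params} points for {harmonics} harmonics, got {n}")
    t = np.arange(1, n + 1, dtype=float)

    freqs = np.geomspace(1.0 / n, 0.5, n_freq_starts)
    sses = np.array([_sse_at(f, t, y, harmonics)[0] for f in freqs])
    i = int(np.argmin(sses))
    lo = freqs[max(i - 1, 0)]
    hi = freqs[min(i + 1, n_freq_starts - 1)]
    res = optimize.minimize_scalar(
        lambda f: _sse_at(f, t, y, harmonics)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    freq = float(res.x) if res.fun <= sses[i] else float(freqs[i])

    if robust:
        beta = _robust_coefficients(t, y, freq, harmonics)
        resid = y - _design(t, freq, harmonics) @ beta
        sse = float(resid @ resid)
    else:
        sse, beta = _sse_at(freq, t, y, harmonics)

    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r2a = adjusted_r2(r2, n, 2 * harmonics + 1)
    return DriftFitResult(
        fundamental_frequency=freq,
        coefficients=np.asarray(beta),
        r2=r2,
        r2_adjusted=r2a,
        robust=robust,
        drift_flag=r2a >= threshold,
        threshold=threshold,
    )


def location_shift_test(dataset: PoreMeasurementSet) -> KWResult:
    """Kruskal–Wallis screen for environmental shifts across scan locations.

    A p-value above the significance level means no detected shift in the
    pore-radius distribution between the scan locations of one dataset.
    """
    groups = list(dataset.groups_by_location().values())
    if len(groups) < 2:
        raise ValueError("location shift test requires at least two scan locations")
    return kruskal_wallis(groups)
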