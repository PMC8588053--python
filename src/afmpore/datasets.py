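"""Synthetic pore-measurement generator.

AFM pore-radius datasets are emulated as iid draws from a right-skewed
Gamma distribution, organised into scan-location blocks in acquisition
order, optionally perturbed with a sinusoidal instrument drift, per-location
mean offsets (environmental shifts) and multiplicative outliers.  Six
presets reproduce the published study conditions: three membrane classes
(50, 100 and 1000 kDa molecular weight cutoff) imaged in tapping mode
(n = 60 over 5 scan locations, 12 pores/location) and fluid mode (n = 304
over 4 locations, 76 pores/location), with Gamma parameters recovered from
the published per-dataset mean and skewness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np

from .distributions import GammaParams, gamma_fit_moments

MODES = ("tapping", "fluid")
MWCOS_KDA = (50, 100, 1000)

#: Published per-dataset (mean nm, skewness) by (mode, MWCO kDa).
FIXTURE_MOMENTS: Dict[Tuple[str, int], Tuple[float, float]] = {
    ("tapping", 1000): (9.45, 2.314),
    ("tapping", 100): (7.34, 2.599),
    ("tapping", 50): (5.65, 2.069),
    ("fluid", 1000): (15.3, 4.776),
    ("fluid", 100): (8.34, 2.833),
    ("fluid", 50): (11.1, 2.307),
}

#: Sample size and scan-location count per imaging mode.
MODE_DESIGN: Dict[str, Tuple[int, int]] = {"tapping": (60, 5), "fluid": (304, 4)}

#: Default master seed for the study presets (documented, arbitrary).
DEFAULT_FIXTURE_SEED = 20211108


@dataclass(frozen=True)
class PoreMeasurementSet:
    """Labeled pore-radius sample with acquisition metadata.

    ``values`` are radii in nm, strictly positive; ``location_ids`` and
    ``acquisition_index`` (1-based) run parallel to ``values``.
    """

    values: np.ndarray
    mwco_kda: int
    mode: str
    location_ids: np.ndarray
    acquisition_index: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "location_ids", np.asarray(self.location_ids))
        object.__setattr__(
            self, "acquisition_index", np.asarray(self.acquisition_index, dtype=int)
        )
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        n = self.values.size
        if n == 0:
            raise ValueError("measurement set must be non-empty")
        if self.location_ids.size != n or self.acquisition_index.size != n:
            raise ValueError("values, location_ids and acquisition_index must be equal length")
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("pore radii must be finite and > 0")
        if len(set(self.acquisition_index.tolist())) != n:
            raise ValueError("acquisition_index entries must be unique")

    @property
    def n(self) -> int:
        return self.values.size

    def groups_by_location(self) -> Dict[object, np.ndarray]:
        return {
            loc: self.values[self.location_ids == loc]
            for loc in np.unique(self.location_ids)
        }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings for one synthetic measurement set.

    ``location_shift`` gives one additive offset (nm) per location; drift is
    ``drift_amplitude * sin(2 pi t / drift_period)`` over acquisition index
    ``t``.  Outliers multiply a random subset of values by ``outlier_scale``.
    """

    gamma: GammaParams
    n: int
    n_locations: int
    seed: int = 0
    mwco_kda: int = 100
    mode: str = "tapping"
    drift_amplitude: float = 0.0
    drift_period: float = 20.0
    location_shift: Sequence[float] | None = None
    outlier_rate: float = 0.0
    outlier_scale: float = 3.0

    def __post_init__(self):
        if self.n < 1 or self.n_locations < 1:
            raise ValueError("n and n_locations must be >= 1")
        if self.n_locations > self.n:
            raise ValueError("cannot have more locations than measurements")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be > 0")
        if self.location_shift is not None and len(self.location_shift) != self.n_locations:
            raise ValueError("location_shift must supply one offset per location")


def _location_blocks(n: int, n_locations: int) -> np.ndarray:
    """Contiguous location labels, sizes as even as possible (remainder first)."""
    base, extra = divmod(n, n_locations)
    sizes = [base + (1 if i < extra else 0) for i in range(n_locations)]
    return np.repeat(np.arange(1, n_locations + 1), sizes)


def make_membrane_dataset(config: SyntheticConfig) -> PoreMeasurementSet:
    """Draw one synthetic measurement set.

    Base radii are iid Gamma(shape, scale); drift, per-location offsets
    and outliers are applied on top.  Perturbed values that would be
    non-positive are regenerated from a fresh base draw rather than
    truncated, so the output never carries a point mass near zero.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    t = np.arange(1, n + 1)
    locations = _location_blocks(n, config.n_locations)
    shifts = (
        np.asarray(config.location_shift, float)[locations - 1]
        if config.location_shift is not None
        else np.zeros(n)
    )
    drift = config.drift_amplitude * np.sin(2.0 * np.pi * t / config.drift_period)

    def perturb(base: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return base + drift[idx] + shifts[idx]

    base = rng.gamma(config.gamma.shape_a, config.gamma.scale_b, n)
    if config.outlier_rate > 0:
        mask = rng.random(n) < config.outlier_rate
        base[mask] *= config.outlier_scale
    values = perturb(base, np.arange(n))
    for _ in range(1000):
        bad = np.flatnonzero(values <= 0)
        if bad.size == 0:
            break
        redraw = rng.gamma(config.gamma.shape_a, config.gamma.scale_b, bad.size)
        values[bad] = perturb(redraw, bad)
    else:
        raise RuntimeError("could not generate strictly positive values; perturbations too large")

    return PoreMeasurementSet(
        values=values,
        mwco_kda=config.mwco_kda,
        mode=config.mode,
        location_ids=locations,
        acquisition_index=t,
    )


def fixture_gamma_params(mode: str, mwco_kda: int) -> GammaParams:
    """Gamma parameters implied by the published mean/skewness of one dataset."""
    mean, skew = FIXTURE_MOMENTS[(mode, mwco_kda)]
    return gamma_fit_moments(mean, skew)


def membrane_fixtures(
    seed: int = DEFAULT_FIXTURE_SEED,
) -> Dict[Tuple[str, int], PoreMeasurementSet]:
    """The six preset datasets (three MWCOs x two imaging modes).

    Each preset draws from the Gamma distribution matching its published
    mean and skewness, at the published design (tapping: n = 60 over 5
    locations; fluid: n = 304 over 4 locations), with a reproducible
    per-dataset substream of ``seed``.
    """
    out: Dict[Tuple[str, int], PoreMeasurementSet] = {}
    for mi, mode in enumerate(MODES):
        n, n_loc = MODE_DESIGN[mode]
        for ki, mwco in enumerate(MWCOS_KDA):
            sub = np.random.SeedSequence([seed, mi, ki]).generate_state(1)[0]
            cfg = SyntheticConfig(
                gamma=fixture_gamma_params(mode, mwco),
                n=n,
                n_locations=n_loc,
                seed=int(sub),
                mwco_kda=mwco,
                mode=mode,
            )
            out[(mode, mwco)] = make_membrane_dataset(cfg)
    return out


def inject_drift(
    dataset: PoreMeasurementSet, amplitude: float, period: float
) -> PoreMeasurementSet:
    """Add a sinusoidal drift ``amplitude * sin(2 pi t / period)`` to a set.

    Positive control for the drift detector; metadata are preserved.  An
    amplitude of 0 is a no-op.  Raises if the drifted values would violate
    positivity.
    """
    if period < 2:
        raise ValueError("drift period must be >= 2 acquisition steps")
    t = dataset.acquisition_index
    drifted = dataset.values + amplitude * np.sin(2.0 * np.pi * t / period)
    return replace(dataset, values=drifted)
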