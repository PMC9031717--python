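"""Square-wave voltammogram synthesis and peak extraction.

The ferrocene oxidation peak is modelled as a Gaussian net-current bell on
a linear capacitive baseline; its height is proportional to the fraction
of labelled strands still hybridized.  Extraction fits a straight baseline
through the two window edges and reads the maximum baseline-corrected
current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SWVParams",
    "FerrocenePeakModel",
    "Voltammogram",
    "PeakEstimate",
    "synth_voltammogram",
    "extract_peak",
]


class SWVError(ValueError):
    pass


@dataclass(frozen=True)
class SWVParams:
    """Square-wave voltammetry scan parameters (defaults: 0-0.7 V window,
    10 mV step, 0.1 V modulation amplitude, 25 Hz)."""

    potential_start: float = 0.0
    potential_end: float = 0.7
    step_potential: float = 0.010
    modulation_amplitude: float = 0.1
    frequency: float = 25.0

    def __post_init__(self) -> None:
        if not self.potential_start < self.potential_end:
            raise SWVError("potential_start must be below potential_end")
        if not self.step_potential > 0:
            raise SWVError("step_potential must be > 0")

    @property
    def n_points(self) -> int:
        span = self.potential_end - self.potential_start
        return int(round(span / self.step_potential)) + 1

    @property
    def potentials(self) -> np.ndarray:
        return self.potential_start + self.step_potential * np.arange(self.n_points)


@dataclass(frozen=True)
class FerrocenePeakModel:
    """Gaussian ferrocene oxidation peak on a linear baseline."""

    peak_potential: float = 0.35
    peak_width_sigma: float = 0.05
    max_current: float = 1.0
    baseline_intercept: float = 0.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.peak_width_sigma > 0:
            raise SWVError("peak_width_sigma must be > 0")
        if not self.max_current > 0:
            raise SWVError("max_current must be > 0")
        if self.noise_sd < 0:
            raise SWVError("noise_sd must be >= 0")

    def check_window(self, params: SWVParams) -> None:
        lo = params.potential_start + 2 * self.peak_width_sigma
        hi = params.potential_end - 2 * self.peak_width_sigma
        if not (lo <= self.peak_potential <= hi):
            warnings.warn(
                "peak_potential is within 2 sigma of the potential window edge",
                stacklevel=3,
            )


@dataclass
class Voltammogram:
    """Current vs potential at one (electrode, temperature)."""

    potentials: np.ndarray
    currents: np.ndarray
    electrode_id: str = ""
    temperature: float = float("nan")

    def __post_init__(self) -> None:
        p = np.asarray(self.potentials, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        self.potentials = p
        self.currents = i
        if p.ndim != 1 or p.shape != i.shape:
            raise SWVError("potentials and currents must be equal-length 1-D arrays")
        if len(p) > 1 and (np.diff(p) <= 0).any():
            raise SWVError("potentials must be strictly increasing")


@dataclass(frozen=True)
class PeakEstimate:
    height: float
    peak_potential: float


def synth_voltammogram(
    theta: float,
    peak: FerrocenePeakModel,
    params: SWVParams = SWVParams(),
    seed: Optional[int] = None,
    electrode_id: str = "",
    temperature: float = float("nan"),
    rng: Optional[np.random.Generator] = None,
) -> Voltammogram:
    """Forward model: i(E) = theta*Imax*exp(-(E-E0)^2/(2 sigma^2)) + baseline + noise.

    Reproducible per seed; an explicit ``rng`` can be passed instead to
    draw from a shared stream.
    """
    if not (0.0 <= theta <= 1.0):
        raise SWVError(f"theta must lie in [0, 1], got {theta!r}")
    peak.check_window(params)
    E = params.potentials
    i = theta * peak.max_current * np.exp(
        -((E - peak.peak_potential) ** 2) / (2.0 * peak.peak_width_sigma**2)
    )
    i = i + peak.baseline_intercept + peak.baseline_slope * E
    if peak.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, peak.noise_sd, size=E.shape)
    return Voltammogram(E, i, electrode_id=electrode_id, temperature=temperature)


def extract_peak(v: Voltammogram, baseline_window: int = 5) -> PeakEstimate:
    """Baseline-corrected peak height of a voltammogram.

    A straight baseline is drawn through the mean of the first and last
    ``baseline_window`` points; the height is the maximum corrected
    current over the interior points (ties toward lower potential),
    floored at 0.
    """
    if baseline_window < 1:
        raise SWVError("baseline_window must be >= 1")
    n = len(v.potentials)
    if n < 2 * baseline_window + 3:
        raise SWVError(
            f"need at least {2 * baseline_window + 3} points, got {n}"
        )
    E, i = v.potentials, v.currents
    e_lo = float(E[:baseline_window].mean())
    i_lo = float(i[:baseline_window].mean())
    e_hi = float(E[-baseline_window:].mean())
    i_hi = float(i[-baseline_window:].mean())
    slope = (i_hi - i_lo) / (e_hi - e_lo)
    baseline = i_lo + slope * (E - e_lo)
    corrected = i - baseline
    interior = slice(baseline_window, n - baseline_window)
    idx = int(np.argmax(corrected[interior])) + baseline_window
    height = max(0.0, float(corrected[idx]))
    return PeakEstimate(height=height, peak_potential=float(E[idx]))
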