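"""Melt-curve construction, first-derivative Tm calling and genotyping.

Works identically for electrochemical (SWV peak-height) and fluorescence
inputs: normalize to the pre-melt signal, smooth, differentiate, read the
melting temperature at the extremum of -dS/dT, aggregate replicates as
mean +- sample SD, and call genotypes from the Tm depression relative to
a wild-type reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "MeltCurve",
    "TmResult",
    "ReplicateSummary",
    "GenotypeCall",
    "build_melt_curve",
    "call_tm",
    "aggregate_replicates",
    "discriminate",
    "NoMeltTransition",
]

Modality = Literal["swv", "fluorescence"]


class PipelineError(ValueError):
    pass


class NoMeltTransition(PipelineError):
    """Raised when a curve shows no detectable melting transition."""


@dataclass
class MeltCurve:
    temperatures: np.ndarray
    normalized_signal: np.ndarray
    electrode_id: str = ""
    allele_hint: Optional[str] = None
    modality: Modality = "swv"
    n_reference: int = 3

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.normalized_signal, dtype=float)
        self.temperatures = t
        self.normalized_signal = s
        if t.ndim != 1 or t.shape != s.shape:
            raise PipelineError("temperatures and signal must be equal-length 1-D")
        if len(t) > 1 and (np.diff(t) <= 0).any():
            raise PipelineError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TmResult:
    tm: float
    derivative: np.ndarray
    derivative_temperatures: np.ndarray
    smoothing_used: str
    interpolated: bool


@dataclass(frozen=True)
class ReplicateSummary:
    mean_tm: float
    sd_tm: float  # NaN when n < 2
    n: int


@dataclass(frozen=True)
class GenotypeCall:
    call: Literal["wild_type", "variant", "indeterminate"]
    delta_tm: float
    threshold: float


def build_melt_curve(
    temperatures: Sequence[float],
    heights: Sequence[float],
    n_reference: int = 3,
    electrode_id: str = "",
    allele_hint: Optional[str] = None,
    modality: Modality = "swv",
) -> MeltCurve:
    """Normalize peak heights to the mean of the first ``n_reference``
    pre-melt points."""
    t = np.asarray(temperatures, dtype=float)
    h = np.asarray(heights, dtype=float)
    if n_reference < 1:
        raise PipelineError("n_reference must be >= 1")
    if len(h) < n_reference:
        raise PipelineError("fewer points than n_reference")
    ref = float(h[:n_reference].mean())
    if ref <= 0:
        raise PipelineError("no pre-melt signal: reference mean is not positive")
    return MeltCurve(
        t,
        h / ref,
        electrode_id=electrode_id,
        allele_hint=allele_hint,
        modality=modality,
        n_reference=n_reference,
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def call_tm(
    curve: MeltCurve,
    smoothing_window: int = 3,
    interpolate: bool = False,
    refine_points: int = 1,
    min_peak_snr: float = 5.0,
) -> TmResult:
    """First-derivative Tm call.

    The (optionally smoothed) normalized signal is differentiated by
    central differences on the actual temperature grid; Tm is the
    temperature of the maximum of -dS/dT, refined by a parabolic fit
    through the extremum and its ``refine_points`` neighbours per side
    when ``interpolate`` is set.  Ties break toward lower temperature.
    Raises :class:`NoMeltTransition` when the derivative extremum does
    not rise ``min_peak_snr`` times above the derivative's median
    absolute deviation.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise PipelineError("smoothing_window must be a positive odd integer")
    t = curve.temperatures
    s = curve.normalized_signal
    if len(t) < 7:
        raise PipelineError("need at least 7 points spanning the transition")
    smoothed = _moving_average(s, smoothing_window)
    deriv = np.gradient(smoothed, t)  # dS/dT on the (possibly non-uniform) grid
    neg = -deriv
    peak = float(neg.max())
    mad = float(np.median(np.abs(deriv - np.median(deriv))))
    if peak <= 0 or peak < min_peak_snr * mad:
        raise NoMeltTransition("no melting transition detected")
    if refine_points < 1:
        raise PipelineError("refine_points must be >= 1")
    idx = int(np.argmax(neg))  # argmax takes the first (lowest-T) maximum
    tm = float(t[idx])
    interpolated = False
    if interpolate and 0 < idx < len(t) - 1:
        lo = max(0, idx - refine_points)
        hi = min(len(t), idx + refine_points + 1)
        a, b, _ = np.polyfit(t[lo:hi], neg[lo:hi], 2)
        if a < 0:
            vertex = -b / (2 * a)
            if t[lo] <= vertex <= t[hi - 1]:
                tm = float(vertex)
                interpolated = True
    return TmResult(
        tm=tm,
        derivative=deriv,
        derivative_temperatures=t.copy(),
        smoothing_used=f"moving_average(window={smoothing_window})",
        interpolated=interpolated,
    )


def aggregate_replicates(results: Sequence[TmResult | float]) -> ReplicateSummary:
    """Mean +- sample SD (n-1 denominator) of replicate Tm calls."""
    if len(results) == 0:
        raise PipelineError("no replicates to aggregate")
    tms = np.array(
        [r.tm if isinstance(r, TmResult) else float(r) for r in results], dtype=float
    )
    mean = float(tms.mean())
    sd = float(tms.std(ddof=1)) if len(tms) >= 2 else float("nan")
    return ReplicateSummary(mean_tm=mean, sd_tm=sd, n=len(tms))


def discriminate(
    sample: ReplicateSummary,
    wild_type_reference: ReplicateSummary,
    threshold: float = 2.0,
) -> GenotypeCall:
    """Two-class call from the Tm depression relative to wild type.

    variant if delta_tm >= threshold; indeterminate when the depression
    is below threshold but still exceeds both replicate SDs; wild_type
    otherwise.
    """
    delta = wild_type_reference.mean_tm - sample.mean_tm
    if not (math.isfinite(delta) and math.isfinite(threshold)):
        raise PipelineError("summaries and threshold must be finite")
    sds = [x for x in (sample.sd_tm, wild_type_reference.sd_tm) if math.isfinite(x)]
    max_sd = max(sds) if sds else 0.0
    if delta >= threshold:
        call = "variant"
    elif delta > max_sd:
        call = "indeterminate"
    else:
        call = "wild_type"
    return GenotypeCall(call=call, delta_tm=delta, threshold=threshold)
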