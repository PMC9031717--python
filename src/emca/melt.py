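"""Two-state duplex melting model with mismatch-position destabilization.

The hybridized fraction of a surface-tethered probe-target duplex follows
a unimolecular two-state van't Hoff sigmoid.  Single-base mismatches
depress the melting midpoint by a position-dependent penalty (largest for
a central mismatch), and continuous washing makes the measured signal
irreversible: once strands melt off and are flushed away they do not
rebind, so the observable fraction is the running minimum of the
equilibrium fraction along the ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal

import numpy as np

GAS_CONSTANT = 8.314  # J / mol / K
CELSIUS_OFFSET = 273.15

ALLELES = ("full", "bottom", "top", "middle")
Allele = Literal["full", "bottom", "top", "middle"]
Phase = Literal["surface", "solution"]

__all__ = [
    "ALLELES",
    "DuplexSpec",
    "MismatchPenaltySet",
    "hybridized_fraction",
    "effective_tm",
    "washed_fraction",
]


class MeltModelError(ValueError):
    pass


@dataclass(frozen=True)
class DuplexSpec:
    """One surface-tethered probe-target duplex.

    ``surface_tm`` is the melting midpoint of the fully matched duplex on
    the electrode surface (degC); ``vant_hoff_enthalpy`` is the effective
    dissociation enthalpy in kJ/mol setting the transition sharpness;
    ``solution_offset`` is added to obtain the solution-phase midpoint
    (surface duplexes melt roughly 10 degC lower than in solution).
    """

    name: str
    allele: Allele
    surface_tm: float
    vant_hoff_enthalpy: float = 300.0
    solution_offset: float = 10.0

    def __post_init__(self) -> None:
        if self.allele not in ALLELES:
            raise MeltModelError(f"unknown allele class {self.allele!r}")
        if not self.vant_hoff_enthalpy > 0:
            raise MeltModelError("vant_hoff_enthalpy must be > 0 (dissociation)")
        if not (0.0 < self.surface_tm < 100.0):
            raise MeltModelError("surface_tm must lie in (0, 100) degC")


@dataclass(frozen=True)
class MismatchPenaltySet:
    """Tm depression per mismatch position class, degC.

    Invariant: middle >= top >= bottom >= 0 and full == 0, mirroring the
    observation that a central mismatch destabilizes the duplex most.
    """

    delta_tm: Dict[str, float] = field(
        default_factory=lambda: {"full": 0.0, "bottom": 0.8, "top": 2.1, "middle": 4.3}
    )

    def __post_init__(self) -> None:
        d = self.delta_tm
        missing = [a for a in ALLELES if a not in d]
        if missing:
            raise MeltModelError(f"penalty set missing allele classes: {missing}")
        if d["full"] != 0.0:
            raise MeltModelError("delta_tm['full'] must be 0")
        if not (d["middle"] >= d["top"] >= d["bottom"] >= 0.0):
            raise MeltModelError(
                "penalty ordering violated: require middle >= top >= bottom >= 0"
            )

    def __getitem__(self, allele: str) -> float:
        try:
            return self.delta_tm[allele]
        except KeyError:
            raise MeltModelError(f"unknown allele class {allele!r}") from None


def hybridized_fraction(temperature, duplex: DuplexSpec, tm: float | None = None):
    """Equilibrium hybridized fraction theta(T) of a two-state duplex.

    theta(T) = 1 / (1 + exp[(dH/R) * (1/Tm - 1/T)]) with T and Tm in
    Kelvin and dH the dissociation van't Hoff enthalpy.  Strictly
    decreasing in T with theta(Tm) = 0.5.  ``tm`` overrides the duplex's
    own surface midpoint (used for penalty-shifted or solution-phase
    evaluation); scalar in, scalar out.
    """
    T = np.asarray(temperature, dtype=float)
    tm_c = duplex.surface_tm if tm is None else tm
    t_kelvin = T + CELSIUS_OFFSET
    if np.any(t_kelvin <= 0):
        raise MeltModelError("absolute temperature must be positive")
    tm_kelvin = tm_c + CELSIUS_OFFSET
    dh = duplex.vant_hoff_enthalpy * 1e3  # kJ/mol -> J/mol
    arg = (dh / GAS_CONSTANT) * (1.0 / tm_kelvin - 1.0 / t_kelvin)
    # clip the exponent to avoid overflow; theta saturates at 0/1 anyway
    theta = 1.0 / (1.0 + np.exp(np.clip(arg, -700.0, 700.0)))
    return float(theta) if np.isscalar(temperature) else theta


def effective_tm(
    duplex: DuplexSpec, penalties: MismatchPenaltySet, phase: Phase = "surface"
) -> float:
    """Melting midpoint after mismatch penalty, on the surface or in solution."""
    if phase not in ("surface", "solution"):
        raise MeltModelError(f"unknown phase {phase!r}")
    tm = duplex.surface_tm - penalties[duplex.allele]
    if phase == "solution":
        tm += duplex.solution_offset
    return tm


def washed_fraction(equilibrium_fractions: Iterable[float]) -> List[float]:
    """Irreversible (continuously washed) signal: the running minimum.

    Output is non-increasing and pointwise <= input; idempotent.
    """
    out: List[float] = []
    current = np.inf
    for i, f in enumerate(equilibrium_fractions):
        if not (0.0 <= f <= 1.0):
            raise MeltModelError(f"fraction out of [0, 1] at index {i}: {f!r}")
        current = min(current, float(f))
        out.append(current)
    return out
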