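"""End-to-end synthetic experiment generator.

Stands in for the instrument: a 9-electrode gold array (8 assay
electrodes = 4 alleles in duplicate + 1 ferrocene-thiol control) ramped
25 -> 95 degC at 1 degC per step while square-wave voltammograms are
recorded at every step.  Each assay electrode carries one duplex whose
equilibrium hybridized fraction is rendered irreversible by continuous
washing before being turned into a ferrocene peak.  Everything is seeded
and deterministic; a truth table records the generator's effective Tm per
electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd

from .melt import (
    ALLELES,
    DuplexSpec,
    MismatchPenaltySet,
    effective_tm,
    hybridized_fraction,
    washed_fraction,
)
from .swv import FerrocenePeakModel, SWVParams, Voltammogram, synth_voltammogram
from .thermal import RampProtocol

__all__ = [
    "Electrode",
    "ArrayLayout",
    "ExperimentConfig",
    "ExperimentResult",
    "default_layout",
    "simulate_experiment",
    "simulate_fluorescence_mca",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Electrode:
    id: str
    role: Literal["assay", "control"]
    allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role == "assay" and self.allele not in ALLELES:
            raise SimulationError(
                f"assay electrode {self.id!r} needs an allele class, got {self.allele!r}"
            )


@dataclass(frozen=True)
class ArrayLayout:
    """Working-electrode layout; counter/reference electrodes are metadata only."""

    electrodes: tuple[Electrode, ...]
    counter_note: str = "rectangular counter electrode, 4 mm2 (metadata only)"

    def __post_init__(self) -> None:
        ids = [e.id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate electrode ids in layout")

    @property
    def assay_electrodes(self) -> List[Electrode]:
        return [e for e in self.electrodes if e.role == "assay"]

    @property
    def control_electrodes(self) -> List[Electrode]:
        return [e for e in self.electrodes if e.role == "control"]


def default_layout() -> ArrayLayout:
    """Nine working electrodes: four alleles in duplicate plus one control."""
    electrodes = []
    i = 1
    for allele in ALLELES:
        for _ in range(2):
            electrodes.append(Electrode(id=f"e{i}", role="assay", allele=allele))
            i += 1
    electrodes.append(Electrode(id=f"e{i}", role="control"))
    return ArrayLayout(electrodes=tuple(electrodes))


def default_duplexes(
    base_tm: float = 37.0, enthalpy: float = 300.0, solution_offset: float = 10.0
) -> Dict[str, DuplexSpec]:
    return {
        allele: DuplexSpec(
            name=f"{allele}-duplex",
            allele=allele,  # type: ignore[arg-type]
            surface_tm=base_tm,
            vant_hoff_enthalpy=enthalpy,
            solution_offset=solution_offset,
        )
        for allele in ALLELES
    }


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int
    layout: ArrayLayout = field(default_factory=default_layout)
    ramp: RampProtocol = field(
        default_factory=lambda: RampProtocol(start=25.0, end=95.0, step=1.0)
    )
    duplexes: Dict[str, DuplexSpec] = field(default_factory=default_duplexes)
    penalties: MismatchPenaltySet = field(default_factory=MismatchPenaltySet)
    peak_model: FerrocenePeakModel = field(default_factory=FerrocenePeakModel)
    swv: SWVParams = field(default_factory=SWVParams)
    electrode_scale_sd: float = 0.0  # relative per-electrode max_current spread

    def __post_init__(self) -> None:
        for e in self.layout.assay_electrodes:
            if e.allele not in self.duplexes:
                raise SimulationError(
                    f"electrode {e.id!r} carries allele {e.allele!r} "
                    "with no duplex spec"
                )


@dataclass
class ExperimentResult:
    voltammograms: List[Voltammogram]
    truth: pd.DataFrame
    config: ExperimentConfig


def _electrode_fractions(
    electrode: Electrode, config: ExperimentConfig, temperatures: np.ndarray
) -> np.ndarray:
    if electrode.role == "control":
        # chemisorbed ferrocene-thiol: no duplex, stable signal
        return np.ones_like(temperatures)
    duplex = config.duplexes[electrode.allele]  # type: ignore[index]
    tm = effective_tm(duplex, config.penalties, phase="surface")
    eq = hybridized_fraction(temperatures, duplex, tm=tm)
    return np.asarray(washed_fraction(eq))


def simulate_experiment(config: ExperimentConfig) -> ExperimentResult:
    """One full ramp: per electrode per temperature, equilibrium fraction ->
    washed fraction -> voltammogram.  Same seed, same output, always."""
    temperatures = config.ramp.temperatures
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.layout.electrodes))

    voltammograms: List[Voltammogram] = []
    truth_rows = []
    for electrode, child in zip(config.layout.electrodes, children):
        rng = np.random.default_rng(child)
        scale = 1.0
        if config.electrode_scale_sd > 0:
            scale = max(0.05, 1.0 + rng.normal(0.0, config.electrode_scale_sd))
        peak = replace(config.peak_model, max_current=config.peak_model.max_current * scale)
        fractions = _electrode_fractions(electrode, config, temperatures)
        for T, theta in zip(temperatures, fractions):
            voltammograms.append(
                synth_voltammogram(
                    float(theta),
                    peak,
                    config.swv,
                    electrode_id=electrode.id,
                    temperature=float(T),
                    rng=rng,
                )
            )
        if electrode.role == "control":
            tm_truth = float("nan")
        else:
            tm_truth = effective_tm(
                config.duplexes[electrode.allele], config.penalties, "surface"
            )
        truth_rows.append(
            {
                "electrode_id": electrode.id,
                "role": electrode.role,
                "allele": electrode.allele if electrode.allele else "",
                "effective_tm_C": tm_truth,
                "max_current_scale": scale,
                "seed": config.seed,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return ExperimentResult(voltammograms=voltammograms, truth=truth, config=config)


def simulate_fluorescence_mca(
    duplex: DuplexSpec,
    penalties: MismatchPenaltySet,
    ramp: RampProtocol = RampProtocol(start=25.0, end=95.0, step=1.0),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    max_intensity: float = 1.0,
) -> pd.DataFrame:
    """Cuvette melt: intensity proportional to the equilibrium hybridized
    fraction at the solution-phase midpoint (surface Tm + solution offset);
    no washing, so the underlying signal is reversible/equilibrium.
    Returns columns ``temperature_C`` and ``intensity``."""
    temperatures = ramp.temperatures
    tm = effective_tm(duplex, penalties, phase="solution")
    intensity = max_intensity * hybridized_fraction(temperatures, duplex, tm=tm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return pd.DataFrame({"temperature_C": temperatures, "intensity": intensity})
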