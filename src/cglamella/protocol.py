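"""Self-assembly protocol arithmetic: initial box sizing, the estimated
leaflet area, and the shape-annealing / temperature-ramp schedule.

The schedule is emitted as data (a phase table any MD driver can
consume); no simulation engine is bound or executed.  Shape annealing
expands the box cross-section to 2.5x the estimated leaflet area at
constant volume and high temperature, then compresses back while cooling
— a procedure that accelerates lamellar self-assembly and helps escape
metastable states — followed by an NPT heating/cooling ramp and a
production run at physiological conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .topology import CompositionSpec, TopologyError, composition_counts, default_registry

__all__ = ["Phase", "AnnealSchedule", "estimate_area", "initial_box", "build_schedule"]

AMU_TO_G = 1.66053906892e-24
CM3_TO_NM3 = 1e21


@dataclass(frozen=True)
class Phase:
    """One schedule phase.  Area/temperature pairs are (start, end); equal
    entries mean a constant value, differing entries a linear ramp."""

    name: str
    stage: str  # "prelude" | "anneal" | "production"
    ensemble: str  # "NVE" | "NVT" | "NPT"
    duration_ns: float
    temperature_K: tuple[float, float]
    area_nm2: tuple[float, float] | None = None  # NVT phases: box-area target
    pressure_bar: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.duration_ns <= 0:
            raise ValueError(f"phase {self.name}: duration must be > 0")
        if self.area_nm2 is not None and min(self.area_nm2) <= 0:
            raise ValueError(f"phase {self.name}: area targets must be > 0")

    def temperature_at(self, frac: float) -> float:
        """Linear ramp: temperature at a fraction of the phase duration."""
        t0, t1 = self.temperature_K
        return t0 + (t1 - t0) * frac


@dataclass
class AnnealSchedule:
    phases: list[Phase]
    a_est_nm2: float

    @property
    def total_ns(self) -> float:
        """Scheduled time over the anneal + production phases (the
        equilibration preludes are listed but not counted)."""
        return sum(p.duration_ns for p in self.phases if p.stage != "prelude")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.phases:
            rows.append(
                {
                    "phase": p.name,
                    "stage": p.stage,
                    "ensemble": p.ensemble,
                    "duration_ns": p.duration_ns,
                    "T_start_K": p.temperature_K[0],
                    "T_end_K": p.temperature_K[1],
                    "area_start_nm2": None if p.area_nm2 is None else p.area_nm2[0],
                    "area_end_nm2": None if p.area_nm2 is None else p.area_nm2[1],
                    "pressure_bar": p.pressure_bar,
                    "note": p.note,
                }
            )
        return pd.DataFrame(rows)

    def write_text(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def estimate_area(apl_est: float, n_lipids: int, n_leaflets: int) -> float:
    """Estimated leaflet area: A_est = APL_est · N_lipids / N_leaflets (nm²)."""
    if apl_est <= 0 or n_lipids <= 0:
        raise ValueError("apl_est and n_lipids must be > 0")
    if n_leaflets <= 0:
        raise ValueError("n_leaflets must be > 0")
    return apl_est * n_lipids / n_leaflets


def initial_box(
    spec: CompositionSpec,
    target_area: float,
    lipid_masses: Mapping[str, float] | None = None,
    lipid_density: float = 0.8,
    water_density: float = 1.0,
) -> tuple[float, float, float]:
    """Initial box (Lx, Ly, Lz) in nm for random packing before assembly.

    Lipid and water volumes follow from their masses at the packing
    densities (g/cm³); the z length is volume / cross-sectional area and
    the x, y lengths are the square root of the target area.  Default
    molecular masses come from the built-in templates.
    """
    if target_area <= 0:
        raise ValueError("target_area must be > 0")
    if lipid_masses is None:
        lipid_masses = {s: t.molecular_mass for s, t in default_registry().items()}
    counts = composition_counts(spec)
    lipid_amu = 0.0
    for sp, n in counts.items():
        if sp not in lipid_masses:
            raise TopologyError(f"no molecular mass for species {sp!r}")
        lipid_amu += n * lipid_masses[sp]
    water_amu = spec.water_beads_per_lipid * spec.n_lipids * lipid_masses.get(
        "WATER", default_registry()["WATER"].molecular_mass
    )
    v_lipid = lipid_amu * AMU_TO_G / lipid_density * CM3_TO_NM3
    v_water = water_amu * AMU_TO_G / water_density * CM3_TO_NM3
    lz = (v_lipid + v_water) / target_area
    lx = ly = target_area**0.5
    return lx, ly, lz


def build_schedule(
    a_est: float,
    include_preludes: bool = True,
    t_assembly: float = 305.0,
    t_anneal: float = 500.0,
    t_heat: float = 400.0,
) -> AnnealSchedule:
    """The shape-annealing and heating/cooling schedule for one assembly.

    Phases (after the optional equilibration preludes): NVT expansion of
    the box area to 2.5·A_est over 150 ns at 500 K, NVT compression back
    to A_est over 150 ns with a linear 500→305 K ramp, NPT heating
    305→400 K over 100 ns, NPT cooling 400→305 K over 50 ns, and a 150 ns
    NPT production run at 305 K and 1 bar.
    """
    if a_est <= 0:
        raise ValueError("a_est must be > 0")
    phases: list[Phase] = []
    if include_preludes:
        phases += [
            Phase(
                "nve-overlap-relax", "prelude", "NVE", 0.01, (105.0, 105.0),
                note="displacement-limited integration (engine-specific cap, ~0.1 Å/step)",
            ),
            Phase("nve-warm", "prelude", "NVE", 0.01, (t_assembly, t_assembly)),
            Phase(
                "npt-density-equil", "prelude", "NPT", 10.0,
                (t_assembly, t_assembly), pressure_bar=1.0,
            ),
        ]
    phases += [
        Phase(
            "nvt-expand", "anneal", "NVT", 150.0, (t_anneal, t_anneal),
            area_nm2=(a_est, 2.5 * a_est),
            note="constant volume: box height shrinks as the area grows",
        ),
        Phase(
            "nvt-compress", "anneal", "NVT", 150.0, (t_anneal, t_assembly),
            area_nm2=(2.5 * a_est, a_est),
            note="constant volume, linear temperature ramp",
        ),
        Phase(
            "npt-heat", "anneal", "NPT", 100.0, (t_assembly, t_heat), pressure_bar=1.0,
            note="semi-isotropic pressure coupling in the x-y plane",
        ),
        Phase("npt-cool", "anneal", "NPT", 50.0, (t_heat, t_assembly), pressure_bar=1.0),
        Phase(
            "npt-production", "production", "NPT", 150.0,
            (t_assembly, t_assembly), pressure_bar=1.0,
        ),
    ]
    return AnnealSchedule(phases=phases, a_est_nm2=a_est)
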