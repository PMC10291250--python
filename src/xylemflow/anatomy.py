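"""Anatomical hydraulic traits from conduit-level measurements.

A cross-section is measured inside a radial sector ("wedge") of known area;
each water-conducting conduit contributes its lumen area (or, equivalently, a
circle-equivalent lumen diameter).  From these the module derives

* conduit density  CD  (n mm^-2),
* lumen fraction   F   (% of sector area occupied by lumina),
* mean and hydraulically weighted conduit diameter  D_mean, D_h  (µm),
* potential xylem-specific conductivity  KS_pot  (kg m^-1 MPa^-1 s^-1)
  from the Hagen-Poiseuille law,  KS_pot = π ρ ΣD⁴ / (128 η A_xylem).

All public interfaces use µm / µm² (the scale of light-microscopy data);
conversion to SI happens internally, once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "PhysicalConstants",
    "ConduitSet",
    "AnatomyTraits",
    "equivalent_diameter",
    "hydraulic_diameter",
    "conduit_density",
    "lumen_fraction",
    "potential_conductivity",
    "anatomy_traits",
]

#: metres per micrometre
_UM = 1e-6
#: mm² per µm²
_UM2_TO_MM2 = 1e-6

DhMethod = Literal["d5_over_d4", "fourth_moment"]


@dataclass(frozen=True)
class PhysicalConstants:
    """Water properties at 20 °C used by the Hagen-Poiseuille equation.

    eta : dynamic viscosity of water, MPa s (1.002e-9 MPa s = 1.002 mPa s)
    rho : density of water, kg m^-3
    """

    eta: float = 1.002e-9
    rho: float = 998.2


WATER_20C = PhysicalConstants()


@dataclass
class ConduitSet:
    """Conduit lumen measurements inside one radial sector of one sample.

    ``lumen_areas`` are µm²; if the raw data supplied diameters instead,
    construct via :meth:`from_diameters` (the flag ``from_diameters`` records
    which was measured).
    """

    sample_id: str
    organ: str  # "root" | "branch"
    sector_angle: float  # degrees, 20-70 in typical wedge measurements
    sector_area: float  # µm²
    lumen_areas: np.ndarray  # µm², one entry per conduit
    from_diameters: bool = False

    def __post_init__(self) -> None:
        self.lumen_areas = np.asarray(self.lumen_areas, dtype=float)
        if self.sector_area <= 0:
            raise ValueError("sector_area must be positive")
        if self.lumen_areas.size < 1:
            raise ValueError("a ConduitSet needs at least one conduit")
        if np.any(self.lumen_areas <= 0):
            raise ValueError("all lumen areas must be positive")
        if self.lumen_areas.sum() > self.sector_area * (1 + 1e-9):
            raise ValueError(
                "total lumen area exceeds sector area (inconsistent measurement)"
            )

    @classmethod
    def from_diameters(
        cls,
        sample_id: str,
        organ: str,
        sector_angle: float,
        sector_area: float,
        diameters_um: Sequence[float],
    ) -> "ConduitSet":
        d = np.asarray(diameters_um, dtype=float)
        if np.any(d <= 0):
            raise ValueError("all diameters must be positive")
        return cls(
            sample_id=sample_id,
            organ=organ,
            sector_angle=sector_angle,
            sector_area=sector_area,
            lumen_areas=math.pi / 4.0 * d**2,
            from_diameters=True,
        )

    @property
    def n_conduits(self) -> int:
        return int(self.lumen_areas.size)

    def diameters(self) -> np.ndarray:
        """Circle-equivalent lumen diameters, µm."""
        return equivalent_diameter(self.lumen_areas)


@dataclass(frozen=True)
class AnatomyTraits:
    """Derived sector-level anatomical traits (units in field names' docs)."""

    sample_id: str
    organ: str
    n_conduits: int
    CD: float  # conduits mm^-2
    F: float  # lumen fraction, %
    D_mean: float  # µm
    D_h: float  # µm
    KS_pot: float  # kg m^-1 MPa^-1 s^-1


def equivalent_diameter(lumen_area):
    """Circle-equivalent diameter (µm) of a lumen area (µm²): 2·sqrt(A/π)."""
    a = np.asarray(lumen_area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("lumen area must be positive")
    out = 2.0 * np.sqrt(a / math.pi)
    return float(out) if np.isscalar(lumen_area) else out


def hydraulic_diameter(
    diameters: Iterable[float], method: DhMethod = "d5_over_d4"
) -> float:
    """Hydraulically weighted conduit diameter D_h (µm).

    Two conventions are in circulation and both are implemented:

    * ``d5_over_d4``:  Σd⁵/Σd⁴ — weights each conduit by its Poiseuille
      contribution (d⁴); consistent with the conductivity weighting used by
      the rest of the pipeline.  Default.
    * ``fourth_moment``: (Σd⁴/n)^(1/4) — the diameter of the uniform conduit
      population with the same mean fourth moment.

    Both reduce to d when all conduits are identical.
    """
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("all diameters must be positive")
    d4 = d**4
    if method == "d5_over_d4":
        return float((d4 * d).sum() / d4.sum())
    if method == "fourth_moment":
        return float(d4.mean() ** 0.25)
    raise ValueError(f"unknown D_h method: {method!r}")


def conduit_density(n: int, sector_area: float) -> float:
    """Conduit density CD (n mm^-2) from a count and a sector area in µm²."""
    if sector_area <= 0:
        raise ValueError("sector_area must be positive")
    if n < 0:
        raise ValueError("conduit count cannot be negative")
    return n / (sector_area * _UM2_TO_MM2)


def lumen_fraction(lumen_areas: Iterable[float], sector_area: float) -> float:
    """Lumen fraction F (%): summed lumen area over sector (woody) area."""
    a = np.asarray(list(lumen_areas), dtype=float)
    if sector_area <= 0:
        raise ValueError("sector_area must be positive")
    total = a.sum() if a.size else 0.0
    if total > sector_area * (1 + 1e-9):
        raise ValueError("total lumen area exceeds sector area")
    return 100.0 * total / sector_area


def potential_conductivity(
    diameters: Iterable[float],
    reference_area: float,
    constants: PhysicalConstants = WATER_20C,
    unit: Literal["um", "mm", "m"] = "um",
) -> float:
    """Hagen-Poiseuille potential conductivity per xylem area.

    KS_pot = π ρ ΣD⁴ / (128 η A),  in kg m^-1 MPa^-1 s^-1.

    ``diameters`` and ``reference_area`` are interpreted in ``unit`` and
    ``unit``² respectively (µm by default) and converted to SI internally.
    """
    scale = {"um": 1e-6, "mm": 1e-3, "m": 1.0}[unit]
    d = np.asarray(list(diameters), dtype=float) * scale
    a = reference_area * scale**2
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("all diameters must be positive")
    if a <= 0:
        raise ValueError("reference area must be positive")
    return float(math.pi * constants.rho * (d**4).sum() / (128.0 * constants.eta * a))


def anatomy_traits(
    conduits: ConduitSet,
    constants: PhysicalConstants = WATER_20C,
    dh_method: DhMethod = "d5_over_d4",
) -> AnatomyTraits:
    """All five sector-level traits for one ConduitSet.

    KS_pot uses the sector's own woody area as the reference xylem area (it
    must never be mixed with the flow module's segment-level A_xylem).
    """
    d = conduits.diameters()
    return AnatomyTraits(
        sample_id=conduits.sample_id,
        organ=conduits.organ,
        n_conduits=conduits.n_conduits,
        CD=conduit_density(conduits.n_conduits, conduits.sector_area),
        F=lumen_fraction(conduits.lumen_areas, conduits.sector_area),
        D_mean=float(d.mean()),
        D_h=hydraulic_diameter(d, method=dh_method),
        KS_pot=potential_conductivity(d, conduits.sector_area, constants),
    )
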