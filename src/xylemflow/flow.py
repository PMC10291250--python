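"""Gravimetric hydraulic-conductivity processing.

A segment (2nd-year branch or coarse root) is perfused with filtered KCl
solution under a small static head; the steady mass flow gives the axial
conductivity

    K_h = F · l / Δp      (kg m MPa^-1 s^-1),

with F the mass flow (kg s^-1), l the sample length (m) and Δp the head
(MPa).  Segments are then flushed at high pressure until the conductivity
plateaus (k_max, removal of emboli/plugging).  Derived quantities:

* KS_hydr = K_h(max) / A_xylem     xylem-specific conductivity,
* K_L     = K_h(max) / A_leaf      leaf-specific conductivity (branches),
* HV      = A_xylem / A_leaf       Huber value (branches).

A_xylem is the ellipse from two crosswise caliper diameters at the basal end
(branches, minus the pith ellipse) or the distal end (roots).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

__all__ = [
    "FlowRecord",
    "SegmentGeometry",
    "HydraulicTraits",
    "axial_conductivity",
    "xylem_area",
    "select_kmax",
    "specific_conductivity",
    "leaf_specific_conductivity",
    "huber_value",
    "hydraulic_traits",
]

log = logging.getLogger(__name__)

#: kg s^-1 per g h^-1
G_PER_H_TO_KG_PER_S = 1e-3 / 3600.0
#: MPa per kPa
KPA_TO_MPA = 1e-3
#: m per mm
MM = 1e-3


@dataclass(frozen=True)
class FlowRecord:
    """One gravimetric measurement at one flushing stage.

    ``stage`` is ``"initial"`` (native state, before flushing) or
    ``"flush_1"`` … ``"flush_k"`` in flushing order.
    """

    sample_id: str
    stage: str
    pressure_head: float  # kPa
    mass_flow: float  # g h^-1
    solution: str = "10 mM KCl"

    def __post_init__(self) -> None:
        if self.pressure_head <= 0:
            raise ValueError("pressure head must be positive")
        if self.mass_flow < 0:
            raise ValueError("mass flow cannot be negative")

    @property
    def flush_index(self) -> Optional[int]:
        if self.stage == "initial":
            return None
        if self.stage.startswith("flush_"):
            return int(self.stage.split("_", 1)[1])
        raise ValueError(f"unrecognised stage label: {self.stage!r}")


@dataclass
class SegmentGeometry:
    """Debarked segment (or stem core) geometry and dry mass.

    Outer xylem diameters are crosswise caliper readings in mm at each end;
    pith diameters only apply to branches.  ``core_length`` is used for stem
    cores instead of end diameters.
    """

    sample_id: str
    organ: str  # "root" | "branch" | "stem_core"
    length: float  # m
    end1_d1: Optional[float] = None  # mm
    end1_d2: Optional[float] = None
    end2_d1: Optional[float] = None
    end2_d2: Optional[float] = None
    pith_d1: Optional[float] = None  # mm, branches only
    pith_d2: Optional[float] = None
    dry_mass: Optional[float] = None  # g
    core_length_mm: Optional[float] = None  # stem cores

    def __post_init__(self) -> None:
        if self.length <= 0 and self.organ != "stem_core":
            raise ValueError("segment length must be positive")
        for name in ("end1_d1", "end1_d2", "end2_d1", "end2_d2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.has_pith:
            for p, d1, d2 in (
                (self.pith_d1, self.end1_d1, self.end2_d1),
                (self.pith_d2, self.end1_d2, self.end2_d2),
            ):
                for d in (d1, d2):
                    if d is not None and p is not None and p >= d:
                        raise ValueError("pith diameter must be smaller than xylem")

    @property
    def has_pith(self) -> bool:
        return self.pith_d1 is not None and self.pith_d2 is not None


@dataclass(frozen=True)
class HydraulicTraits:
    """Per-sample measured hydraulic traits (SI units throughout)."""

    sample_id: str
    organ: str
    K_h: float  # kg m MPa^-1 s^-1, after flushing (k_max)
    K_h_initial: Optional[float]  # native state, diagnostic only
    A_xylem: float  # m²
    KS_hydr: float  # kg m^-1 MPa^-1 s^-1
    K_L: Optional[float] = None  # branches with leaf area
    HV: Optional[float] = None  # m² m^-²


def axial_conductivity(mass_flow: float, pressure_head: float, length: float) -> float:
    """K_h (kg m MPa^-1 s^-1) from flow (g h^-1), head (kPa) and length (m)."""
    if pressure_head <= 0:
        raise ValueError("pressure head must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    if mass_flow < 0:
        raise ValueError("mass flow cannot be negative")
    return mass_flow * G_PER_H_TO_KG_PER_S * length / (pressure_head * KPA_TO_MPA)


def _ellipse_area_m2(d1_mm: float, d2_mm: float) -> float:
    return math.pi * (d1_mm * MM) * (d2_mm * MM) / 4.0


def xylem_area(
    geometry: SegmentGeometry, end: Literal["basal", "distal"] | None = None
) -> float:
    """Xylem cross-sectional area (m²) at the measurement end.

    Convention: the basal end for branches, the distal end for roots (the
    end attached to the tubing).  ``end1`` holds the measurement end's
    diameters.  The pith ellipse is subtracted for branches that have pith
    diameters recorded.
    """
    if end is None:
        end = "basal" if geometry.organ == "branch" else "distal"
    if geometry.end1_d1 is None or geometry.end1_d2 is None:
        raise ValueError("measurement-end diameters are missing")
    area = _ellipse_area_m2(geometry.end1_d1, geometry.end1_d2)
    if geometry.organ == "branch" and geometry.has_pith:
        pith = _ellipse_area_m2(geometry.pith_d1, geometry.pith_d2)
        if pith >= area:
            raise ValueError("pith area exceeds xylem area")
        area -= pith
    return area


def select_kmax(
    records: Sequence[FlowRecord],
    length: float,
    stability_tol: float = 0.02,
) -> float:
    """K_h at the flushing plateau (k_max), kg m MPa^-1 s^-1.

    Flush-stage conductivities are scanned in stage order; the first flush
    whose relative increase over the previous flush is below
    ``stability_tol`` is taken as the plateau.  If no stable pair exists the
    maximum across flushes is returned with a warning.  With no flush
    records at all, the initial-stage value is returned (warned) — the
    native state is then the best available estimate.
    """
    flushes = sorted(
        (r for r in records if r.flush_index is not None),
        key=lambda r: r.flush_index,
    )
    if not flushes:
        initial = [r for r in records if r.stage == "initial"]
        if not initial:
            raise ValueError("no flow records supplied")
        log.warning(
            "sample %s: no flush records; falling back to initial-state K_h",
            records[0].sample_id,
        )
        r = initial[0]
        return axial_conductivity(r.mass_flow, r.pressure_head, length)

    kh = [axial_conductivity(r.mass_flow, r.pressure_head, length) for r in flushes]
    for prev, cur in zip(kh, kh[1:]):
        if prev > 0 and (cur - prev) / prev < stability_tol:
            return cur
    if len(kh) == 1:
        return kh[0]
    log.warning(
        "sample %s: conductivity never stabilised across %d flushes; using max",
        flushes[0].sample_id,
        len(kh),
    )
    return max(kh)


def specific_conductivity(K_h: float, A_xylem: float) -> float:
    """KS_hydr = K_h / A_xylem (kg m^-1 MPa^-1 s^-1)."""
    if A_xylem <= 0:
        raise ValueError("xylem area must be positive")
    if K_h < 0:
        raise ValueError("K_h cannot be negative")
    return K_h / A_xylem


def leaf_specific_conductivity(
    K_h_max: float, leaf_area: float, reporting_scale: float = 1.0
) -> float:
    """K_L = K_h(max) / A_leaf (kg m^-1 MPa^-1 s^-1, one-sided leaf area).

    ``reporting_scale`` multiplies the SI value for display conventions that
    report K_L on a scaled axis; it defaults to 1 (pure SI).
    """
    if leaf_area <= 0:
        raise ValueError("leaf area must be positive")
    if K_h_max < 0:
        raise ValueError("K_h cannot be negative")
    return K_h_max / leaf_area * reporting_scale


def huber_value(A_xylem: float, leaf_area: float) -> float:
    """Huber value HV = A_xylem / A_leaf (m² m^-², wood-to-leaf direction)."""
    if leaf_area <= 0:
        raise ValueError("leaf area must be positive")
    if A_xylem < 0:
        raise ValueError("xylem area cannot be negative")
    return A_xylem / leaf_area


def hydraulic_traits(
    records: Iterable[FlowRecord],
    geometry: SegmentGeometry,
    leaf_area: Optional[float] = None,
    stability_tol: float = 0.02,
    kl_reporting_scale: float = 1.0,
) -> HydraulicTraits:
    """Full per-sample processing: k_max selection, KS_hydr, K_L, HV."""
    records = list(records)
    area = xylem_area(geometry)
    kmax = select_kmax(records, geometry.length, stability_tol)
    initial = [r for r in records if r.stage == "initial"]
    kh_init = (
        axial_conductivity(initial[0].mass_flow, initial[0].pressure_head, geometry.length)
        if initial
        else None
    )
    kl = hv = None
    if geometry.organ == "branch" and leaf_area is not None:
        kl = leaf_specific_conductivity(kmax, leaf_area, kl_reporting_scale)
        hv = huber_value(area, leaf_area)
    return HydraulicTraits(
        sample_id=geometry.sample_id,
        organ=geometry.organ,
        K_h=kmax,
        K_h_initial=kh_init,
        A_xylem=area,
        KS_hydr=specific_conductivity(kmax, area),
        K_L=kl,
        HV=hv,
    )
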