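"""Wood density (dry mass per fresh volume, g cm^-3).

Segment volume is the mean elliptical woody area of the two debarked ends
times the length, with the pith volume subtracted for branches.  Stem-core
volume is a cylinder at the corer's inner diameter (5 mm).  Inputs are
debarked dimensions — the bark-off convention is an upstream contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .flow import SegmentGeometry

__all__ = ["DensityResult", "segment_volume", "core_volume", "wood_density", "density_result"]

log = logging.getLogger(__name__)

#: cm³ per mm³
_MM3_TO_CM3 = 1e-3

#: plausibility band for woody tissue, g cm^-3 (warning outside)
WD_SANITY = (0.2, 1.2)


@dataclass(frozen=True)
class DensityResult:
    sample_id: str
    organ: str
    fresh_volume: float  # cm³
    dry_mass: float  # g
    WD: float  # g cm^-3


def segment_volume(geometry: SegmentGeometry) -> float:
    """Fresh xylem volume of a root/branch segment, cm³.

    Mean of the two elliptical end areas × length; branches with recorded
    pith diameters get the mean pith ellipse × length subtracted.
    """
    g = geometry
    for name in ("end1_d1", "end1_d2", "end2_d1", "end2_d2"):
        if getattr(g, name) is None:
            raise ValueError(f"segment_volume needs both ends measured ({name} missing)")
    a1 = math.pi * g.end1_d1 * g.end1_d2 / 4.0  # mm²
    a2 = math.pi * g.end2_d1 * g.end2_d2 / 4.0
    length_mm = g.length / 1e-3
    vol_mm3 = 0.5 * (a1 + a2) * length_mm
    if g.organ == "branch" and g.has_pith:
        vol_mm3 -= math.pi * g.pith_d1 * g.pith_d2 / 4.0 * length_mm
    return vol_mm3 * _MM3_TO_CM3


def core_volume(core_length: float, corer_diameter: float = 5.0) -> float:
    """Stem-core fresh volume, cm³, from core length (mm) and corer bore (mm)."""
    if core_length <= 0:
        raise ValueError("core length must be positive")
    if corer_diameter <= 0:
        raise ValueError("corer diameter must be positive")
    return math.pi * (corer_diameter / 2.0) ** 2 * core_length * _MM3_TO_CM3


def wood_density(dry_mass: float, volume: float) -> float:
    """WD = dry mass (g) per fresh volume (cm³)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    if dry_mass < 0:
        raise ValueError("dry mass cannot be negative")
    return dry_mass / volume


def density_result(geometry: SegmentGeometry) -> DensityResult:
    """WD of one segment or stem core, with a sanity-band warning."""
    if geometry.dry_mass is None:
        raise ValueError("dry mass missing")
    if geometry.organ == "stem_core":
        if geometry.core_length_mm is None:
            raise ValueError("stem core needs core_length_mm")
        vol = core_volume(geometry.core_length_mm)
    else:
        vol = segment_volume(geometry)
    wd = wood_density(geometry.dry_mass, vol)
    if not (WD_SANITY[0] < wd < WD_SANITY[1]):
        log.warning("sample %s: WD=%.3f g cm^-3 outside plausibility band %s",
                    geometry.sample_id, wd, WD_SANITY)
    return DensityResult(geometry.sample_id, geometry.organ, vol, geometry.dry_mass, wd)
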