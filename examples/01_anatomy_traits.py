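"""Derive anatomical hydraulic traits from one measured sector.

Builds a small conduit table for a radial wedge of a coarse-root cross
section and prints the five sector-level traits.  The hydraulically
weighted diameter D_h sits above the arithmetic mean because wide conduits
dominate Poiseuille flow (ΣD⁴ weighting), and KS_pot is the conductivity
the Hagen-Poiseuille law predicts for this conduit population per unit
xylem area.
"""

import numpy as np

from xylemflow import ConduitSet, anatomy_traits

rng = np.random.default_rng(0)

# 60 conduits, lognormal diameters around 45 µm, in a 45° wedge at 15% lumen
diameters = 45.0 * np.exp(0.25 * rng.standard_normal(60))
lumen = np.pi / 4 * diameters**2
sector = ConduitSet.from_diameters(
    sample_id="demo-root",
    organ="root",
    sector_angle=45.0,
    sector_area=lumen.sum() / 0.15,
    diameters_um=diameters,
)

tr = anatomy_traits(sector)
print(f"conduits measured : {tr.n_conduits}")
print(f"CD   (n mm^-2)    : {tr.CD:8.1f}   conduit density in the wedge")
print(f"F    (%)          : {tr.F:8.1f}   lumen fraction of the wedge area")
print(f"D_mean (µm)       : {tr.D_mean:8.1f}")
print(f"D_h  (µm)         : {tr.D_h:8.1f}   flow-weighted (> D_mean)")
print(f"KS_pot            : {tr.KS_pot:8.2f}   kg m^-1 MPa^-1 s^-1 (theoretical)")
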