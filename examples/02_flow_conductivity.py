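"""Process one gravimetric conductivity measurement series.

A branch segment is measured at a 2 kPa head, then repeatedly flushed to
remove emboli until the flow plateaus (k_max).  The script prints the
plateau axial conductivity K_h, the xylem-specific KS_hydr (per xylem
area, pith excluded), the leaf-specific K_L and the Huber value
(xylem-to-leaf area ratio).
"""

from xylemflow import FlowRecord, SegmentGeometry, hydraulic_traits

geometry = SegmentGeometry(
    sample_id="branch-07",
    organ="branch",
    length=0.05,               # m (50 mm segment)
    end1_d1=4.2, end1_d2=4.0,  # crosswise basal diameters, mm (debarked)
    end2_d1=4.1, end2_d2=3.9,
    pith_d1=1.0, pith_d2=1.0,  # pith is not conducting wood
)

records = [
    FlowRecord("branch-07", "initial", 2.0, 1.4),   # native state (plugged)
    FlowRecord("branch-07", "flush_1", 2.0, 2.1),
    FlowRecord("branch-07", "flush_2", 2.0, 2.45),
    FlowRecord("branch-07", "flush_3", 2.0, 2.48),  # < 2% above flush_2: stable
]

tr = hydraulic_traits(records, geometry, leaf_area=0.012)
print(f"A_xylem (m²)      : {tr.A_xylem:.3e}")
print(f"K_h initial       : {tr.K_h_initial:.3e}  (native, plugged)")
print(f"K_h max (k_max)   : {tr.K_h:.3e}  kg m MPa^-1 s^-1")
print(f"KS_hydr           : {tr.KS_hydr:.3f}      kg m^-1 MPa^-1 s^-1")
print(f"K_L               : {tr.K_L:.3e}  per m² leaf area")
print(f"Huber value       : {tr.HV:.2e}  m² xylem per m² leaf")
print(f"native/max        : {tr.K_h_initial / tr.K_h:.2f}  (plugging diagnostic)")
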