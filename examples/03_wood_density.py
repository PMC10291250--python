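"""Wood density of a branch segment and a stem core.

Segment volume is the mean elliptical area of the two debarked ends times
the length minus the pith volume (branches); core volume is the corer
cylinder.  WD is dry mass per fresh volume.
"""

from xylemflow import SegmentGeometry, core_volume, density_result, segment_volume

branch = SegmentGeometry(
    sample_id="branch-07", organ="branch", length=0.05,
    end1_d1=4.2, end1_d2=4.0, end2_d1=4.1, end2_d2=3.9,
    pith_d1=1.0, pith_d2=1.0, dry_mass=0.41,
)
core = SegmentGeometry(
    sample_id="core-03", organ="stem_core", length=0.045,
    dry_mass=0.52, core_length_mm=45.0,
)

print(f"branch fresh volume : {segment_volume(branch):.3f} cm³ (pith-corrected)")
print(f"branch WD           : {density_result(branch).WD:.3f} g cm^-3")
print(f"core volume (5 mm corer): {core_volume(45.0):.3f} cm³")
print(f"stem WD             : {density_result(core).WD:.3f} g cm^-3")
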