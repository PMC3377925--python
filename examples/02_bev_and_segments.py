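"""Project the horseshoe case into the beam's-eye view and build the three
segment orders for one gantry angle.

S0 is the PTV-conformal hull (it would irradiate the OAR through the
concavity), S1 keeps the PTV but blocks the margin-expanded OAR shadow on
the chosen side, and S2 is the narrow strip right beside the OAR edge that
re-saturates the PTV rim S1 leaves cold.
"""

import twostep_imrt as ts

case = ts.make_phantom("quasimodo", grid_shape=(128, 128, 8), voxel_size=2.5)
mlc = ts.mlc_preset("s4")
params = ts.SegmentationParams()
beam = ts.Beam(90.0)  # lateral view

ptv_bev = ts.project_structure(case, "ptv", beam, mlc, resolution=1.0)
oar_bev = ts.project_structure(case, "oar_primary", beam, mlc, resolution=1.0)
print(f"gantry {beam.gantry_angle_deg:.0f} deg: PTV shadow {ptv_bev.area_mm2/100:.1f} cm^2, "
      f"OAR shadow {oar_bev.area_mm2/100:.1f} cm^2")

for order in ("S0", "S1", "S2"):
    ap = ts.make_aperture(order, ptv_bev, oar_bev, params, mlc)
    rows = int(ap.open_.sum())
    print(f"  {order}: {'valid' if ap.valid else 'invalid':7s} "
          f"open rows {rows:2d}  area {ap.area_cm2:5.1f} cm^2")
    if ap.valid:
        r = int(ap.open_.argmax())
        print(f"      first open row: leaves at [{ap.x_left[r]:+.1f}, {ap.x_right[r]:+.1f}] mm")
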