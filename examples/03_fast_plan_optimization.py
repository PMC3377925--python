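"""Build a single-segment-per-beam ("fast") plan and fine-tune it.

Thirty beams alternate S1/S2 orders around the full circle; the optimizer
varies only segment weights and leaf positions (2 runs x 40 steps, <2 MU
segments discarded at run boundaries).  The report lists each DVH objective
C_j against the plan value M_j; the COV is the weighted quadratic penalty
sum the optimizer minimized, S_D/n the mean dose shortfall/excess over the
violated objectives.  A small grid keeps this demo around a minute.
"""

import twostep_imrt as ts

case = ts.make_phantom(
    "quasimodo",
    dict(body_semiaxes=(80, 60), oar_radius=12, gap_mm=5, ptv_thickness=14),
    grid_shape=(96, 96, 4),
    voxel_size=2.0,
)
objectives = ts.make_objective_template(case, "quasimodo")
mlc = ts.MLCModel(leaf_width=4.0, n_leaf_pairs=12, max_field_extent=80.0)
params = ts.SegmentationParams(min_open_area_cm2=0.3)

plan = ts.build_fast_plan(case, 30, params=params, mlc=mlc, name="fast-30")
print(f"built {plan.name}: {plan.n_beams} beams, {plan.n_segments} segments "
      f"(one per beam), orders {[s.order.value for s in plan.segments[:6]]}...")

result = ts.optimize_plan(plan, case, objectives, ts.OptimizerConfig(aperture_passes=3))
dose = ts.plan_dose(result.plan, result.influence)
report = ts.build_quality_report(dose, objectives, case)
print(f"COV {result.cov_trace[0]:.0f} -> {result.cov_trace[-1]:.0f} "
      f"after {len(result.cov_trace)} accepted steps; "
      f"total {result.plan.total_mu:.0f} MU_eff; S_D/n {report.s_d_per_n:.2f}")
print(report.objective_table[["structure", "kind", "dvh_point", "C", "M", "violated"]]
      .round(1).to_string(index=False))
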