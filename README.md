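# twostep-imrt

Fast step-and-shoot IMRT planning by geometric segmentation, for medical
physicists and algorithm researchers who want a self-contained, scriptable
testbed for the "2-Step" family of techniques on synthetic phantoms.

## The problem and the method

Step-and-shoot IMRT delivers a plan as `N` static MLC apertures (segments)
spread over `n` gantry angles. Conventional planning puts many segments on
few beams; every extra segment costs shaping time while the gantry stands
still. The idea implemented here is the opposite trade: **one segment per
beam, but many beams**, with segment shapes derived directly from the
beam's-eye-view (BEV) topology of the target (PTV) and the dominant organ
at risk (OAR):

- **S0** — PTV-conformal aperture (per-leaf-row hull of the PTV shadow);
- **S1** — covers the PTV but blocks the margin-expanded OAR shadow,
  opening only on the chosen side;
- **S2** — a narrow strip hugging the OAR shadow edge, re-saturating the
  PTV rim that S1 leaves underdosed (a discretized "Brahme peak").

"Fast" plans assign the orders cyclically over equidistant angles
(`{S1 S2}^m`, or `{S0 S1 S2}^m` / `{S0 S2 S1 S2 S1 S2}^m'` when conformal
segments are allowed); beams with no valid segment are discarded. Segment
weights and leaf positions are then fine-tuned against weighted quadratic
DVH objectives (the composite objective value, COV): two runs of 40
accepted steps, segments under 2 MU discarded at run boundaries.

Delivery time is modelled as

    T = (n-1)·max{τ_GSS, τ̄_S} + (N-n+1)·τ̄_S + MU/Ḋ + (n-1)·τ_F

with the gantry transition time τ_GSS = τ_SS + Δθ·(rotation time)/360°.
The `max` term is the crux: segment shaping and gantry motion run
concurrently, so single-segment-per-beam plans hide their leaf travel
inside the gantry moves. Machine presets: "new" (60 s/360°, τ_SS 3 s,
τ̄_S 7 s, τ_F 3 s) and "old" (78 s, 3 s, 12 s, 9 s); dose rates 500/350
MU_eff/min are back-solved defaults and flagged in every report.

Plan quality is reported as COV normalized to a reference plan (only
+25%/−20% differences count as relevant) and as the score
`S_D = Σ_j |M_j − C_j|` over *violated* objectives only (zero for a fully
compliant plan), plus cumulative DVH curves.

Everything runs on synthetic voxel phantoms built in-repo: a horseshoe PTV
around a central cylindrical OAR, a nested-boost (SIB) case with an
indenting OAR, and a tangent breast-like crescent beside a lung-sized OAR.

## Worked example

Segment construction for a lateral beam on the horseshoe phantom
(`python examples/02_bev_and_segments.py`):

```
gantry 90 deg: PTV shadow 20.9 cm^2, OAR shadow 12.2 cm^2
  S0: valid   open rows  6  area  20.9 cm^2
      first open row: leaves at [-50.5, +36.5] mm
  S1: valid   open rows  6  area   5.3 cm^2
      first open row: leaves at [-50.5, -28.5] mm
  S2: valid   open rows  6  area   1.3 cm^2
      first open row: leaves at [-34.0, -28.5] mm
```

S0 spans the whole PTV shadow; S1 stops 3 mm (the block margin) short of
the OAR shadow; S2 is the 5.5 mm strip right beside that edge.

Delivery times for published example plan summaries
(`python examples/04_delivery_time.py`):

```
                          n   N   MU  T_new_min  dT_new_pct  T_old_min  dT_old_pct
reference-9 (prostate)    9  50  591        7.8        -3.7       12.9        -4.4
fast*-23 (prostate)      23  23  468        4.7       -42.0        9.2       -31.9
reference-9 (horseshoe)   9  54  525        8.1         0.0       13.5         0.0
fast-30 (horseshoe)      30  30  802        6.6       -18.5       12.6        -6.7
fast*-30 (horseshoe)     30  30  504        6.0       -25.9       11.8       -12.6
```

On the new machine the 30-beam single-segment plans are 19–26% faster than
the 9-beam reference; on the old machine the 9 s per-beam data handling
eats most of the gain — exactly the regime distinction the time model is
built to expose.

Other example scripts: `01_phantoms.py` (geometry and volumes),
`03_fast_plan_optimization.py` (building and fine-tuning a fast plan with
the full objective report), `05_experiment_runner.py` (config-driven
end-to-end study). A thin CLI covers the shell-worthy entry points:
`twostep-imrt make-phantom`, `twostep-imrt time-plan`,
`twostep-imrt run-experiment`.

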