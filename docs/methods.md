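# Methods

This note documents the models, defaults and numerical choices of
`twostep_imrt`, and what its synthetic experiments do and do not show.

## Geometry and conventions

Patient coordinates are millimetres with the isocenter at the origin: `x`
lateral, `y` anterior, `z` longitudinal. Gantry angles follow IEC 61217
(0° = beam from anterior, clockwise viewed from the feet); all beams are
coplanar with SAD 1000 mm. MLC leaf pairs stack along `z` and travel in
the axial plane, so the aperture logic is one open interval per leaf row
along the BEV travel axis `u`. The angle convention is a package choice —
no results depend on a global rotation of the beam set, and the projection
tests assert rotational consistency rather than a particular zero.

BEV projection is divergent: a raster cell on the isocenter plane is
occupied iff the source→cell ray intersects the structure mask, sampled at
half the smallest voxel. The raster is 1 mm along `u` (configurable; must
divide the leaf width) and one row per leaf pair along `v`.

## Phantoms

Phantoms are 3D voxel grids with deliberately small longitudinal extent
(default 256×256×16 at 2 mm): the planning problems are effectively 2.5D,
which keeps coplanar planning meaningful and runtimes desk-scale. Masks
are voxel-centre rasterizations of analytic shapes with no partial-volume
weighting, so they can be tested against closed-form volumes, distances
and shadows. Construction rejects inadmissible parameters (OAR not inside
the PTV concavity; PTV–OAR gap under two in-plane voxels).

The published horseshoe phantom's exact dimensions are not in scope; the
preset uses documented approximations (body ellipse 300×200 mm, OAR radius
25 mm, 20 mm PTV annulus at a 5 mm gap, 90° posterior opening). The SIB
and tangent presets are likewise stand-ins that reproduce the topology
(nested PTVs with an indenting OAR; a surface crescent beside a large
lateral OAR), not any patient's anatomy.

Objective templates reproduce the per-case *pattern and count* of the
study design — 14 (horseshoe), 21 (SIB prostate-like), 28 (SIB
spine-like), 25 (tangent) terms; every PTV gets D_100 > 95 / D_98 > 97
lower and D_02 < 102 / D_00 < 104 upper objectives plus a D_50 window on
an eroded central plateau; OARs get up to three upper objectives; weights
lie in [0.1, 100]. The numeric OAR levels are package defaults (the
originals are not published) and are configurable. Helper structures
(plateau, envelopes, healthy tissue, GTV) are derived by Euclidean
morphology on demand.

## Segmentation

Per leaf row, with `O` the margin-expanded hull of the OAR shadow
(default margin 3 mm, a penumbra allowance):

- S0 opens `[min, max]` of the PTV shadow in the row (concavities are
  bridged — that is the point of S0);
- S1 opens the chosen-side PTV portion strictly outside `O`; rows without
  OAR shadow fall back to the S0 row; rows whose chosen side holds no PTV
  close. S1/S2 never overlap `O` — blocking has priority;
- S2 opens a strip of width `w2` immediately beside the `O` edge,
  clipped to the S0 row interval; rows without OAR shadow stay closed.

`w2` defaults to a geometric rule — a quarter of the chosen-side PTV
extent beyond the OAR edge in the central row, clamped to [5, 30] mm —
reflecting that the strip should scale with the unsaturated rim but stay
narrow; a fixed width can be set instead. "Left-sided" means the same
bank (smaller `u`) relative to the dominant OAR shadow at every angle,
which minimizes inter-beam leaf travel; the side is configurable and
mirroring the phantom mirrors every aperture exactly.

A segment is valid if its aperture is structurally possible and its open
area reaches `min_open_area_cm2`. The default threshold is **0.5 cm²**:
the threshold exists to reject degenerate slivers, and its scale must
match the phantoms' ~2–3 cm longitudinal extent — an order of magnitude
below a clinical field height. A clinically-scaled absolute threshold
(a few cm²) would discard every S2 strip on these slab phantoms and with
them the defining behaviour of the method (all 30 horseshoe beams retained
with one segment each), so the smaller default is the consistent choice;
it remains a parameter.

## Dose engine

A calibrated primary-fluence pencil model:

    dose = OF · F(u, v) · exp(−μ·(d_rad − 100 mm)) · (SAD/dist)²  per MU_eff

with μ = 0.005/mm (≈6 MV water), Gaussian penumbra σ = 3 mm applied to the
aperture raster, radiological depth = geometric depth inside the
unit-density body (ray-marched at 2 mm with a half-step end correction;
0.5 mm in calibration-accuracy tests), and OF fixed by the MU_eff
contract: 100 MU_eff deposit 1 Gy on the axis of a 100×100 mm field at
100 mm depth, SAD 1000 mm. There are no scatter kernels, transmission or
heterogeneity: the claims under test (segment geometry, timing, score
arithmetic, relative plan comparison) need an engine that is linear in the
weights, monotone in the aperture and physically plausible in depth — not
clinical-grade absolute dose. Absolute agreement with a commercial engine
is explicitly out of reach and never asserted.

Influence is stored as one float32 unit-dose row per segment over body
voxels; per-beam geometry (BEV coordinates, attenuation) is cached per
gantry angle so aperture trials only re-evaluate fluence.

## Optimization

The optimizer is an in-house analog of a direct-machine-parameter engine's
final stage: it varies segment weights and apertures only.

*Weights.* Projected gradient (weights kept ≥ 0) with a backtracking line
search that accepts only COV-decreasing steps, so the accepted COV trace
is non-increasing by construction. The objective is scored on the DVH
statistic itself; its exact gradient lives on a single percentile voxel,
which is correct (verified against finite differences) but a poor search
direction. The search direction therefore comes from a per-voxel surrogate
of each violated term (every structure voxel on the violating side
contributes), with fallback to the exact gradient; acceptance is always on
the true COV. A per-voxel objective variant is available as a term flag.

*Apertures.* Greedy coordinate descent over leaf positions: fixed sweep
order (segments in plan order, rows top to bottom, left bank before
right), moves of up to `aperture_move_limit` steps of `leaf_step_mm`
(default 1 × 3 mm), plus trial-opening of closed rows adjacent to open
ones (inheriting the neighbour's interval) so the optimizer can compensate
penumbra beyond the shadow edge along the stacking axis. Only
COV-decreasing moves are accepted; deliverability and travel limits are
preserved. The sweep is deterministic; the default pipeline has no
stochastic component (the seed only governs optional stochastic variants).

*Protocol.* Two runs of 40 weight steps; within each run,
`aperture_passes` (default 6) leaf sweeps are interleaved between equal
blocks of weight steps; at every run boundary segments under 2 MU are
discarded (all discards logged). Initial weights are uniform, scaled so
the mean PTV dose equals the prescription. Fine interleaving matters:
plans built from S1/S2 orders only need substantial shape corrections near
the OAR margin, and batching all sweeps between the two runs converges
visibly worse than interleaving.

## Scores and timing

COV is the weighted quadratic penalty sum (dimensionless, doses in % of
prescription; for OAR terms the primary PTV prescription is the
reference). `S_D` sums `|M_j − C_j|` in percent points over violated
objectives only — it is weight-independent and zero iff the plan is
compliant; the percent convention is adopted and documented since the
original score's units are not stated. Normalized COV divides by a
designated reference plan; the ±(25/20)% relevance band is reported with
every ratio.

The time model treats the printed full-rotation gantry time as a rate:
τ_GSS(Δθ) = τ_SS + Δθ·(rotation time)/360. Only this per-transition
reading reproduces the eight published new-linac example times to 0.1 min,
which the acceptance script recomputes. Dose rates are not part of the
published parameter set; 500 (new) and 350 (old) MU_eff/min are
back-solved defaults, exposed as fields and flagged in every report. The
old-linac example times are not exactly reproducible under any single dose
rate across cases and are therefore reported but never asserted. Reported
times and percent reductions are rounded to 0.1 min for table consistency;
raw seconds are kept internally.

## Problem sizes

The comparative experiment runs the horseshoe case at 128×128×8 voxels of
2.5 mm (≈60k body voxels), 4 mm leaves, 1 mm BEV raster — small enough to
optimize a 45-segment reference and a 30-segment fast plan in a few
minutes on one core, large enough that the PTV rim, the 5 mm gap and the
penumbra interact as intended. Unit tests use a further down-scaled
horseshoe (96×96×4 at 2 mm) whose validity threshold is scaled
accordingly.

## What passing tests show — and what they do not

The synthetic experiments validate the *machinery*: aperture construction
against brute-force raster oracles, score arithmetic against hand
evaluation, the time model against published example plans, and the
comparative claim — one segment per beam over 30 angles matches a 9-beam
multi-segment reference within the relevance band *under this engine and
these phantoms*. They do not show clinical equivalence: real anatomies are
not z-uniform, real dose has scatter and heterogeneity, and the commercial
optimizer differs from this one. Known limitations: no interdigitation or
tongue-and-groove constraints, no MLC transmission, no fluence-map
optimization path (deliberately — avoiding it is the method's point), and
greedy aperture descent can stop in local optima (mitigated, not removed,
by interleaving).
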