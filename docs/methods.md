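# Methods

## Problem and model

Given a CT volume and a pair of roughly orthogonal radiographs (frontal and
lateral), the task is to find the rigid 6-DOF pose — translations
`(tx, ty, tz)` in mm and rotations `(θx, θy, θz)` in degrees about the fixed
world axes — that makes simulated projections of the CT match the
radiographs.  The pose acts as extrinsic `Rz·Ry·Rx` about the volume centre
followed by the translation.  This convention is fixed, not configurable:
a single silently mismatched convention between rendering, error reporting
and serialisation is the classic failure mode of registration code, so the
package offers exactly one.

The two views are tied together by a *view-change* transform applied on the
left of the frontal volume transform (`lateral = view_change @ frontal`).
The default is a +90° rotation about the world Y axis (the patient
longitudinal axis).  Equivalently — and this is how the renderer implements
it — the lateral camera is the frontal source/detector pair moved by the
*inverse* view change, which places the lateral source on the +X axis at the
frontal source's radius.  A unit test asserts the two formulations render
identical images.

## DRR rendering

For every detector pixel a ray is cast from the point source through the
pixel centre.  Source and pixel positions are mapped into the volume frame
with the inverse pose transform, the ray is clipped against the volume's
bounding box (slab test), and samples are taken at the midpoints of
consecutive `step`-length intervals.  The pixel value is
`step * Σ trilinear(volume, sample)` — a midpoint Riemann approximation of
the line integral.  Points outside the grid contribute 0 (air).  CT values
are used as-is; no HU-to-attenuation conversion or log transform is applied
(an affine pre-window can be emulated by preprocessing the volume).
Grayscale conversion is per-image linear min–max onto [0, 255]; this
interacts with edge detection (contrast is renormalised every pose), which
the contour-based similarity tolerates by construction.

Defaults: source-to-isocenter 1000 mm, isocenter-to-detector 200 mm
(magnification 1.2), 256×256 detector at 1 mm pixels, step = half the
smallest voxel spacing.  None of these are physically canonical; they are
chosen so a ~100 mm anatomy fills roughly half the field of view.

Numerics: the ray-marching kernel exists twice — a vectorised numpy path
and a numba-jitted fused loop with identical sampling rules; tests assert
agreement to 1e-9.  The batch API renders a list of poses in input order
and is contractually equal to mapping the single-pose renderer; concurrency
is an implementation detail it deliberately does not expose.

## Contour-point similarity

Both the rendered DRR and the reference radiograph are reduced to Canny
edge maps (Gaussian σ = 1.0; hysteresis thresholds at the 70th/90th
percentiles of the gradient magnitude, configurable).  Each DRR contour
point is scored by the Euclidean distance to the nearest radiograph contour
point: 1 at distance 0, `w1 = 0.8` within `a = 1 px`, `w2 = 0.5` within
`b = 3 px`, 0 beyond; the similarity is the mean score.  The band radii and
weights are design defaults — one-pixel jitter is mildly penalised and the
score saturates to zero outside a 7×7 window — and are configurable.  The
nearest-match rule means one radiograph point may serve several DRR points;
no one-to-one assignment is enforced.  Ties in the nearest-neighbour search
resolve to the earlier point in row-major order (they cannot change the
score, only the matched partner).

The measure is asymmetric.  The rendered DRR supplies the scored
(reference) set and the radiograph the searched (floating) set, so the
radiograph's KD-searchable contour set is extracted once per run while the
DRR contours are recomputed per candidate pose.  A pose that pushes the
volume out of a view yields an empty DRR contour set and scores 0 in that
view; an empty *radiograph* contour set aborts the run before optimization,
because it indicates a broken input rather than a bad candidate.

Dual-view combination: `Sim = wf·Sim_f + wl·Sim_l`, `wf = 0.6 > wl = 0.4`,
`wf + wl = 1`.  The frontal view is weighted more heavily; the lateral view
is the auxiliary that constrains depth.  Single-view mode scores the
frontal similarity alone.

## Phased differential evolution

Minimisation with DE/rand/2 (`V = X_r1 + F(X_r2−X_r3) + F(X_r4−X_r5)`,
five mutually distinct donors distinct from the target), binomial crossover
(mutant coordinate where `rand_j < CR` or `j = j_rand`), and greedy
selection (trial replaces the target only if strictly better; ties keep
the incumbent).  Control parameters switch stages at generation
`ceil(Gmax/2)`: `F: 0.5 → 0.8` and `CR: 0.9 → 0.3` (the schedule is
validated to straddle 0.5).  A per-dimension multiplier on `F` defaults to
0.8 on the depth translation `tz` and 1 elsewhere: depth moves the
projection weakly, so a smaller mutation scale there wastes fewer trials.

Mutants are clipped to the search box before crossover.  Trial vectors for
a generation are all built from the generation-start population and then
evaluated together (synchronous DE) so the renderer can batch a whole
generation.  The run costs exactly `NP·(Gmax+1)` objective evaluations.
The random-draw order (init block; per individual: five rejection-sampled
donor indices, `j_rand`, D crossover uniforms) is frozen and documented in
the module docstring; a straight-line replay oracle in the tests reproduces
whole runs bit-for-bit from the seed.

Registration defaults `NP = 10`, `Gmax = 50` (510 renders per view per
run); the benchmark protocol uses population 30 for 1000 generations.

## Benchmark functions

Six standard test functions with their usual boxes and optima: Schwefel
2.22, 1.2 and 2.21 (unimodal, D = 30), Generalized Penalized 1 and 2
(multimodal, D = 30, with the `u(x, a, k, m)` boundary penalty at
`(10, 100, 4)` and `(5, 100, 4)` respectively, per the standard
definitions), and the Kowalik 4-parameter rational least-squares fit over
`[-5, 5]^4` with its canonical 11-point data table (optimum ≈ 3.075e-4).
The frozen Kowalik minimizer used in tests was refined numerically from the
literature starting point; the evaluated optimum agrees with the printed
value to 1.4e-8.

## Synthetic phantom and study conditions

The default phantom is a 96³ volume at 1 mm: soft-tissue background 100,
four bone cylinders (intensity 300, radius 12 mm, length 14 mm) stacked
along Y, and a thin posterior ridge box.  The ridge breaks rotational
symmetry about the long axis; without it `θy` would be unobservable in
projections and recovery would be ill-posed, not merely hard.  Volume noise
is Gaussian (sd 5); reference radiographs get additive Gaussian pixel noise
(sd 2 on the 8-bit scale) clamped to [0, 255].  All randomness is seeded;
the global seed is split into independent per-purpose streams
(optimizer / phantom / image noise / trial perturbations) via
`numpy.random.SeedSequence`.

The pose-recovery study runs at a deliberate desk scale: 128×128 detector
at 1.5 mm pixels, 1 mm ray step, 10 trials.  At magnification 1.2 one
detector pixel is ~1.25 mm at the isocenter, so the 3 mm success band is
~2.4 px and the outer similarity band (3 px) corresponds to ~3.75 mm of
capture range per view.  Ground-truth poses are drawn uniformly within
±2 mm/° of zero and initial poses offset the truth by a uniform ±4 mm/° per
axis — emulating a manual initial registration that is close but, with
probability ≈ 0.82, violates the 3°/3 mm criterion on at least one axis at
the start.  The ±10 mm/° search half-widths (the spec of the search box,
centred on the initial pose) always contain the truth.

What the phantom does *not* emulate: real radiographic physics
(polyenergetic spectra, scatter, detector blur), soft-tissue contour
clutter, anatomy that deforms between CT and radiograph, and truly
multimodal intensity relationships.  Passing the recovery study shows the
geometry/similarity/optimizer loop is self-consistent and that the dual
view constrains depth; it does not certify clinical accuracy.

## Degenerate inputs and tie-breaks

Constant images yield empty contour sets (N = 0): an error for reference
radiographs, a 0 score for candidate DRRs.  All-zero volumes render warnings
plus zero images.  Angles are stored wrapped to (−180°, 180°]; error
reporting uses the shorter arc, so per-axis rotation errors lie in
[0°, 180°].  Rigid-transform validation accepts matrices within 1e-6 of
orthonormality (text round trips), while freshly constructed transforms are
tested orthonormal to 1e-9.  Selection ties keep the incumbent; crossover
with CR = 0 still copies exactly one mutant coordinate (`j_rand`).

## Known limitations

- The contour similarity has a small capture range (set by `b_band` in
  pixels); starts far outside it rely on the optimizer's global moves, and
  a multi-resolution scheme would be the natural extension.
- Min–max grayscale per pose couples contrast to pose; a fixed window mode
  would decouple them but needs intensity calibration.
- The rotation about the anatomy's long axis is weakly observable even with
  the symmetry-breaking ridge; it dominates the residual error in recovery
  runs.
- Single-CPU rendering at clinical resolutions (512² detector, sub-mm
  steps) is minutes per run; the batch API is the hook for parallel or GPU
  backends.
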