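# Methods

This note records the model behind `pgslit`, the parameter choices and their
rationale, the numerical decisions, and the known limits of the synthetic
generator. Units are mm, MeV and counts/proton unless stated otherwise.

## 1. Coordinates and geometry

- `z`: object coordinate along the beam axis, origin at the target entrance
  face, increasing downstream.
- `u`: detector coordinate along the beam axis, origin at the camera centre.
  The camera centre (and the KES slit axis) sits at object coordinate
  `fov_center`, so a detector point `u` is at lab position `z = fov_center + u`.
- `y`: perpendicular distance from the beam axis toward the camera.

**KES.** A single aperture between two mirrored tungsten prisms: slit width
6 mm at the centre plane, full opening angle `2·arccot(2) = 53.13°`, wall
thickness 40 mm, slit centre plane at `d1 = 220` from the axis, crystal
centres `d2 = 176` behind it. Projection through the slit centre gives
magnification `d2/d1 = 0.8` with an inverted image and a field of view of
`80 mm · d1/d2 = 100 mm`. The walls are treated as laterally unbounded.

**MPS.** Twenty 2.4 mm gaps separated by 1.6 mm tungsten septa (pitch 4 mm,
matching the camera slabs; septa sit on slab boundaries), 100 mm deep,
mid-depth at `d1 = 250`, crystals directly behind the exit face. Fill factor
40%, equivalent tungsten thickness 40 mm — the same tungsten budget as the
KES walls. Magnification 1, field of view 80 mm. Outside the aperture region
the collimator is modelled as solid tungsten of the full depth (laterally
unbounded), mirroring the KES treatment; a ray far outside every aperture at
normal incidence crosses the full 100 mm. An earlier development version
terminated the stack at the camera edge, which let out-of-field emission
reach the crystals around the collimator with zero attenuation and produced a
large artificial leakage ramp; the solid-flank convention removes it.

**Camera.** 20 LYSO slabs, 4 mm pitch, 100 mm tall, 31.5 mm deep, intrinsic
efficiency 0.6 per 3–6 MeV photon; one row ("half camera") or two
("full camera", doubling efficiency).

**Path lengths.** The tungsten crossed by the straight ray from an on-axis
source to a crystal-face point is computed in closed form: for the KES, as
the lengths of the `y`-intervals on which the ray violates the linear
half-gap inequalities of the two prism halves; for the MPS, as the block
crossing minus the per-gap overlap intervals. Both are validated in the test
suite against a voxel ray-march oracle to better than 0.05 mm. An obliquity
factor converts the `y`-extent to true path length.

## 2. Range and emission model

The proton range in PMMA uses a Bragg–Kleeman water-range fit divided by the
PMMA relative stopping power:

```
R_water(E) = α E^p,  α = 2.5806e-3 cm/MeV^p, p = 1.738;  R_PMMA = R_water / 1.16
```

α and p are fitted to tabulated CSDA proton ranges in liquid water (7.718 cm
at 100 MeV, 37.94 cm at 250 MeV) and reproduce them within 1%; the PMMA
relative stopping power 1.16 is the standard value. The resulting ranges are
6.66 / 15.07 / 28.31 cm at 100 / 160 / 230 MeV. Validity window 50–250 MeV.

The prompt-gamma linear emission density along the track is a smooth plateau
with Gaussian-CDF edges:

```
s(z) = yield · Φ(z / rise_width) · (1 − Φ((z − (R − 3)) / falloff_width))
```

with the falloff centred 3 mm before the range and both edge widths 2 mm
(σ). The plateau yield is `4.0e-4 / proton / mm` of 3–6 MeV prompt gammas
escaping the target at 160 MeV, scaled as `(E/160)^−0.5`; this puts the total
detected correlated counts of the default single-row KES acquisition at
`2.7e-5` per proton, the clinically quoted order of one count per 1e5
protons. The emission spectrum is collapsed to the dominant 4.44 MeV line.
The PMMA cylinder is 75 mm in radius and 200 mm long (400 mm at 230 MeV).

## 3. Background model

The uncollimated neutron-induced background per slab, per proton and per
crystal row is

```
b(u) = b0 · (E/230)^1.7 · (250 / y_crystal)^2 · (1 + β_eff · u / 40)
```

with `b0 = 1.6e-6`, `β_eff = 0.30·(E/230)` for entrance-aligned and
`0.05·(E/230)` for Bragg-peak-aligned acquisitions. `b0` is calibrated so
that background is ≈40% of the plateau counts of the 230 MeV KES acquisition
and ≈13% at 100 MeV (inside the intended 30–50% / ~10% bands). The
inverse-square distance factor makes the background relatively larger for the
MPS, whose crystals sit closer to the axis (316 mm vs 396 mm) — with one
`b0` the two setups cannot be anchored to the same fraction simultaneously,
and the KES was chosen as the calibration setup. The slope is positive
toward downstream `u` for both collimators (neutrons are forward-peaked and
penetrate the collimator); because the KES inverts the prompt-gamma image
while the background is not inverted, the slope partially cancels the imaged
entrance edge for the KES and adds to it for the MPS.

## 4. Transport and quadrature

Expected profiles are deterministic: the emission density is integrated on a
0.5 mm depth grid; each emission element illuminates every crystal face,
sampled on a 16×4 midpoint grid (beam-axis × height), each sample weighted by
`area·cosθ / 4πr²`, attenuated by `exp(−μ·t_W)` with `μ = 0.70 /cm` at
4.44 MeV, times intrinsic efficiency and row count. Poisson noise is applied
only in `sample_profile`. The face quadrature was originally 5×5; doubling
tests showed the MPS profile then moved by up to 0.7% (the gap/septum pattern
needs fine sampling along the beam axis, not the height), so the default is
16×4, which is converged to <0.2% at equal cost. No photon scatter and no
target self-attenuation are modelled; their diffuse net effect is what the
explicit background term stands in for.

## 5. Impulse response and the MPS resolution figure

The impulse response is the projection of a 4.44 MeV point source at the
centre of the field of view; its FWHM in object coordinates (floor
subtracted, half-maximum crossings linearly interpolated) is 23.4 mm for the
KES and 9.6 mm for the MPS.

A penetration-free geometric argument for a parallel-slit collimator gives
`FWHM ≈ gap·(L + b)/L ≈ 7.2 mm` (aperture 2.4 mm + septum 1.6 mm over depth
`L = 100`, source-to-collimator gap `b`), and ~7 mm is the conventionally
quoted figure for this design. An attenuation-only transport cannot
reproduce it: at 4.44 MeV the effective septal depth is reduced to
`L_eff = L − 2/μ ≈ 71 mm`, and entire families of oblique rays pass through
first-neighbour gaps crossing no tungsten at all, widening the response to
`gap·(L_eff + b)/L_eff ≈ 9 mm` with a ~6% penetration floor. The 9.6 mm
value is stable against the source registration relative to the gap pattern
(8.9–9.5 mm across sub-pitch offsets) and against ±15% in μ. This is a
physical property of the simplified transport, not a tuning residue, and it
is reported as-is.

## 6. Precision estimator

The statistical quality of an acquisition is rated exactly as a repeated
two-acquisition range-shift measurement would be:

1. A high-statistics expected profile (1e11 protons) serves as the matching
   reference.
2. For each proton number `N ∈ {1e8, 3e8, 1e9}` and each of 3 seeds, 1000
   profiles are Poisson-drawn from the reference scaled to `N`.
3. Each sample is smoothed with a Gaussian whose FWHM (in object
   coordinates) equals the collimator impulse-response FWHM, suppressing
   spatial frequencies the collimator cannot produce.
4. The retrieved shift is the grid point in ±20 mm (0.25 mm steps)
   minimising the root-summed-squared difference between the smoothed sample
   and the reference **shifted first and smoothed after**, rescaled to `N`.
   Ties break toward smaller |shift|, then negative.
5. `σ(N)` is the standard deviation of the 1000 retrieved shifts;
   `log σ` vs `log N` is fitted by least squares (slopes land at −0.47 to
   −0.51, consistent with counting statistics) and interpolated to the
   proton number `N*` at which `2σ = 4 mm`. `N*` is averaged over the three
   seeds and its seed-to-seed relative SD reported (2–8% in the default
   matrix, soft-bounded at 10%).

**Why shift-then-smooth.** The smoothing kernel is column-normalised
(counts-conserving) and therefore distorts the outer ~3 bins; shifting an
already-smoothed reference then disagrees with the expectation of a smoothed
sample by up to 12% of peak at the edges, and on a 20-bin profile that edge
mismatch dominates the least-squares objective — a noise-free sample with a
true 3 mm shift was retrieved at 0.5 mm, and Monte Carlo σ violated the
Cramér–Rao bound of the Poisson model. Building the bank as
`smooth(shift(reference))` makes the matcher exact on noise-free injected
shifts and brings Monte Carlo σ into agreement with the bound (e.g. 2.09 mm
vs 2.06 mm for the 230 MeV Bragg-aligned MPS cell at 1e8 protons).

**Smoothing edge policy.** The kernel is truncated at ±4σ and renormalised
per *source* bin, so total counts are conserved exactly (column sums 1) and
flat profiles are preserved exactly in the interior; the trade-off is a
small value distortion in the outer bins (a flat profile is not exactly flat
there). Conservation was preferred because the estimator matches absolute
count levels.

## 7. Comparison pipeline

`run_comparison` evaluates the 12-cell matrix (3 energies × 2 collimators ×
2 alignments) with the field of view centred on the target entrance or on
the expected range. Smoothing FWHMs are computed once per collimator. Each
cell receives its own seed set derived from the master seed via
`SeedSequence(master_seed, spawn_key=(cell_index,))` (all derived seeds
< 2³¹), making the report bit-reproducible. Clinical-context utilities:
`distal_margin` (3.5% of range + 2 mm at 1.5σ, rounded; 4 mm at 100 MeV,
12 mm at 230 MeV) and `spot_feasibility` (single-spot if the spot weight
reaches `N*`, aggregation needed within a factor 10, infeasible below).

## 8. Generator realism and known limits

The default matrix gives `N*` between 0.8e7 and 1.1e8 protons, with the
expected orderings: Bragg-peak `N*` increases with energy for both
collimators, and the KES beats the MPS at the Bragg peak at every energy.
Two limits are worth stating plainly:

- **Absolute scale.** Published full-scale experiments place `N*` around
  0.3–4.5 × 1e8; this generator's best cells (100 MeV KES) land ~20% below
  the 1e7 lower edge of the intended order-of-magnitude band. The synthetic
  profiles are more informative per proton than measured ones: the
  detected-counts calibration sits near the top of its plausible band, and
  the fixed 2 mm emission-edge widths ignore beam spot size and range
  straggling (which would grow from ~1 mm at 100 MeV to ~3.5 mm at
  230 MeV). These parameters are study conditions and were not adjusted
  retroactively.
- **Entrance-alignment ordering.** In full-scale measurements the MPS
  outperforms the KES when imaging the entrance point at high energy,
  because the sloped background flattens the inverted KES image almost
  completely. The mechanism is present here with the correct sign, but with
  the default slope (`β_eff = 0.3` at 230 MeV) and background fraction
  (≤50% of plateau) it cancels only ~20% of the smeared entrance edge, so
  the KES retains its efficiency advantage at the entrance. Reproducing the
  flip would require a background slope well above the shipped default;
  the ordering is therefore config-dependent in this model.

Out of scope by design: Monte Carlo particle transport, photon scatter,
neutron transport, detector electronics, energy calibration, time-of-flight
discrimination, and absolute treatment-plan integration.
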