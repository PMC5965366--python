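# Methods

This note documents the models, numerical choices and known limitations of
`dose4d`. Everything quantitative below is recomputed by the test suite or
by `scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Coordinate conventions

Arrays are indexed `[ix, iy, iz]` with patient axes LR = x, AP = y, SI = z;
indices are 0-based, voxel centers sit at `origin + index * spacing` (mm),
grids are axis-aligned. Two grids are used throughout, mirroring the
two-resolution design of online dose reconstruction: a CT/DVF grid
(default 1 × 1 × 2 mm) carrying density, masks and deformation fields, and
a coarser dose grid (default 2 × 2 × 2 mm) on which dose-influence data are
computed. Dose is trilinearly resampled from the dose grid onto the CT/DVF
grid — materialized once as a sparse operator — before energy conversion.

## Breathing phantom

The phantom is a body ellipsoid (density 1.0 g/cm³) containing a static
lung ellipsoid (0.26), a proximal-airway tube (0.2), a spinal-cord cylinder
(1.0) and a tumor sphere (1.0) that traverses a 1 − cos respiratory cycle
in SI and AP over `n_phases` = 10 phases; phase 0 is peak exhale and is the
accumulation reference. LR motion is omitted (small in lung patients).
Mass density stands in for electron density — an equivalence declared at
phantom scale, where no CT calibration exists. The default motion
(14 mm SI / 2.6 mm AP peak-to-peak, rigid tumor, small 4.2 cm³ GTV) is a
large-motion, small-tumor case — the regime in which margin reduction
without tracking demonstrably fails.

The push field (phase → reference) is the rigid phase displacement scaled
by a C¹ smoothstep of the distance outside the tumor surface, reaching zero
over a 24 mm shell inside the lung. The shell must satisfy
`1.5 · amplitude / shell < 1` or the map `x ↦ x + v(x)` folds over;
`build_phantom` rejects configurations that violate it (this is why the
default shell is 24 mm for 14 mm motion). The pull field is the *exact*
numerical inverse of the analytic push field (fixed-point iteration to
10⁻⁵ mm), so dose-mapping behaviour is isolated from registration error —
the real platform delegates registration to a commercial deformable
registration whose accuracy was only assessed visually, and an optional
`dvf_noise_mm` perturbation is the hook for studying that sensitivity.

What the phantom does *not* emulate: realistic anatomy and CT texture,
hysteresis loops beyond a phase lag between SI and AP, baseline drift,
irregular breathing, and deformation beyond isotropic tumor-radius scaling.
Passing tests therefore demonstrate the correctness of the reconstruction
machinery under known motion, not clinical dosimetric accuracy.

## Trajectory and online phase binning

Per-phase GTV centroids are reduced to a 1:1 Lissajous ellipse
(`SI = c + a_SI cos θ`, `AP = c' + a_AP cos(θ + φ)`) by harmonic least
squares: each coordinate is regressed on the fundamental harmonic of the
ordered, uniformly phase-sampled points. This estimator is exact on
noiseless samples and unbiased under isotropic noise, unlike algebraic
conic fits, which shrink eccentric ellipses at the 0.1–0.5 mm noise level
relevant here; the reported `rms_error` is the geometric RMS
point-to-curve distance. Collinear input (zero AP motion) is flagged
degenerate with `a_AP = 0`.

The trajectory samples the ellipse at 25 Hz with a 5 s default period.
During replay the respiratory phase of each sample is computed causally:

* Extrema of the SI component are detected by a zigzag rule — a candidate
  is confirmed after the signal retreats from it by 10% of the running
  peak-to-peak *and* 0.5 s have elapsed — and refined to sub-sample
  precision by parabolic interpolation. The prominence floor guards jitter;
  the delay makes detection unambiguous at the cost of a latency that only
  defers which cycle is "last complete".
* A sample at time t is assigned `floor(frac · N + ½) mod N`, where `frac`
  is its position relative to the last confirmed exhale extremum in units
  of the last complete cycle's duration. Bins are therefore equal-duration,
  half-open, anchored at peak exhale (bin 0), and *centered* on the phase
  times p/N — each sample is paired with the nearest phase's geometry.
  (Left-edge bins would pair every sample with a geometry that lags the
  true position by half a bin, ~1 mm at 14 mm motion, which measurably
  biases tracked-dose reconstruction.)
* The respiratory period is estimated from the trailing 20 s by FFT with a
  Hann window and parabolic refinement of the dominant spectral peak; the
  raw 0.05 Hz resolution of a 20 s window is otherwise too coarse near
  0.2 Hz breathing. The refined estimate is logged with the trajectory;
  the bin arithmetic itself uses the measured duration of the last
  complete cycle, which for quasi-periodic signals is the same quantity
  with less variance.
* Samples before the first fully acquired cycle are `WARMUP`; delivery
  replay starts after warm-up and maps any residual warm-up ticks to the
  planning phase.

## Beam model and dose influence

Nine equidistant coplanar beams (gantry 0…320°). Each beam's fluence is a
grid of rectangular bixels; the collimator is held rotated so leaf *travel*
runs along SI for every beam, the standard MLC-tracking choice for lung:
the dominant SI motion is compensated continuously along leaf travel while
only the small transverse component is quantized to whole 5 mm leaves.
Rows of the bixel grid are leaf pairs (5 mm leaf width, Agility-like);
the leaf-travel bixel size is a purely computational resolution and
defaults finer than the leaf width (see "Numerical choices").

The dose-influence entry for bixel j and voxel v is

    D_jv = A · exp(−μ · d_rad(v)) · Px(v) · Py(v)

with μ = 0.005/mm (≈ 6 MV in water), A = 0.01 Gy/MU (≈ 1 cGy/MU), and
Px, Py error-function edge profiles of the bixel aperture with
σ = 6.4 mm / 1.683 ≈ 3.8 mm, so a field edge shows the ~6.4 mm 80–20
penumbra of photons in lung. Radiological depth is computed by resampling
density into a beam-aligned frame, midpoint-cumulative summation along the
beam axis (2 mm steps), and sampling back at voxel centers; in uniform
water the axial falloff matches exp(−μ·depth) to 10⁻⁹. Beams are parallel
(unit magnification), consistent with the orthographic BEV projection used
for tracking; no buildup region or scatter kernel is modelled — the study's
mechanism needs attenuation and penumbra, not absolute dosimetry. Entries
below 10⁻⁴ of the per-bixel maximum are dropped; matrices are stored as
float32 CSR per (beam, phase).

## Plans and delivery

Plans are conformal step-and-shoot: one segment per beam shaped to the
PTV's BEV silhouette, rounded out to bixel boundaries and dilated by one
bixel in both directions, then a single global MU rescale so the statically
accumulated dose satisfies D95(PTV) = 18 Gy on the planning phase (exactly,
by linearity). This replaces inverse IMRT optimization; margin × motion ×
tracking interplay — the object of study — survives the simplification,
but absolute OAR numbers are those of conformal, not optimized, plans.

Delivery is replayed at 25 Hz: segments in gantry order at 550 MU/min
(0.3667 MU/tick, last tick carries the remainder so per-beam MU is exact),
2 s beam-off gaps between segments. Tracking latency is zero and reported
positions are exact — the real platform compensates latency by prediction,
which is out of scope. TRACKED mode shifts each segment by the orthographic
BEV projection of (reported − planning) position: continuously along leaf
travel, in whole leaves across rows (vacated rows close, off-carriage
shifts clamp and flag).

## EMT accumulation

Each phase voxel is split into s³ subvoxels (default s = 4); each subvoxel
carries mass m/s³ and energy d·m/s³, is displaced by the trilinearly
interpolated push field, and deposited on the reference grid. Deposition is
*box-overlap*: the displaced subvoxel cube's volume is split exactly over
the reference voxels it overlaps. This keeps identity fields and
whole-voxel translations bit-exact (the cube lands wholly inside one
voxel) while making deposition continuous in displacement — nearest-voxel
binning instead quantizes deposition in steps of 1/s³ and fails its own
s = 4 vs s = 8 1% convergence target in rarefaction zones. Because the
transport is linear, it is materialized per phase as a sparse transfer
operator S (built only over the dilated support of the push field; the
static remainder is identity), with `deformed mass = S·m`,
`energy = S·(d∘m)`, and dose = energy / deformed mass where the deformed
mass exceeds a 10⁻⁶ g floor (guards division in air). Off-grid deposition
is tallied in an explicit lost-mass/lost-energy ledger; deposited + lost
equals the source total to 10⁻⁹ relative.

The reference phase has an identically zero field and keeps S = None; its
accumulation path is the same as STATIC mode, which makes zero-motion
CONVENTIONAL and TRACKED deliveries bit-identical to STATIC — a designed
exactness, not a numerical coincidence. A DDM comparator (trilinear pull
of the phase dose) is provided for contrast experiments only.

Real-time behaviour is replayed, not enforced: `accumulate_tick` logs wall
time per tick (mean / 5th / 95th percentiles via `runtime_summary`), and
beam-off ticks cost nothing, which is where a live system would catch up.
The batched `accumulate_delivery` exploits the linearity of dose in bixel
weights and of EMT in phase dose to apply each dose-influence matrix and
transfer operator once per delivery; it equals the tick loop to
floating-point summation order and is what the study driver uses.

## Analysis

D_x is computed from the empirical voxel-dose distribution (linear
interpolation between order statistics — the inverse of the cumulative
curve); V_x is a direct voxel count. The binned cumulative DVH (0.01 Gy
bins) is kept for export. Lung V20 is evaluated on lung minus GTV_ref with
the fraction dose scaled ×3 to the course dose; all other endpoints are
per-fraction. The comparison report shows each (plan, mode) against its
own static delivery (target-coverage view) and against the conventionally
delivered ITV+5 reference (OAR view), the latter also after rescaling GTV
D98 to the reference's — separating margin-driven OAR sparing from
prescription differences.

## Numerical choices, briefly

| quantity | default | why |
| --- | --- | --- |
| CT/DVF grid | 1 × 1 × 2 mm | clinical 4DCT-like; DVF and mass live here |
| dose grid | 2 × 2 × 2 mm (64³) | dose-influence size/speed |
| subvoxels s | 4 | s=4 vs s=8 max dose change < 1% on phantom fields |
| leaf width | 5 mm | Agility-like hardware |
| leaf-travel bixel | 2.5 mm | resolves sub-bixel tracked aperture edges; see below |
| kernel μ, σ, A | 0.005/mm, 3.8 mm, 0.01 Gy/MU | 6 MV-like attenuation, 6.4 mm 80–20 penumbra, ~1 cGy/MU |
| D cutoff | 1e-4 of bixel max | sparsity; < 0.1% dose effect |
| mass floor | 1e-6 g | air-division guard |
| extremum detector | 10% prominence, 0.5 s confirm | jitter guard; no detector is prescribed by the physics |
| period | 5 s, 25 Hz, 550 MU/min | study conditions |

A tracked aperture whose edge falls inside a bixel is represented by a
fractional weight on that bixel, i.e. a scaled — not translated — edge
profile. At 5 mm leaf-travel bixels this discretization alone shifts the
tracked GTV D98 of a 1 mm-margin plan by −0.38 Gy; at 2.5 mm the residual
is −0.08 Gy and at 1.25 mm it vanishes (+0.005 Gy), with the static and
untracked endpoints unchanged across resolutions. The default is 2.5 mm
(below the 3.8 mm penumbra σ). For the same reason the conformal aperture's
dilation is a fixed length (one 5 mm leaf width), not "one bixel" — the
computational fluence resolution must not alter the physical field margin.
The leaf-width direction keeps the physical 5 mm leaf quantization.

## Known limitations

* Analytic pencil kernel, not Monte Carlo: no lateral scatter
  disequilibrium in lung, no buildup, no leakage/tongue-and-groove.
* Conformal plans, not inverse-optimized: OAR endpoint magnitudes are not
  comparable to optimized clinical plans.
* Rigid-plus-falloff deformation with an exact inverse; no registration
  error unless injected.
* Perfect, latency-free position reporting.
* Wall-clock figures are logged for information only; the package makes no
  real-time guarantee.
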