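# dose4d

Desk-scale, fully synthetic re-implementation of a real-time 4D
dose-reconstruction platform for MLC-tracked lung SBRT.

## The problem

A peripheral lung tumor moves with respiration — up to ~14 mm
superior–inferior over a ~5 s cycle. Conventional planning covers that
motion geometrically: the internal target volume (ITV) is the union of the
gross target volume (GTV) over all phases of a respiration-correlated CT
(4DCT), expanded by a safety margin into the planning target volume (PTV).
That guarantees coverage but irradiates a large envelope of healthy lung.
Dynamic MLC *centroid tracking* instead shifts the treatment aperture in the
beam's-eye-view to follow the target, which permits a much smaller target —
the moving target volume (MTV), the union of centroid-aligned GTVs — with a
1–5 mm margin.

Whether the tracked dose actually reaches the moving target can be verified
by **online 4D dose reconstruction**: every 40 ms (25 Hz) the actually set
MLC aperture and the reported target position are converted into a dose
contribution on the current respiratory phase using precalculated
dose-influence data, and accumulated onto the peak-exhale reference phase by
**energy–mass transfer (EMT)** mapping:

* aperture → bixel weights `w_j` (fractional opening of each fluence element),
* phase dose `d(v) = MU · Σ_j w_j D_jv` with the per-(beam, phase) sparse
  dose-influence matrix `D`,
* per-voxel energy `d·m` and mass `m` pushed separately through the phase's
  deformation field, subdivided into subvoxels,
* reference dose = deposited energy / deposited ("deformed") mass —
  the physical definition of dose, robust where direct dose interpolation
  (DDM) fails at sharp local features.

This package rebuilds the whole pipeline on a synthetic breathing thorax
phantom with analytically known deformation fields: phantom construction,
trajectory synthesis (least-squares ellipse through per-phase GTV centroids,
sampled sinusoidally at 25 Hz), causal online respiratory phase binning with
Fourier period estimation, an analytic pencil-kernel dose-influence
generator (exponential attenuation at radiological depth × error-function
penumbra, 80–20 width 6.4 mm), conformal step-and-shoot plans for nine
equidistant beams normalized to D95 = 18 Gy per fraction, tracked /
untracked / static delivery replay at 550 MU/min, EMT accumulation, and
DVH endpoint analysis (GTV D98, lung V20 on the 3-fraction course dose,
spinal-cord and airway D2).

## Worked example

```python
from dose4d import RunConfig, run_study

cfg = RunConfig(mtv_margins_mm=(1.0, 3.0, 5.0),
                include_itv=False, include_midv=False)
result = run_study(cfg)
print(result.report[["plan", "mode", "gtv_d98_gy", "lung_v20_pct",
                     "d98_minus_static_gy"]].to_string(index=False))
```

which prints (default phantom: 14 mm SI / 2.6 mm AP peak-to-peak rigid
tumor motion, 64³ dose grid at 2 mm; ~4 min on one CPU):

```
 plan      mode  gtv_d98_gy  lung_v20_pct  d98_minus_static_gy
MTV+1    static       17.93         21.53                 0.00
MTV+1   tracked       17.85         18.66                -0.08
MTV+1 untracked        9.02         20.12                -8.90
MTV+3    static       18.14         26.21                 0.00
MTV+3   tracked       18.16         23.52                 0.02
MTV+3 untracked       11.28         24.89                -6.85
MTV+5    static       17.95         34.12                 0.00
MTV+5   tracked       17.97         31.32                 0.02
MTV+5 untracked       13.52         32.58                -4.43
```

Reading: the static rows are the planned doses (D95 of each PTV is
normalized to 18 Gy, so GTV D98 sits near 18). Delivering the tight
1 mm-margin plan *without* tracking while the phantom breathes loses
~9 Gy of near-minimum GTV dose — the aperture simply misses the tumor for
much of the cycle. With centroid MLC tracking the coverage is restored to
within a tenth of a Gy of the plan for every margin, while lung V20 falls
with the shrinking margin (34.1% → 21.5% static, 31.3% → 18.7% tracked).
The same run writes `report.csv`, per-mode reference-phase dose
grids (NIfTI), the 25 Hz trajectory log and a manifest when an output
directory is passed to `run_study`.

A CLI wraps the same pipeline: `dose4d all --config cfg.json --seed 1
--out out/` (sub-commands `phantom`, `precompute`, `plan`, `deliver`,
`accumulate`, `report` run the individual stages).

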