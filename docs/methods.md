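# Methods

This note documents the models, numerical choices and design decisions behind
perfquant, and what the synthetic studies do and do not demonstrate.

## Two-compartment exchange model

The tissue model is the standard 2CXM. With plasma flow `Fp` and
permeability–surface-area product `PS` in ml/min per ml tissue, and volume
fractions `vp`, `ve`:

```
vp dCp/dt = Fp (Ca − Cp) + PS (Ce − Cp)
ve dCe/dt = PS (Cp − Ce)
C(t)      = vp Cp + ve Ce = Fp (Ca(· − t0) ⊛ R)(t)
```

The residue function is biexponential, `R(t) = E₊ e^{λ₊ t} + E₋ e^{λ₋ t}`.
With per-second rates `fp = Fp/60`, `ps = PS/60` and
`α = (fp+ps)/vp`, `β = ps/ve`, `γ = ps/vp`, the eigenvalues are

```
λ± = ½ [ −(α+β) ± √((α−β)² + 4γβ) ]
```

and the amplitudes follow from `R(0) = 1`, `R'(0) = −fp/vp`. The discriminant
is a sum of squares, so both rates are real and non-positive for all valid
parameters; the `PS = 0` limit reduces exactly to the one-compartment
`R(t) = exp(−fp t / vp)`. Closed form and direct ODE integration agree to
<1e−10 (tested to <1e−6 over 100 random parameter sets), and
`∫R dt = (vp+ve)/Fp` (the mean-transit-time identity) holds to <0.1%.

Convolution runs on a uniform internal grid at the median frame interval
(frame times may be R-R-irregular), with linear interpolation of the delayed
AIF and trapezoid end corrections; the delay `t0` is a continuous shift, not
an integer frame. MBF is reported as `Fp / ρ` with myocardial density
`ρ = 1.05 g/ml` (configurable). No hematocrit correction is applied by
default; an optional `1/(1−Hct)` AIF factor (Hct 0.45) can be enabled.

## Pixel-wise fitting and its identifiability limit

The fit is bounded trust-region least squares (`scipy.optimize.least_squares`,
tolerances 1e−8, ≤200 function evaluations per start) over
`Fp ∈ [0.01, 8]`, `PS ∈ [0, 5]`, `vp ∈ [0.01, 0.25]`, `ve ∈ [0.01, 0.6]`,
`t0 ∈ [0, 10] s`, with a 3-point multi-start on `Fp` ∈ {0.5, 1.5, 3.0}
(fixed mid-range starts elsewhere; residual ties go to the lower flow).
Residuals are unweighted.

A single-pixel 2CXM fit is near-degenerate: flow can be traded against
`(vp, PS, ve, t0)` with almost no change in the predicted curve once the AIF
is smooth relative to the vascular transit time (~2 s at stress flow). The
Cramér–Rao bound for the relative SD of `Fp` in the unconstrained 5-parameter
fit exceeds 25% at SNR 20 even for sharp inputs, so no unbiased pixel-wise
estimator can reach ~10% precision there. The fit therefore adds **weak
Gaussian priors** on the non-flow parameters — centers (PS 1.2, vp 0.10,
ve 0.25, t0 1.0 s), SDs (1.0, 0.05, 0.15, 1.5) — appended as penalty
residuals with weight `λ = 2·σ̂`, where `σ̂` is the noise SD estimated from
the tissue curve's pre-contrast baseline frames. Consequences:

- on noiseless data `σ̂ = 0`, the penalty vanishes, and recovery is exact;
- at SNR 20 the priors pin the unidentifiable directions and the median
  absolute relative MBF error is ≈8% (vs ≈25% unregularized);
- `Fp` itself is never penalized, and because `λ` scales with the data's
  noise amplitude, the fit stays invariant under joint rescaling of AIF and
  tissue units.

The prior centers deliberately differ from the phantom's true tissue
parameters, so the synthetic recovery studies do not simply read back the
prior. An all-zero tissue curve returns `Fp` at its lower bound flagged
non-converged, not an exception.

## Dual-bolus input handling

Bolus arrivals are detected on the mean LV blood-pool curve of the basal
slice (mask eroded by 1 pixel against partial volume): first frame whose
baseline-corrected signal exceeds `max(5·SD_baseline, 2% of that pass's own
peak)` for two consecutive frames; the main-bolus search re-arms only after
the pre-bolus has decayed back below threshold. Referencing each pass's own
peak makes the two crossings comparable, and linear interpolation of the
crossing gives sub-frame arrival times, so the rescaled pre-bolus is realigned
to the main bolus with sub-frame accuracy (reconstruction error <1% of peak
on noiseless phantoms).

The reconstructed AIF (`×1/dose_fraction`, realigned, on the main-bolus
window) follows the published dual-bolus scheme. For fitting, the package
goes one step further: tissue physically responds to *both* injections, so
the quantification uses the **composite input** — measured diluted pre-bolus
followed by the reconstructed full-dose AIF — over the full time axis. This
removes the decaying pre-bolus tissue residual from the model error (left
unmodeled it biases noiseless MBF by ~6–25% depending on washout), at the
cost of neglecting the truncated pre-bolus tail in the main window (<0.3% of
peak at a 10% dose with the default 30 s gap).

Mask consensus uses the test-time-augmentation voting rule: a pixel is
myocardium iff ≥8 of 10 candidate segmentations agree (threshold and count
configurable); the augmentation transforms themselves are outside this
package's scope, the combiner accepts any externally produced mask stack.

## AHA mapping and territory score

Angles are measured at the LV centroid, counterclockwise in image coordinates
with patient-anterior up. Insertion points are the end angles of the
RV-dilation ∩ myocardium contact arc (largest circular gap rule); the
anterior point is the one met first counterclockwise from 12 o'clock.
Basal/mid slices get six equal 60° sectors anchored at the anterior insertion
point, numbered counterclockwise (anterior, anteroseptal, inferoseptal,
inferior, inferolateral, anterolateral); apical slices get four 90° sectors
with the anchor rotated by 45° so sector centers fall on
anterior/septal/inferior/lateral. Boundary pixels go to the counterclockwise
sector. Segment 17 is omitted (not measurable with ≤3 short-axis slices).
Territory lookup is the classical assignment — LAD {1,2,7,8,13,14},
RCA {3,4,9,10,15}, LCx {5,6,11,12,16} — exposed as a configurable table
since some schemes assign boundary segments differently. With 2-slice
studies the two-lowest rule applies within the reduced basal+mid sets.

The territory score is the mean of the territory's two lowest segment means
(converged pixels only), a lower-tail statistic; segments without converged
pixels are flagged absent, and scoring requires ≥2 present segments.

## Synthetic phantom

Geometry per slice: concentric LV blood-pool disk (radius 0.125·grid),
myocardial annulus (outer radius 0.1875·grid), and an RV crescent spanning
the arc between the ground-truth insertion angles (60° and 160° by default);
the apical slice is scaled by 0.75. Defaults: 128×128 grid at 1.25 mm,
three slices, 0.7 s frame interval (stress heart rate ≈100 bpm approximated
as a constant interval), 60 frames per pass, 30 s inter-pass gap, pre-bolus
dose fraction 0.1.

The arterial input is a gamma-variate
`A·((t−t₀)/(kθ))^k·exp(k−(t−t₀)/θ)` with shape k = 1 and scale θ = 2.5 s
(onset-to-peak 2.5 s, FWHM ≈ 6 s — a compact pediatric stress bolus; the
sharp foot is also what makes flow identifiable at all, see above). A
dispersed recirculation term is available but off by default (first-pass
analysis). Tissue truth: PS 1.0 ml/min/ml, vp 0.10, ve 0.20, t0 1.5 s,
territory-dependent MBF (defaults: LAD 1.3, RCA/LCx 2.5 ml/min/g).
Signals are linear in concentration on a constant baseline (1.0 a.u.) with
seeded additive Gaussian noise (default SD 0.005 ≈ SNR 20 at the peak
myocardial enhancement for a unit-amplitude AIF). An optional
saturation-recovery operator `S = S₀(1 − exp(−T_sat·R1(c)))` can be enabled
to emulate the high-dose nonlinearity that motivates dual-bolus acquisition;
it is off by default because the quantification assumes linearity.

What the phantom does **not** emulate: k-t SENSE undersampling artifacts,
dark-rim artifacts, respiratory or cardiac motion, heart-rate variability of
the frame spacing, coil-profile or saturation-efficiency spatial variation,
partial-volume mixing at mask borders, and anatomical variability of the
ventricle. Passing recovery tests on these phantoms therefore demonstrates
the correctness and calibration of the estimation chain under its own model
assumptions — not robustness to real-world acquisition physics.

## Cohort generator and statistics

Territory-level cohorts draw MBF per group from a **quantile-matched split
log-normal**: `X = exp(ln m + σ(Z)·Z)`, `Z ~ N(0,1)`, with separate log-SDs
below/above the median derived from (q1, m, q3). Population median and both
quartiles match the group specification exactly; a symmetric log-normal
(IQR-matched) is available as `"lognormal"`, but cannot represent the
left-skewed normal-coronary group summary. Default group structure: normal
2.57 (2.02, 2.69) × 24, small aneurysm 2.52 (2.45, 2.83) × 6, affected 1.26
(1.05, 1.67) × 15 territory observations (≈15 scans × 3 territories).
Observations are treated as independent — no within-patient correlation is
modeled, matching how the territory tables are analyzed.

`median_iqr` uses linear interpolation of order statistics. The Mann–Whitney
U statistic comes from joint mid-ranks. Exact mode computes the tie-aware
permutation null by dynamic programming over the pooled multiset (doubled U
to keep half-integer ties integral), verified against full enumeration; the
two-sided p doubles the smaller tail, capped at 1. Auto mode uses exact when
`min(n) ≤ 8` and `n_a·n_b ≤ 400`, otherwise the tie-corrected,
continuity-corrected normal approximation (scipy). The approximation tracks
the exact two-sided p to ≲0.011 at `n_a = n_b = 8` (worst case over all
attainable U, by enumeration). Empirical size at α = 0.05 is ≈0.04–0.05
(slightly conservative, as expected with continuity correction). No
multiple-comparison correction is applied.

## Pipeline, determinism and problem sizes

`run_pipeline` executes simulate → preprocess → quantify → map → score →
stats per scan; a failing scan is excluded with a recorded reason and the
run continues. Scan `i` uses seed `base·1000 + i`; identical config + seed
gives byte-identical territory tables (CSV written with fixed formatting).
The run configuration defaults to a 48-pixel, two-slice phantom so that a
complete three-scan run with pixel-wise fitting of every myocardial pixel
finishes in about half a minute; recovery and acceptance studies use
32-pixel two-slice phantoms with subsampled myocardial masks (pixel fits are
independent, so subsampling changes cost, not statistics). The full-size
128-pixel, three-slice default of `PhantomConfig` remains available.

## Known limitations

- The priors that stabilize the pixel fit encode population physiology; in
  tissue whose true `vp`/`ve`/`PS` are far outside them (infarct scar,
  severe microvascular disease) MBF acquires a bias proportional to the
  noise level.
- Signal is assumed proportional to concentration; with the saturation
  operator enabled, quantification of the main-bolus blood pool would be
  biased — which is precisely why the AIF comes from the pre-bolus.
- Insertion-point accuracy degrades with very coarse grids (<5° requires
  roughly ≥64-pixel grids with this geometry).
- The exact Mann–Whitney DP is practical for `n_a·n_b` up to a few thousand;
  far beyond that, auto mode switches to the normal approximation anyway.
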