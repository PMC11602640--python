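# Methods

## Signal model

The steady-state signal fractions are

- SE: `(1 − exp(−TR/T1)) · exp(−TE/T2)`
- STEAM: `½ · (1 − exp(−(TR−TM)/T1)) · exp(−TM/T1) · exp(−TE/T2)`

with all times in ms. The STEAM mixing time defaults to the diffusion
encoding time Δ (the encoding interval is realized by longitudinal
storage during TM); the diffusion gradient-lobe duration δ is not
modelled in the relaxation terms. The `(1 − exp(−(TR−TM)/T1))`
saturation term is kept for generality although at TR ≈ 6700 ms it
changes the SE:STEAM ratio by well under 0.1%. SNR ratios assume equal
bandwidth and noise level, so they equal signal ratios.

The free diffusion length uses the three-dimensional mean-squared
displacement form `L = sqrt(6 D t)` (D in mm²/s, t in ms, L in µm): with
muscle-typical diffusivities this spans ~14 µm at the SE encoding time
(19 ms) up to ~66 µm at Δ = 600 ms, bracketing the ~25 µm myofiber
diameter that motivates long-encoding-time acquisitions.

Protocol constants (five sequences: SE and STEAM at Δ =
100/200/400/600 ms; TR 6700 ms except 9700 ms for the longest STEAM;
TE 42/36 ms; rotator-cuff T1/T2 = 1420/32 ms; per-sequence reference SNR
levels 72.3/40.1/37.6/33.2/29.2) ship as a versioned YAML resource.

## Diffusion encoding

Weighted volumes carry the rank-one b-matrix
`(√b_nom g + √b_ss ẑ)(√b_nom g + √b_ss ẑ)ᵀ`, i.e. nominal weighting plus
a slice-axis background `b_ss` plus the fully correlated cross term
`√(b_nom b_ss)(g ẑᵀ + ẑ gᵀ)`; this is positive semidefinite by
construction and its trace is `b_nom + b_ss + 2√(b_nom b_ss) g_z`. With
the default `b_ss = 5×10⁻⁴ s/mm²` the weighted traces span ≈ 499–501
s/mm² around the nominal 500. Nominally unweighted STEAM volumes carry
`b_bg(TM) · ẑ ẑᵀ`, with `b_bg` a straight line in the mixing time
calibrated by ordinary least squares to the protocol's printed effective
values (12/22/46/69 s/mm² at TM = 100/200/400/600 ms; slope
0.1151 s/mm²/ms, intercept −0.15 s/mm², residuals ≤ 0.87 s/mm²; the
three-point fit predicts the held-out 600 ms value as 68.6 → 69). The
background is modelled phenomenologically because gradient waveforms are
not integrated; SE volumes carry no background term.

Direction sets come from electrostatic repulsion on the sphere
(seeded isotropic initialization, 300 fixed iterations, forces include
each point's antipode because diffusion encoding is axial). The n = 64
default gives ≥ 16° minimum axis separation and a quadratic-design
condition number < 2. Antipodal symmetry is not enforced. `.bval`/`.bvec`
files use the FSL dialect, writing each volume's effective trace as its
b-value and a zero vector for reference volumes.

`pgse_b_value` provides the closed-form rectangular-lobe b-value
`γ²G²δ²(Δ − δ/3)` as an independent sanity check on b-matrix traces.

## Phantom and study simulation

The phantom is a 64×64×15 grid of 3 mm voxels: two elliptical-cylinder
bundles (anterior/posterior, ≥ 200 voxels each) flanking a thin tendon
sheet along the second axis, with fiber orientations tilted ±15°
(pennation) from the tendon axis in-plane. Proton density is uniform in
muscle and zero elsewhere; tendon voxels carry no signal and no
orientation. There is no fat compartment, no motion or eddy distortion,
and no partial-volume modelling — so passing recovery tests demonstrates
estimator correctness under the stated noise model, not robustness to
those real-world effects.

Ground truth is a direct (FA, MD)(Δ) law rather than a biophysical
restriction model: anchors FA 0.38→0.46 and MD 1.33→1.20 ×10⁻³ mm²/s
across STEAM Δ = 100→600 ms, SE at (0.26, 1.62×10⁻³); intermediate Δ are
interpolated log-linearly in Δ (the interpolated values are modelling
choices, not measured anchors). Per-voxel tensors are axially symmetric
with the closed-form FA inversion `λ∥ = MD(1+2a)`, `λ⊥ = MD(1−a)`,
`a = FA/√(3−2FA²)`, principal axis along the local fiber orientation.

Series synthesis: clean signal `S0 · steady_state · exp(−B : D)` per
voxel and volume, then two-channel Rician magnitude noise
`√((S+ε₁σ)² + (ε₂σ)²)` with `σ` set from the mean clean muscle reference
signal divided by the per-sequence SNR target (defaults are the
reference SNR levels above). At SNR ≥ 29 the Rician floor biases MD by
under 1%, which is accepted without correction.

The study simulator perturbs the ground truth additively per metric:
`value = base + u_s + w_st` with `u ~ N(0, σ_between²)` subject effects
and `w ~ N(0, σ_within²)` session effects, shared across sequences
within a subject/session to mimic physiology. Session effects act on the
metrics, not the raw signal, so the implied test–retest ICC is exactly
`σ_b²/(σ_b² + σ_w²)`. Defaults: FA σ_b = 0.03, σ_w = 0.008 (ICC ≈ 0.934,
the "excellent" regime); MD σ_b = 0.05×10⁻³, σ_w = 0.025×10⁻³ mm²/s
(ICC = 0.80, the "good" regime reported for muscle MD). Everything is
reproducible from one master seed, fanned out per series through
`SeedSequence([master, subject, session, sequence])` (all derived seeds
< 2³¹); the manifest records every per-series seed and truth value.

## Tensor fitting

Per voxel, `ln S_j = ln s0 − B_j : D` is solved by least squares with
the full 3×3 b-matrices (background and cross terms enter exactly). The
default is one-step reweighted WLS: an OLS pass, then one weighted pass
with weights equal to the squared predicted signal; no iterative
nonlinear fit, which is adequate at SNR ≥ 29. Voxels with any
nonpositive signal are flagged and skipped; a scheme with fewer than 6
independent directions (design rank < 7) is rejected. Negative
eigenvalues are clamped to zero for FA/MD and flagged, not constrained
away. No spatial smoothing is applied and registration is assumed done.

Ignoring the background encoding (fitting with scalar nominal b only)
leaves the STEAM reference volumes' attenuation unmodelled; this
deflates the fitted `s0` and biases MD low by ~10% at Δ = 600 ms in the
noiseless check — the motivation for carrying the full b-matrices.

## SNR estimation

Difference method on the ≥ 2 reference volumes: for each unordered pair,
the single-image noise SD is `SD(difference)/√2` over the ROI; estimates
are averaged over all pairs (3 pairs for 3 reference volumes — which
pairs to use is otherwise arbitrary). SNR = mean ROI/volume signal ÷
noise SD; identical volumes raise a degenerate-noise error. In synthetic
studies the ROI is the full 3-D anterior bundle (≥ 300 voxels) for
estimator stability; a tiny-ROI mode is available by passing any mask.
No Rician bias correction is applied to the signal mean (SNR ≥ 29
regime).

## ROI aggregation

FA and MD are read on the central slice (2-D regions, mirroring
single-slice freehand analysis; 3-D configurable), averaging the
anterior and posterior bundle values with voxel-count weights into one
value per series — the combination rule is a package choice, as is
excluding the tendon by construction. The measurement table has one row
per (subject, session, sequence, metric); for the default 10×3×5 design
that is 450 rows.

## Reliability statistics

- **ICC**: two-way mixed model, single measures, consistency form —
  ICC(3,1) = `(MS_subjects − MS_error)/(MS_subjects + (k−1) MS_error)` —
  with the Shrout–Fleiss F-quantile 95% CI. The consistency form is
  invariant to constant session shifts. Koo–Li bands: > 0.90 excellent,
  0.75–0.90 good (both endpoints map to the lower band at equality, so
  0.90 → good), 0.50–0.75 moderate, < 0.50 poor.
- **Bland–Altman**: bias = mean difference, limits = bias ± 1.96·SD
  (sample SD, n−1).
- **Friedman**: tie-corrected chi-square on within-subject mid-ranks
  (implemented directly so the two-condition case works), df = k−1;
  post-hoc pairs use `z = ΔR̄ / √(k(k+1)/(6n))` on the Friedman mean
  ranks with two-sided normal p, Bonferroni ×(k choose 2) — the
  rank-based construction, not per-pair Wilcoxon tests.
- **Wilcoxon signed-rank**: zeros dropped; exact enumeration for n ≤ 25
  without ties, otherwise tie- and continuity-corrected normal
  approximation.
- **Shapiro–Wilk** gate at α = 0.05 decides mean ± SD vs median (IQR)
  presentation downstream.

α = 0.05 throughout. Scipy supplies Shapiro–Wilk and Wilcoxon; the ICC,
Friedman chi-square and post-hoc z are computed from their ANOVA/rank
decompositions in this package.

## Problem sizes and numerical choices

Unit tests run on a 32×32×7 phantom; the image-based recovery check uses
the full 64×64×15 grid with a 4-subject × 2-session design (40 series of
67 volumes), chosen as the smallest layout that still exercises every
sequence, both session contrasts and the monotone Δ trend. The
metric-level table simulator (no images) backs the ICC-recovery and
type-I-error checks (200 and 2000 replicates), since those properties
depend only on the additive variance model. Determinism everywhere comes
from explicit seeds; direction generation uses a fixed iteration budget;
tensor eigendecomposition uses symmetric `eigh` with descending-sorted
eigenvalues and the antipodal color convention `|e1|·FA`.

## Known limitations

The phantom's two fixed orientations and uniform proton density make
ROI statistics more homogeneous than in vivo muscle; no registration,
distortion, fat or perfusion (IVIM) effects are simulated; the
interpolated Δ = 200/400 ground-truth values are placeholders between
measured anchors; and the linear background-b law is a calibration, not
a waveform computation, so it should not be extrapolated far outside
TM ∈ [100, 600] ms.
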