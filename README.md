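# steamdti

Simulation and analysis of skeletal-muscle diffusion tensor imaging (DTI)
acquired with stimulated-echo (STEAM) and spin-echo (SE) sequences.

Muscle DTI probes tissue microstructure through the water diffusion
tensor: fractional anisotropy (FA) and mean diffusivity (MD) report on
myofiber integrity. An SE sequence limits the diffusion encoding time Δ to
a few tens of milliseconds (T2 decay), whereas STEAM stores magnetization
longitudinally during a mixing time TM and can encode over hundreds of
milliseconds — long enough for water to feel the sarcolemma (free
diffusion length √(6 D t) beyond the ~25 µm myofiber diameter), so FA
rises and MD falls with Δ. The price is signal: the stimulated echo
recalls at most half the magnetization,

- SE:  S = (1 − e^(−TR/T1)) · e^(−TE/T2)
- STEAM: S = ½ · (1 − e^(−(TR−TM)/T1)) · e^(−TM/T1) · e^(−TE/T2)

This package is aimed at people developing or validating muscle-DTI
protocols and their statistical analysis. It provides:

- **signal model** — the steady-state equations above, SE:STEAM SNR-ratio
  prediction, and free-diffusion-length calculus;
- **encoding** — well-spread diffusion-direction sets, full 3×3 b-matrices
  including slice-select/crusher background and cross terms, a background
  b(TM) calibration, FSL `.bval`/`.bvec` I/O;
- **synthetic data** — a digital supraspinatus phantom (anterior/posterior
  pennate bundles flanking a tendon) with Δ-dependent (FA, MD) ground
  truth, Rician-noise series synthesis, and a multi-subject, multi-session
  test–retest study simulator;
- **tensor fit** — weighted log-linear tensor estimation using the full
  b-matrices, FA/MD/eigenvector/color maps;
- **SNR estimation** — the pairwise-subtraction (difference) method on
  repeated b = 0 volumes;
- **ROI analysis & reliability statistics** — ROI aggregation into a
  subject × session × sequence table; two-way mixed ICC with 95% CI and
  Koo–Li bands, Bland–Altman bias/limits, Friedman with Bonferroni rank
  post-hocs, Wilcoxon signed-rank, Shapiro–Wilk.

## Worked example

```python
from steamdti import (SequenceTiming, TissueRelaxation,
                      predicted_snr_ratio, free_diffusion_length,
                      steady_state_signal)

relax = TissueRelaxation(t1=1420, t2=32)          # rotator cuff, 3 T
se = SequenceTiming("SE", repetition_time=6700, echo_time=42,
                    encoding_time=19)
steam = SequenceTiming("STEAM", repetition_time=6700, echo_time=36,
                       encoding_time=100)          # TM defaults to Δ

print(f"SE signal fraction:    {steady_state_signal(se, relax):.4f}")
print(f"STEAM signal fraction: {steady_state_signal(steam, relax):.4f}")
print(f"SE:STEAM SNR ratio:    {predicted_snr_ratio(se, steam, relax):.1f}%")
print(f"free diffusion length, SE (D=1.6e-3 mm2/s, t=19 ms):  "
      f"{free_diffusion_length(1.6e-3, 19):.1f} um")
print(f"free diffusion length, STEAM (D=1.2e-3, t=600 ms): "
      f"{free_diffusion_length(1.2e-3, 600):.1f} um")
```

prints

```
SE signal fraction:    0.2667
STEAM signal fraction: 0.1498
SE:STEAM SNR ratio:    178.0%
free diffusion length, SE (D=1.6e-3 mm2/s, t=19 ms):  13.5 um
free diffusion length, STEAM (D=1.2e-3, t=600 ms): 65.7 um
```

i.e. SE is predicted to deliver 1.78× the SNR of STEAM at Δ = 100 ms for
rotator-cuff relaxation times, and the displacement probed grows from
~14 µm (SE, unrestricted) to ~66 µm (STEAM at Δ = 600 ms, well beyond the
myofiber diameter — radially restricted diffusion).

A full synthetic test–retest study (simulate → fit → ROI/SNR →
reliability statistics) runs from the command line:

```sh
steamdti run --seed 7 --out my-study     # full 10x3x5 study (slow)
steamdti physics                         # deterministic physics block
steamdti scheme --kind STEAM --delta 200 --out dwi
```

`my-study/report/` then contains the measurement table, per-sequence ICC
with confidence intervals and reliability bands, Bland–Altman bias,
Friedman/Wilcoxon comparisons, the SNR table and a plain-text summary.

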