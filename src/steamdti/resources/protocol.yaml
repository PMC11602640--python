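# Shoulder DTI protocol constants: one block per sequence, with the tissue
# relaxation times used for signal predictions and the study-level reference
# SNR per sequence. All times in ms, b-values in s/mm^2.
version: 1
tissue:
  t1_ms: 1420.0
  t2_ms: 32.0
se_diffusion_time_ms: 19.0
nominal_b: 500.0
n_directions: 64
n_reference: 3
grid:
  shape: [64, 64, 15]
  voxel_mm: 3.0
sequences:
  SE:
    kind: SE
    tr_ms: 6700.0
    te_ms: 42.0
    delta_ms: 19.0
    b0_effective: 0.0
    snr_reference: 72.3
  STEAM100:
    kind: STEAM
    tr_ms: 6700.0
    te_ms: 36.0
    delta_ms: 100.0
    b0_effective: 12.0
    snr_reference: 40.1
  STEAM200:
    kind: STEAM
    tr_ms: 6700.0
    te_ms: 36.0
    delta_ms: 200.0
    b0_effective: 22.0
    snr_reference: 37.6
  STEAM400:
    kind: STEAM
    tr_ms: 6700.0
    te_ms: 36.0
    delta_ms: 400.0
    b0_effective: 46.0
    snr_reference: 33.2
  STEAM600:
    kind: STEAM
    tr_ms: 9700.0
    te_ms: 36.0
    delta_ms: 600.0
    b0_effective: 69.0
    snr_reference: 29.2
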