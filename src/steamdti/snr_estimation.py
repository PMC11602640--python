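"""SNR estimation from repeated unweighted volumes by pairwise subtraction.

With two acquisitions of the same volume the signal cancels in the
difference image and the noise SD of a single image is the ROI standard
deviation of the difference divided by sqrt(2).  SNR is the ROI- and
volume-mean signal divided by that noise SD, averaged over all unordered
pairs of reference volumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateNoiseError, ValidationError

__all__ = ["SNRResult", "estimate_snr"]


@dataclass(frozen=True)
class SNRResult:
    snr: float
    signal_mean: float
    noise_sd: float
    n_pairs: int
    roi_voxels: int


def estimate_snr(reference_volumes: Sequence[np.ndarray], roi: np.ndarray) -> SNRResult:
    """Difference-method SNR over an ROI from >= 2 aligned volumes.

    Scale invariant: multiplying all volumes by c > 0 leaves the SNR
    unchanged.  Raises on identical (noiseless) volumes, whose difference
    carries no noise information.
    """
    vols = [np.asarray(v, dtype=float) for v in reference_volumes]
    if len(vols) < 2:
        raise ValidationError("need at least 2 reference volumes")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != vols[0].shape:
        raise ValidationError("ROI shape does not match the volumes")
    n_roi = int(roi.sum())
    if n_roi < 2:
        raise ValidationError("ROI must contain at least 2 voxels")

    samples = np.stack([v[roi] for v in vols])  # (n_vol, n_roi)
    signal_mean = float(samples.mean())
    sds = [
        float((samples[i] - samples[j]).std(ddof=1) / np.sqrt(2.0))
        for i, j in itertools.combinations(range(len(vols)), 2)
    ]
    noise_sd = float(np.mean(sds))
    if noise_sd == 0.0:
        raise DegenerateNoiseError(
            "degenerate noise estimate: reference volumes are identical"
        )
    return SNRResult(
        snr=signal_mean / noise_sd,
        signal_mean=signal_mean,
        noise_sd=noise_sd,
        n_pairs=len(sds),
        roi_voxels=n_roi,
    )
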