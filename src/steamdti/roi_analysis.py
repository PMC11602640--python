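"""ROI definition from the phantom and aggregation into the study table.

ROI values for FA and MD are taken on the central slice (mirroring 2-D
regions drawn on a single slice), with the anterior and posterior bundle
values combined by voxel-count-weighted averaging into one value per
series.  SNR uses the full 3-D muscle ROI for estimator stability.  The
measurement table has one row per (subject, session, sequence, metric).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Literal, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .encoding import build_scheme, calibrate_background_b
from .errors import ValidationError
from . import protocol
from .signal_model import SequenceKind
from .snr_estimation import estimate_snr
from .synthetic_data import MusclePhantom, PhantomSpec, build_phantom
from .tensor_fit import fit_tensor, tensor_metrics

__all__ = ["ROIMeans", "roi_means", "default_rois", "build_measurement_table"]

TABLE_COLUMNS = ["subject", "session", "sequence", "metric", "value"]


@dataclass(frozen=True)
class ROIMeans:
    anterior: float
    posterior: float
    combined: float  # voxel-count-weighted mean of the union
    n_anterior: int
    n_posterior: int


def roi_means(
    values: np.ndarray,
    rois: Dict[str, np.ndarray],
    tendon_mask: Optional[np.ndarray] = None,
) -> ROIMeans:
    """Per-ROI means and the voxel-weighted combined mean.

    Raises on empty masks and on masks overlapping the tendon label.
    """
    for name in ("anterior", "posterior"):
        if name not in rois:
            raise ValidationError(f"missing ROI {name!r}")
        mask = np.asarray(rois[name], dtype=bool)
        if mask.shape != values.shape:
            raise ValidationError(f"ROI {name!r} shape does not match the map")
        if not mask.any():
            raise ValidationError(f"ROI {name!r} is empty")
        if tendon_mask is not None and (mask & tendon_mask).any():
            raise ValidationError(f"ROI {name!r} overlaps the tendon")
    ant = np.asarray(rois["anterior"], dtype=bool)
    post = np.asarray(rois["posterior"], dtype=bool)
    na, np_ = int(ant.sum()), int(post.sum())
    mean_a = float(values[ant].mean())
    mean_p = float(values[post].mean())
    combined = (mean_a * na + mean_p * np_) / (na + np_)
    return ROIMeans(
        anterior=mean_a, posterior=mean_p, combined=combined,
        n_anterior=na, n_posterior=np_,
    )


def default_rois(
    phantom: MusclePhantom, mode: Literal["2d", "3d"] = "2d"
) -> Dict[str, np.ndarray]:
    """Anterior/posterior bundle masks, on the central slice by default."""
    ant = phantom.anterior_mask.copy()
    post = phantom.posterior_mask.copy()
    if mode == "2d":
        keep = np.zeros_like(ant)
        keep[:, :, phantom.central_slice] = True
        ant &= keep
        post &= keep
    elif mode != "3d":
        raise ValidationError(f"unknown ROI mode {mode!r}")
    return {"anterior": ant, "posterior": post}


def _scheme_from_sidecar(sidecar: dict, background_law: dict):
    kind = SequenceKind(sidecar["kind"])
    if kind is SequenceKind.STEAM:
        law = calibrate_background_b(
            protocol.background_b_samples(),
            slice_select_b=background_law["slice_select_b"],
        )
    else:
        law = None
    return build_scheme(
        kind,
        sidecar["delta_ms"],
        law=law,
        n_directions=sidecar["n_directions"],
        n_reference=sidecar["n_reference"],
        nominal_b=sidecar["nominal_b"],
        direction_seed=sidecar["direction_seed"],
    )


def build_measurement_table(
    study_dir: Union[str, Path],
    roi_mode: Literal["2d", "3d"] = "2d",
    fit_method: Literal["ols", "wls"] = "wls",
) -> pd.DataFrame:
    """Fit every series of a simulated study and tabulate FA, MD and SNR.

    Reads the study manifest, rebuilds the phantom and encoding schemes it
    records, fits each series within the muscle mask, and returns a long
    table with columns (subject, session, sequence, metric, value).
    Deterministic: rerunning on the same directory yields an identical
    table.  A missing series raises an error naming every gap.
    """
    study_dir = Path(study_dir)
    manifest = json.loads((study_dir / "manifest.json").read_text())
    phantom = build_phantom(PhantomSpec.from_dict(manifest["phantom_spec"]))
    rois = default_rois(phantom, mode=roi_mode)
    muscle = phantom.muscle_mask
    snr_roi = phantom.anterior_mask  # 3-D bundle, >= 300 voxels

    missing = [
        e["path"] for e in manifest["series"]
        if not (study_dir / e["path"] / "dwi.nii.gz").exists()
    ]
    if missing:
        raise ValidationError(
            "missing series: " + ", ".join(sorted(missing))
        )

    schemes = {}
    rows = []
    for entry in manifest["series"]:
        series_dir = study_dir / entry["path"]
        sidecar = json.loads((series_dir / "sidecar.json").read_text())
        name = entry["sequence"]
        if name not in schemes:
            schemes[name] = _scheme_from_sidecar(
                sidecar, manifest["background_law"]
            )
        scheme = schemes[name]
        data = np.asarray(
            nib.load(series_dir / "dwi.nii.gz").get_fdata(), dtype=np.float64
        )
        field = fit_tensor(data, scheme, muscle, method=fit_method)
        metrics = tensor_metrics(field)
        fa = roi_means(metrics.fa, rois, phantom.tendon_mask).combined
        md = roi_means(metrics.md, rois, phantom.tendon_mask).combined
        refs = [data[..., j] for j in np.flatnonzero(scheme.reference_index)]
        snr = estimate_snr(refs, snr_roi).snr
        for metric, value in (("FA", fa), ("MD", md), ("SNR", snr)):
            rows.append({
                "subject": entry["subject"],
                "session": entry["session"],
                "sequence": name,
                "metric": metric,
                "value": value,
            })
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return table.sort_values(TABLE_COLUMNS[:4], ignore_index=True)
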