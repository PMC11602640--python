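"""Digital supraspinatus phantom and test-retest study simulator.

The phantom is a labelled 3-D grid: two elliptical-cylinder muscle bundles
(anterior and posterior) flanking a thin tendon sheet, with fiber
orientations tilted by a pennation angle to either side of the tendon
axis.  Ground truth is encoded directly as an (FA, MD) law of the
diffusion encoding time — FA rises and MD falls as the encoding time
grows, reflecting increasing restriction of water displacement by the
sarcolemma — rather than through an explicit biophysical restriction
model, which keeps the per-voxel tensors exactly known.

Series synthesis scales a uniform proton density by the sequence's
steady-state signal, attenuates it through the full b-matrix contraction
exp(-B : D), and adds two-channel (Rician) magnitude noise at a target
SNR.  The study simulator writes a full multi-subject, multi-session,
multi-sequence dataset to disk (NIfTI + bval/bvec + JSON sidecars and a
manifest) with subject- and session-level perturbations of the ground
truth that directly control the intraclass correlation the reliability
analysis should recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import nibabel as nib
import numpy as np

from .encoding import (
    BackgroundEncodingLaw,
    DiffusionScheme,
    build_scheme,
    calibrate_background_b,
    write_bval_bvec,
)
from .errors import ValidationError
from . import protocol
from .signal_model import (
    SequenceKind,
    SequenceTiming,
    TissueRelaxation,
    steady_state_signal,
)

__all__ = [
    "GroundTruthLaw",
    "PhantomSpec",
    "MusclePhantom",
    "StudyDesign",
    "tensor_from_fa_md",
    "ground_truth_metrics",
    "build_phantom",
    "synthesize_series",
    "simulate_study",
    "sample_measurement_grid",
    "theoretical_icc",
]

LABEL_BACKGROUND = 0
LABEL_ANTERIOR = 1
LABEL_POSTERIOR = 2
LABEL_TENDON = 3


# ---------------------------------------------------------------------------
# ground truth law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthLaw:
    """(FA, MD) ground truth per sequence kind and encoding time.

    STEAM values between the anchors are interpolated log-linearly in the
    encoding time; the SE values are a single anchor (its short encoding
    time probes essentially free diffusion).  MD in mm^2/s.
    """

    se_fa: float = 0.26
    se_md: float = 1.62e-3
    steam_anchors: Tuple[Tuple[float, float, float], ...] = (
        (100.0, 0.38, 1.33e-3),
        (600.0, 0.46, 1.20e-3),
    )

    def __post_init__(self) -> None:
        fas = [a[1] for a in self.steam_anchors]
        mds = [a[2] for a in self.steam_anchors]
        if not all(0 < f < 1 for f in fas + [self.se_fa]):
            raise ValidationError("fa values must lie in (0, 1)")
        if not all(m > 0 for m in mds + [self.se_md]):
            raise ValidationError("md values must be > 0")
        if not all(a < b for a, b in zip(fas, fas[1:])):
            raise ValidationError("STEAM fa must increase with encoding time")
        if not all(a > b for a, b in zip(mds, mds[1:])):
            raise ValidationError("STEAM md must decrease with encoding time")
        if not self.se_fa < min(fas):
            raise ValidationError("SE fa must be below all STEAM fa values")
        if not self.se_md > max(mds):
            raise ValidationError("SE md must exceed all STEAM md values")

    def metrics(self, kind: Union[SequenceKind, str], delta: Optional[float] = None
                ) -> Tuple[float, float]:
        kind = SequenceKind(kind)
        if kind is SequenceKind.SE:
            return self.se_fa, self.se_md
        if delta is None:
            raise ValidationError("encoding time required for STEAM")
        times = np.array([a[0] for a in self.steam_anchors])
        if not times[0] <= delta <= times[-1]:
            raise ValidationError(
                f"encoding time {delta} outside interpolation range "
                f"[{times[0]}, {times[-1]}]"
            )
        log_t = np.log(times)
        fa = float(np.interp(math.log(delta), log_t,
                             [a[1] for a in self.steam_anchors]))
        md = float(np.interp(math.log(delta), log_t,
                             [a[2] for a in self.steam_anchors]))
        return fa, md


def ground_truth_metrics(
    kind: Union[SequenceKind, str],
    delta: Optional[float] = None,
    law: Optional[GroundTruthLaw] = None,
) -> Tuple[float, float]:
    """(FA, MD) ground truth for a sequence kind at encoding time `delta`."""
    return (law or GroundTruthLaw()).metrics(kind, delta)


# ---------------------------------------------------------------------------
# tensors
# ---------------------------------------------------------------------------


def tensor_from_fa_md(fa: float, md: float, direction: np.ndarray) -> np.ndarray:
    """Axially symmetric tensor with given FA, MD and principal axis.

    With eigenvalues lambda_par = MD (1 + 2 a) and lambda_perp = MD (1 - a)
    the mean diffusivity is MD for any a, and the FA definition reduces to
    FA = 3a / sqrt(3 + 6 a^2), inverted in closed form as
    a = FA / sqrt(3 - 2 FA^2).  FA < 1 guarantees lambda_perp > 0.
    """
    if not 0 <= fa < 1:
        raise ValidationError("fa must lie in [0, 1)")
    if not md > 0:
        raise ValidationError("md must be > 0")
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValidationError("direction must be a unit vector")
    a = fa / math.sqrt(3.0 - 2.0 * fa * fa)
    lam_perp = md * (1.0 - a)
    lam_par = md * (1.0 + 2.0 * a)
    if lam_perp < 0:
        raise ValidationError("fa too large: negative radial eigenvalue")
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(direction, direction)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital muscle phantom.

    The tendon runs along the second (y) axis; the two bundles are
    elliptical cylinders in the x-z plane on either side of it.  Fractions
    are relative to the grid shape so the phantom scales with resolution.
    """

    shape: Tuple[int, int, int] = (64, 64, 15)
    voxel_mm: float = 3.0
    pennation_deg: float = 15.0
    s0: float = 1000.0
    bundle_halfwidth_frac: float = 0.10  # x semi-axis / nx
    bundle_halfheight_frac: float = 0.24  # z semi-axis / nz
    bundle_offset_frac: float = 0.13  # bundle center offset from tendon / nx
    y_margin_frac: float = 0.15
    tendon_halfwidth: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PhantomSpec":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        return PhantomSpec(**d)


@dataclass(frozen=True)
class MusclePhantom:
    labels: np.ndarray  # int grid
    orientations: np.ndarray  # (nx, ny, nz, 3), zero outside muscle
    s0: np.ndarray  # proton-density grid, a.u.
    voxel_mm: float
    spec: PhantomSpec

    @property
    def muscle_mask(self) -> np.ndarray:
        return (self.labels == LABEL_ANTERIOR) | (self.labels == LABEL_POSTERIOR)

    @property
    def anterior_mask(self) -> np.ndarray:
        return self.labels == LABEL_ANTERIOR

    @property
    def posterior_mask(self) -> np.ndarray:
        return self.labels == LABEL_POSTERIOR

    @property
    def tendon_mask(self) -> np.ndarray:
        return self.labels == LABEL_TENDON

    @property
    def central_slice(self) -> int:
        return self.labels.shape[2] // 2


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> MusclePhantom:
    """Deterministic labelled phantom with pennate fiber orientations."""
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int8)
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    y_lo, y_hi = int(round(ny * spec.y_margin_frac)), int(
        round(ny * (1 - spec.y_margin_frac))
    )
    in_y = (ys >= y_lo) & (ys < y_hi)

    rx = spec.bundle_halfwidth_frac * nx
    rz = spec.bundle_halfheight_frac * nz
    off = spec.bundle_offset_frac * nx
    for label, sign in ((LABEL_ANTERIOR, -1.0), (LABEL_POSTERIOR, +1.0)):
        bx = cx + sign * off
        ell = ((xs - bx) / rx) ** 2 + ((zs - cz) / rz) ** 2 <= 1.0
        labels[ell & in_y] = label
    tendon = (np.abs(xs - cx) <= spec.tendon_halfwidth) & in_y & (
        np.abs(zs - cz) <= max(1, int(rz / 2))
    )
    labels[tendon] = LABEL_TENDON

    for name, mask in (("anterior", labels == LABEL_ANTERIOR),
                       ("posterior", labels == LABEL_POSTERIOR)):
        if mask.sum() < 200:
            raise ValidationError(
                f"{name} bundle has {int(mask.sum())} voxels (< 200); "
                "enlarge the phantom"
            )

    theta = math.radians(spec.pennation_deg)
    orientations = np.zeros(spec.shape + (3,))
    # fibers run along y, fanned toward/away from the tendon in the x-y plane
    orientations[labels == LABEL_ANTERIOR] = (math.sin(theta), math.cos(theta), 0.0)
    orientations[labels == LABEL_POSTERIOR] = (-math.sin(theta), math.cos(theta), 0.0)

    s0 = np.zeros(spec.shape)
    s0[(labels == LABEL_ANTERIOR) | (labels == LABEL_POSTERIOR)] = spec.s0
    return MusclePhantom(
        labels=labels, orientations=orientations, s0=s0,
        voxel_mm=spec.voxel_mm, spec=spec,
    )


# ---------------------------------------------------------------------------
# series synthesis
# ---------------------------------------------------------------------------


def synthesize_series(
    phantom: MusclePhantom,
    scheme: DiffusionScheme,
    timing: SequenceTiming,
    relax: TissueRelaxation,
    snr_target: float,
    seed: int,
    fa_md: Optional[Tuple[float, float]] = None,
    law: Optional[GroundTruthLaw] = None,
) -> np.ndarray:
    """Simulate a 4-D magnitude series (nx, ny, nz, n_volumes).

    The clean signal is S0 * steady_state_signal * exp(-B : D); magnitude
    noise is Rician: sqrt((S + e1 sigma)^2 + (e2 sigma)^2) with iid
    standard-normal e and sigma = mean clean muscle reference signal
    divided by `snr_target`.
    """
    if not snr_target > 0:
        raise ValidationError("snr_target must be > 0")
    if scheme.sequence_kind is not timing.kind:
        raise ValidationError("scheme and timing disagree on sequence kind")
    if fa_md is None:
        fa_md = ground_truth_metrics(timing.kind, timing.encoding_time, law)
    fa, md = fa_md

    muscle = phantom.muscle_mask
    n_muscle = int(muscle.sum())
    if n_muscle == 0:
        raise ValidationError("phantom contains no muscle voxels")
    orient = phantom.orientations[muscle]  # (n_muscle, 3)
    # only a handful of distinct orientations exist: build tensors per group
    uniq, inverse = np.unique(orient.round(12), axis=0, return_inverse=True)
    tensors = np.stack([tensor_from_fa_md(fa, md, u) for u in uniq])
    d_vox = tensors[inverse]  # (n_muscle, 3, 3)

    bmats = scheme.b_matrices  # (n_vol, 3, 3)
    att = np.exp(-np.einsum("jab,vab->jv", bmats, d_vox))  # (n_vol, n_muscle)
    amplitude = phantom.s0[muscle] * steady_state_signal(timing, relax)
    clean_muscle = amplitude[None, :] * att

    ref = scheme.reference_index
    sigma = float(clean_muscle[ref].mean()) / snr_target

    n_vol = len(scheme)
    clean = np.zeros(phantom.labels.shape + (n_vol,), dtype=np.float64)
    clean[muscle] = clean_muscle.T
    rng = np.random.default_rng(seed)
    e1 = rng.standard_normal(clean.shape)
    e2 = rng.standard_normal(clean.shape)
    return np.sqrt((clean + sigma * e1) ** 2 + (sigma * e2) ** 2)


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------


def _default_snr_targets() -> Dict[str, float]:
    return protocol.reference_snr()


@dataclass(frozen=True)
class StudyDesign:
    """Test-retest study layout and between/within-subject variability.

    `sigma_between` / `sigma_within` give, per metric ('fa', 'md'), the SD
    of the subject-level and session-level additive perturbations of the
    ground-truth value; the perturbations are shared across sequences
    within a subject/session, mimicking subject physiology.  The implied
    test-retest intraclass correlation is
    sigma_between^2 / (sigma_between^2 + sigma_within^2).
    """

    n_subjects: int = 10
    n_sessions: int = 3
    sigma_between: Dict[str, float] = field(
        default_factory=lambda: {"fa": 0.03, "md": 0.05e-3}
    )
    sigma_within: Dict[str, float] = field(
        default_factory=lambda: {"fa": 0.008, "md": 0.025e-3}
    )
    snr_targets: Dict[str, float] = field(default_factory=_default_snr_targets)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_sessions < 2:
            raise ValidationError("need at least 2 subjects and 2 sessions")
        for d in (self.sigma_between, self.sigma_within):
            if any(v < 0 for v in d.values()):
                raise ValidationError("sigmas must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_sessions": self.n_sessions,
            "sigma_between": dict(self.sigma_between),
            "sigma_within": dict(self.sigma_within),
            "snr_targets": dict(self.snr_targets),
            "master_seed": self.master_seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "StudyDesign":
        return StudyDesign(**d)


def theoretical_icc(sigma_between: float, sigma_within: float) -> float:
    """Population test-retest ICC implied by the additive variance model."""
    b2, w2 = sigma_between**2, sigma_within**2
    return b2 / (b2 + w2)


def _series_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def sample_measurement_grid(
    design: StudyDesign,
    base_value: float,
    metric: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a subjects x sessions grid of metric values (no imaging).

    value_st = base + u_s + w_st with u ~ N(0, sigma_between^2) and
    w ~ N(0, sigma_within^2).  This is the generative model underlying the
    full image-based study, exposed directly for statistical validation.
    """
    sb = design.sigma_between[metric]
    sw = design.sigma_within[metric]
    u = rng.normal(0.0, sb, size=(design.n_subjects, 1))
    w = rng.normal(0.0, sw, size=(design.n_subjects, design.n_sessions))
    return base_value + u + w


def simulate_study(
    design: StudyDesign,
    law: GroundTruthLaw,
    phantom_spec: PhantomSpec,
    out_dir: Union[str, Path],
    sequences: Optional[Tuple[str, ...]] = None,
) -> Path:
    """Write a full synthetic test-retest study to `out_dir`.

    Layout: ``sub-XX/ses-Y/<sequence>/dwi.nii.gz`` plus ``dwi.bval``,
    ``dwi.bvec`` and ``sidecar.json`` per series, and a top-level
    ``manifest.json`` recording the design, phantom spec, background law,
    per-series seeds and perturbed ground truth.  Returns the manifest
    path.  Fully reproducible from ``design.master_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sequences is None:
        sequences = tuple(protocol.sequence_names())

    proto = protocol.load_protocol()
    relax = protocol.tissue_relaxation()
    bg_law = calibrate_background_b(protocol.background_b_samples())
    phantom = build_phantom(phantom_spec)
    affine = np.diag([phantom.voxel_mm] * 3 + [1.0])

    direction_seed = design.master_seed % (2**31)
    schemes: Dict[str, DiffusionScheme] = {}
    timings: Dict[str, SequenceTiming] = {}
    for name in sequences:
        timings[name] = protocol.sequence_timing(name)
        schemes[name] = build_scheme(
            timings[name].kind,
            timings[name].encoding_time,
            law=bg_law if timings[name].kind is SequenceKind.STEAM else None,
            n_directions=proto["n_directions"],
            n_reference=proto["n_reference"],
            nominal_b=proto["nominal_b"],
            direction_seed=direction_seed,
        )

    # subject/session perturbations, shared across sequences
    rng = np.random.default_rng(
        np.random.SeedSequence([design.master_seed, 0xA11CE])
    )
    perturb = {}
    for metric in ("fa", "md"):
        u = rng.normal(0.0, design.sigma_between[metric], size=design.n_subjects)
        w = rng.normal(
            0.0, design.sigma_within[metric],
            size=(design.n_subjects, design.n_sessions),
        )
        perturb[metric] = (u, w)

    series_entries = []
    for s in range(design.n_subjects):
        for t in range(design.n_sessions):
            for q, name in enumerate(sequences):
                timing = timings[name]
                base_fa, base_md = law.metrics(timing.kind, timing.encoding_time)
                fa = float(np.clip(
                    base_fa + perturb["fa"][0][s] + perturb["fa"][1][s, t],
                    1e-3, 0.999,
                ))
                md = float(max(
                    base_md + perturb["md"][0][s] + perturb["md"][1][s, t], 1e-6
                ))
                seed = _series_seed(design.master_seed, s, t, q)
                rel = (
                    f"sub-{s + 1:02d}/ses-{t + 1}/{name}"
                )
                series_dir = out_dir / rel
                series_dir.mkdir(parents=True, exist_ok=True)
                data = synthesize_series(
                    phantom, schemes[name], timing, relax,
                    snr_target=design.snr_targets[name],
                    seed=seed, fa_md=(fa, md),
                )
                nib.save(
                    nib.Nifti1Image(data.astype(np.float32), affine),
                    series_dir / "dwi.nii.gz",
                )
                write_bval_bvec(series_dir / "dwi", schemes[name])
                sidecar = {
                    "sequence": name,
                    "kind": timing.kind.value,
                    "tr_ms": timing.repetition_time,
                    "te_ms": timing.echo_time,
                    "delta_ms": timing.encoding_time,
                    "tm_ms": timing.mixing_time,
                    "nominal_b": proto["nominal_b"],
                    "n_directions": proto["n_directions"],
                    "n_reference": proto["n_reference"],
                    "direction_seed": direction_seed,
                    "snr_target": design.snr_targets[name],
                }
                (series_dir / "sidecar.json").write_text(
                    json.dumps(sidecar, indent=1, sort_keys=True)
                )
                series_entries.append({
                    "subject": s + 1,
                    "session": t + 1,
                    "sequence": name,
                    "path": rel,
                    "seed": seed,
                    "fa_true": fa,
                    "md_true": md,
                    "snr_target": design.snr_targets[name],
                })
    manifest = {
        "design": design.to_dict(),
        "ground_truth_law": {
            "se_fa": law.se_fa,
            "se_md": law.se_md,
            "steam_anchors": [list(a) for a in law.steam_anchors],
        },
        "phantom_spec": phantom_spec.to_dict(),
        "background_law": {
            "slope": bg_law.slope,
            "intercept": bg_law.intercept,
            "slice_select_b": bg_law.slice_select_b,
        },
        "sequences": list(sequences),
        "series": series_entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path
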