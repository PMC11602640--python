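"""Diffusion-encoding schemes: directions, b-matrices and bval/bvec I/O.

The effective diffusion weighting of a volume is a symmetric 3x3 b-matrix
whose trace is the effective b-value.  On top of the nominal weighting
b_nom * g g^T from the diffusion gradients, slice-select/crusher gradients
along the slice axis contribute a small background term and a cross term
sqrt(b_nom * b_ss) between the two, which is why the nominally unweighted
("b = 0") STEAM volumes carry an effective b that grows with the mixing
time and why the weighted volumes span a ~2 s/mm^2 band around the nominal
b-value.  The background b is modelled phenomenologically as a straight
line in the mixing time, calibrated to the protocol's printed effective
values; gradient waveforms are not integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError
from .signal_model import SequenceKind

__all__ = [
    "DiffusionVolume",
    "DiffusionScheme",
    "BackgroundEncodingLaw",
    "generate_directions",
    "calibrate_background_b",
    "build_scheme",
    "pgse_b_value",
    "write_bval_bvec",
    "read_bval_bvec",
]

#: gyromagnetic ratio of the proton, rad s^-1 T^-1
GYROMAGNETIC_RATIO = 267.513e6

#: default slice-select background b for weighted volumes, s/mm^2
DEFAULT_SLICE_SELECT_B = 5e-4

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class DiffusionVolume:
    nominal_b: float
    direction: np.ndarray  # unit 3-vector (zero vector for reference volumes)
    b_matrix: np.ndarray  # symmetric 3x3, s/mm^2
    is_reference: bool

    @property
    def effective_b(self) -> float:
        return float(np.trace(self.b_matrix))


@dataclass(frozen=True)
class DiffusionScheme:
    """Ordered per-volume encoding description of one series."""

    volumes: Tuple[DiffusionVolume, ...]
    sequence_kind: SequenceKind
    encoding_time: float  # ms

    def __post_init__(self) -> None:
        for i, v in enumerate(self.volumes):
            if not np.allclose(v.b_matrix, v.b_matrix.T, atol=1e-12):
                raise ValidationError(f"b_matrix of volume {i} is not symmetric")
            if np.linalg.eigvalsh(v.b_matrix).min() < -1e-9:
                raise ValidationError(f"b_matrix of volume {i} is not PSD")
            if not v.is_reference:
                if abs(np.linalg.norm(v.direction) - 1.0) > 1e-9:
                    raise ValidationError(
                        f"direction of weighted volume {i} is not unit length"
                    )

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def n_reference(self) -> int:
        return sum(v.is_reference for v in self.volumes)

    @property
    def b_matrices(self) -> np.ndarray:
        return np.stack([v.b_matrix for v in self.volumes])

    @property
    def effective_bvals(self) -> np.ndarray:
        return np.array([v.effective_b for v in self.volumes])

    @property
    def directions(self) -> np.ndarray:
        return np.stack([v.direction for v in self.volumes])

    @property
    def reference_index(self) -> np.ndarray:
        return np.array([v.is_reference for v in self.volumes])


@dataclass(frozen=True)
class BackgroundEncodingLaw:
    """Linear law b_bg(TM) = slope * TM + intercept, s/mm^2.

    `slice_select_b` is the residual background weighting applied along the
    slice axis in the diffusion-weighted volumes (source of the cross term).
    `residuals` are the calibration residuals, in sample order.
    """

    slope: float  # s/mm^2 per ms
    intercept: float  # s/mm^2
    slice_select_b: float = DEFAULT_SLICE_SELECT_B
    residuals: Tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValidationError("slope must be > 0")

    def predict(self, mixing_time: float) -> float:
        return self.slope * mixing_time + self.intercept


def generate_directions(n: int, seed: int) -> np.ndarray:
    """Deterministic well-spread unit vectors by electrostatic repulsion.

    Points are initialized from a seeded isotropic draw and relaxed for a
    fixed number of iterations under pairwise Coulomb forces that include
    each point's antipode, so the set spreads with respect to the axes it
    encodes (diffusion is antipodally symmetric).  Output is bit-identical
    for equal (n, seed).
    """
    if n < 6:
        raise ValidationError("need at least 6 directions to determine a tensor")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.01
    for _ in range(300):
        diff = x[:, None, :] - x[None, :, :]  # repulsion from points
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        force = (diff / dist[..., None] ** 3).sum(axis=1)
        anti = x[:, None, :] + x[None, :, :]  # repulsion from antipodes
        adist = np.linalg.norm(anti, axis=-1)
        adist[adist < 1e-12] = np.inf
        force += (anti / adist[..., None] ** 3).sum(axis=1)
        # project tangentially and take a bounded step
        force -= (force * x).sum(axis=1, keepdims=True) * x
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm < 1e-12] = 1.0
        x = x + step * force / norm
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def calibrate_background_b(
    samples: Sequence[Tuple[float, float]],
    slice_select_b: float = DEFAULT_SLICE_SELECT_B,
) -> BackgroundEncodingLaw:
    """Ordinary least-squares line through (mixing time, effective b) pairs."""
    tm = np.array([s[0] for s in samples], dtype=float)
    beff = np.array([s[1] for s in samples], dtype=float)
    if np.unique(tm).size < 2:
        raise ValidationError(
            "need at least 2 samples with distinct mixing times to calibrate"
        )
    design = np.column_stack([tm, np.ones_like(tm)])
    coef, *_ = np.linalg.lstsq(design, beff, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = beff - (slope * tm + intercept)
    law = BackgroundEncodingLaw(
        slope=slope,
        intercept=intercept,
        slice_select_b=slice_select_b,
        residuals=tuple(float(r) for r in resid),
    )
    if min(law.predict(t) for t in tm) < 0:
        raise ValidationError("calibrated law predicts negative background b")
    return law


def build_scheme(
    kind: Union[SequenceKind, str],
    encoding_time: float,
    law: Optional[BackgroundEncodingLaw] = None,
    n_directions: int = 64,
    n_reference: int = 3,
    nominal_b: float = 500.0,
    direction_seed: int = 0,
) -> DiffusionScheme:
    """Assemble a full scheme: reference volumes first, then weighted ones.

    STEAM reference volumes carry B = b_bg(TM) * z z^T with b_bg from the
    calibrated background law; weighted volumes carry the rank-one matrix
    (sqrt(b_nom) g + sqrt(b_ss) z)(...)^T, i.e. nominal weighting plus
    slice-select background plus the fully correlated cross term.  SE
    volumes have no background contribution.
    """
    kind = SequenceKind(kind)
    if kind is SequenceKind.STEAM:
        if law is None:
            raise ValidationError("a BackgroundEncodingLaw is required for STEAM")
        b_bg = law.predict(encoding_time)
        if b_bg < 0:
            raise ValidationError(
                f"predicted background b is negative ({b_bg:.3f} s/mm^2)"
            )
        b_ss = law.slice_select_b
    else:
        b_bg = 0.0
        b_ss = 0.0

    vols: List[DiffusionVolume] = []
    zero = np.zeros(3)
    ref_matrix = b_bg * np.outer(_Z, _Z)
    for _ in range(n_reference):
        vols.append(
            DiffusionVolume(
                nominal_b=0.0,
                direction=zero.copy(),
                b_matrix=ref_matrix.copy(),
                is_reference=True,
            )
        )
    for g in generate_directions(n_directions, direction_seed):
        q = math.sqrt(nominal_b) * g + math.sqrt(b_ss) * _Z
        vols.append(
            DiffusionVolume(
                nominal_b=nominal_b,
                direction=g,
                b_matrix=np.outer(q, q),
                is_reference=False,
            )
        )
    return DiffusionScheme(
        volumes=tuple(vols), sequence_kind=kind, encoding_time=encoding_time
    )


def pgse_b_value(gradient: float, lobe_duration: float, separation: float) -> float:
    """Closed-form pulsed-gradient spin-echo b-value, s/mm^2.

    b = gamma^2 G^2 delta^2 (Delta - delta/3) for rectangular lobes.

    Parameters
    ----------
    gradient : mT/m
    lobe_duration : ms (delta)
    separation : ms (Delta)
    """
    if gradient < 0 or lobe_duration <= 0 or separation <= 0:
        raise ValidationError("gradient must be >= 0 and durations > 0")
    if lobe_duration >= separation:
        raise ValidationError("lobe_duration must be smaller than separation")
    g_t_per_m = gradient * 1e-3
    delta_s = lobe_duration * 1e-3
    sep_s = separation * 1e-3
    q = GYROMAGNETIC_RATIO * g_t_per_m * delta_s  # rad / m
    b_per_m2 = q * q * (sep_s - delta_s / 3.0)  # s / m^2
    return b_per_m2 * 1e-6  # s / mm^2


def _bval_path(prefix: Union[str, Path]) -> Tuple[Path, Path]:
    prefix = Path(prefix)
    return prefix.with_suffix(".bval"), prefix.with_suffix(".bvec")


def write_bval_bvec(prefix: Union[str, Path], scheme: DiffusionScheme) -> None:
    """Write FSL-dialect .bval/.bvec files.

    One whitespace-separated row of b-values (the effective traces) and
    three rows of direction components; reference volumes get a zero
    direction vector.
    """
    bval_path, bvec_path = _bval_path(prefix)
    bvals = scheme.effective_bvals
    dirs = scheme.directions
    bval_path.write_text(" ".join(f"{b:.6f}" for b in bvals) + "\n")
    lines = [
        " ".join(f"{dirs[j, axis]:.9f}" for j in range(len(scheme)))
        for axis in range(3)
    ]
    bvec_path.write_text("\n".join(lines) + "\n")


def _parse_rows(text: str, path: Path) -> List[List[float]]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise ValidationError(f"{path}, line {lineno}: non-numeric token") from exc
    return rows


def read_bval_bvec(prefix: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray]:
    """Read FSL .bval/.bvec; returns (bvals (N,), bvecs (N, 3))."""
    bval_path, bvec_path = _bval_path(prefix)
    bval_rows = _parse_rows(bval_path.read_text(), bval_path)
    if len(bval_rows) != 1:
        raise ValidationError(f"{bval_path}: expected a single row of b-values")
    bvals = np.array(bval_rows[0])
    bvec_rows = _parse_rows(bvec_path.read_text(), bvec_path)
    if len(bvec_rows) != 3:
        raise ValidationError(f"{bvec_path}: expected exactly 3 rows, "
                              f"found {len(bvec_rows)}")
    lengths = {len(r) for r in bvec_rows}
    if len(lengths) != 1:
        raise ValidationError(f"{bvec_path}: ragged rows")
    bvecs = np.array(bvec_rows).T
    if bvecs.shape[0] != bvals.size:
        raise ValidationError(
            f"{bvec_path}: {bvecs.shape[0]} directions but {bvals.size} b-values"
        )
    return bvals, bvecs
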