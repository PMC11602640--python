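"""Log-linear diffusion-tensor estimation and derived scalar/vector maps.

Per voxel the model is ln S_j = ln s0 - B_j : D with B_j the full 3x3
b-matrix of volume j (so background and cross terms are absorbed exactly,
not approximated by a scalar b-value).  The default estimator is one-step
reweighted least squares: an ordinary least-squares pass in log space,
then one weighted pass with weights equal to the squared predicted signal,
which undoes the noise amplification of the log transform at low signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .encoding import DiffusionScheme
from .errors import ValidationError

__all__ = ["TensorField", "TensorMetrics", "fit_tensor", "tensor_metrics", "color_fa"]

# design columns multiply the 6 independent tensor components
_OFFDIAG_FACTOR = 2.0


def _design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    b = scheme.b_matrices
    cols = np.column_stack([
        b[:, 0, 0], b[:, 1, 1], b[:, 2, 2],
        _OFFDIAG_FACTOR * b[:, 0, 1],
        _OFFDIAG_FACTOR * b[:, 0, 2],
        _OFFDIAG_FACTOR * b[:, 1, 2],
    ])
    return np.column_stack([np.ones(len(scheme)), -cols])


def _unpack(components: np.ndarray) -> np.ndarray:
    """(n, 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (n, 3, 3) symmetric."""
    d = np.zeros(components.shape[:-1] + (3, 3))
    d[..., 0, 0] = components[..., 0]
    d[..., 1, 1] = components[..., 1]
    d[..., 2, 2] = components[..., 2]
    d[..., 0, 1] = d[..., 1, 0] = components[..., 3]
    d[..., 0, 2] = d[..., 2, 0] = components[..., 4]
    d[..., 1, 2] = d[..., 2, 1] = components[..., 5]
    return d


@dataclass(frozen=True)
class TensorField:
    """Fitted per-voxel tensors (mm^2/s) on the image grid."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    s0: np.ndarray  # (nx, ny, nz)
    mask: np.ndarray  # fitted voxels
    flagged: np.ndarray  # voxels excluded for nonpositive signal


def fit_tensor(
    series: np.ndarray,
    scheme: DiffusionScheme,
    mask: np.ndarray,
    method: Literal["ols", "wls"] = "wls",
) -> TensorField:
    """Least-squares tensor fit of a 4-D series within a mask.

    Voxels with any nonpositive signal are flagged and left unfitted.
    Raises if the scheme is rank deficient (fewer than 6 independent
    encoding directions) or the volume counts disagree.
    """
    if method not in ("ols", "wls"):
        raise ValidationError(f"unknown method {method!r}")
    series = np.asarray(series)
    if series.shape[-1] != len(scheme):
        raise ValidationError(
            f"series has {series.shape[-1]} volumes but scheme {len(scheme)}"
        )
    if len(scheme) < 7:
        raise ValidationError("need at least 7 volumes to fit a tensor")
    x = _design_matrix(scheme)
    if np.linalg.matrix_rank(x) < 7:
        raise ValidationError(
            "rank-deficient encoding: fewer than 6 independent directions"
        )
    mask = np.asarray(mask, dtype=bool)
    signals = series[mask]  # (n_vox, n_vol)
    good = (signals > 0).all(axis=1)
    if not good.any():
        raise ValidationError("all masked voxels have nonpositive signals")
    y = np.log(signals[good])

    beta = np.linalg.lstsq(x, y.T, rcond=None)[0].T  # (n_good, 7)
    if method == "wls":
        w = np.exp(2.0 * (beta @ x.T))  # squared predicted signal
        xtwx = np.einsum("ji,vj,jk->vik", x, w, x)
        xtwy = np.einsum("ji,vj,vj->vi", x, w, y)
        beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]

    grid = mask.shape
    tensors = np.zeros(grid + (3, 3))
    s0 = np.zeros(grid)
    fitted = np.zeros(grid, dtype=bool)
    flagged = np.zeros(grid, dtype=bool)
    idx = np.flatnonzero(mask.ravel())
    fit_idx, flag_idx = idx[good], idx[~good]
    tensors.reshape(-1, 3, 3)[fit_idx] = _unpack(beta[:, 1:])
    s0.reshape(-1)[fit_idx] = np.exp(beta[:, 0])
    fitted.reshape(-1)[fit_idx] = True
    flagged.reshape(-1)[flag_idx] = True
    return TensorField(tensors=tensors, s0=s0, mask=fitted, flagged=flagged)


@dataclass(frozen=True)
class TensorMetrics:
    fa: np.ndarray  # (nx, ny, nz), in [0, 1]
    md: np.ndarray  # mm^2/s
    eigenvalues: np.ndarray  # (nx, ny, nz, 3) sorted descending
    primary_eigenvector: np.ndarray  # (nx, ny, nz, 3)
    rgb: np.ndarray  # |e1| * FA
    mask: np.ndarray
    negative_eigenvalue: np.ndarray  # voxels where clamping occurred


def tensor_metrics(field: TensorField) -> TensorMetrics:
    """FA/MD/eigensystem maps from a fitted tensor field.

    FA = sqrt(3/2) * sqrt(sum (lambda_i - MD)^2 / sum lambda_i^2); negative
    eigenvalues are clamped to zero for the metric computation and the
    voxel flagged.  An all-zero tensor maps to FA = 0.
    """
    grid = field.mask.shape
    fa = np.zeros(grid)
    md = np.zeros(grid)
    evals = np.zeros(grid + (3,))
    e1 = np.zeros(grid + (3,))
    if field.mask.any():
        d = field.tensors[field.mask]
        lam, vec = np.linalg.eigh(d)  # ascending
        neg = lam < 0
        lam_clamped = np.where(neg, 0.0, lam)
        lam_sorted = lam_clamped[:, ::-1]
        v1 = vec[:, :, -1]  # eigenvector of the largest eigenvalue
        mean = lam_sorted.mean(axis=1)
        num = ((lam_sorted - mean[:, None]) ** 2).sum(axis=1)
        den = (lam_sorted**2).sum(axis=1)
        fa_v = np.zeros(len(d))
        nz = den > 0
        fa_v[nz] = np.sqrt(1.5 * num[nz] / den[nz])
        fa[field.mask] = fa_v
        md[field.mask] = mean
        evals[field.mask] = lam_sorted
        e1[field.mask] = v1
        negmask = np.zeros(grid, dtype=bool)
        negmask[field.mask] = neg.any(axis=1)
    else:
        negmask = np.zeros(grid, dtype=bool)
    rgb = np.clip(np.abs(e1) * fa[..., None], 0.0, 1.0)
    return TensorMetrics(
        fa=fa, md=md, eigenvalues=evals, primary_eigenvector=e1,
        rgb=rgb, mask=field.mask.copy(), negative_eigenvalue=negmask,
    )


def color_fa(metrics: TensorMetrics) -> np.ndarray:
    """Direction-encoded color map: channel c = |e1_c| * FA, in [0, 1]."""
    return np.clip(
        np.abs(metrics.primary_eigenvector) * metrics.fa[..., None], 0.0, 1.0
    )
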