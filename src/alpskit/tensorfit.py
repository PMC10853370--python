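"""Per-voxel diffusion-tensor estimation and derived scalar maps.

The tensor is estimated by ordinary least squares on log-signals
(log-linear fit), which inverts the monoexponential signal model

    S_i = S0 * exp(-b_i * g_i' D g_i)

exactly on noiseless data. Derived maps are fractional anisotropy (FA),
mean diffusivity (MD), the principal diffusion direction, the color-coded
FA map, and the axis-wise diffusivities Dxx/Dyy/Dzz — the inputs the ALPS
index consumes. Dxx/Dyy/Dzz are tensor *diagonal elements in the image
frame*, not eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gradients import GradientScheme

__all__ = [
    "TensorField",
    "ScalarMaps",
    "TensorFitResult",
    "design_matrix",
    "fit_tensor_loglinear",
    "tensor_metrics",
    "diffusivity_maps",
]

# storage order of the six unique tensor elements
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


def _default_affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


@dataclass
class TensorField:
    """Voxel grid of symmetric diffusion tensors.

    Parameters
    ----------
    d : (nx, ny, nz, 6) array
        Unique tensor elements in mm²/s, ordered Dxx, Dyy, Dzz, Dxy, Dxz,
        Dyz (symmetry is structural: only six elements are stored).
    voxel_size : float
        Isotropic voxel edge in mm.
    affine : (4, 4) array, optional
        Voxel-index → mm mapping; defaults to ``diag(voxel_size)`` with the
        first voxel center at the origin.
    s0 : array, optional
        Baseline (b=0) signal map.
    """

    d: np.ndarray
    voxel_size: float = 2.0
    affine: Optional[np.ndarray] = None
    s0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 4 or self.d.shape[-1] != 6:
            raise ValueError("tensor field must have shape (nx, ny, nz, 6)")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.d.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric (..., 3, 3) tensors."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.d, -1, 0)
        m = np.empty(self.d.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = dxx
        m[..., 1, 1] = dyy
        m[..., 2, 2] = dzz
        m[..., 0, 1] = m[..., 1, 0] = dxy
        m[..., 0, 2] = m[..., 2, 0] = dxz
        m[..., 1, 2] = m[..., 2, 1] = dyz
        return m

    @classmethod
    def from_matrices(
        cls, m: np.ndarray, voxel_size: float = 2.0, affine=None, s0=None
    ) -> "TensorField":
        m = np.asarray(m, dtype=float)
        d = np.stack(
            [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
             m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
            axis=-1,
        )
        return cls(d=d, voxel_size=voxel_size, affine=affine, s0=s0)


@dataclass
class ScalarMaps:
    """FA, MD, principal direction and color-FA derived from a tensor field."""

    fa: np.ndarray                 # unitless, in [0, 1]
    md: np.ndarray                 # mm²/s
    principal_direction: np.ndarray  # (..., 3) unit vectors
    color_fa: np.ndarray           # (..., 3) RGB in [0, 1]
    valid: np.ndarray              # finite-tensor voxels


@dataclass
class TensorFitResult:
    """Fitted field plus quality-control bookkeeping."""

    field: TensorField
    n_clamped: int            # voxels whose negative eigenvalues were clamped
    invalid: np.ndarray       # in-mask voxels with unusable (all-zero) signal
    mask: np.ndarray


def design_matrix(scheme: GradientScheme, b_scale: float = 1.0) -> np.ndarray:
    """Log-linear DTI design matrix.

    Row i is ``[1, -b_i*gx², -b_i*gy², -b_i*gz², -2b_i*gx*gy, -2b_i*gx*gz,
    -2b_i*gy*gz]`` mapping the unknowns (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz) to log-signals.

    ``b_scale`` divides the b-values; the solver passes ``max(b)`` so the
    tensor columns are O(1) and the system is well conditioned (the
    recovered tensor is then rescaled). ``b_scale=1`` gives the raw
    SI-units matrix.
    """
    b = scheme.bvals / float(b_scale)
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )
    X = np.column_stack([np.ones(scheme.n), -b[:, None] * cols])
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient scheme is rank deficient: tensor not identifiable")
    return X


def fit_tensor_loglinear(
    signals: np.ndarray,
    scheme: GradientScheme,
    mask: Optional[np.ndarray] = None,
    voxel_size: float = 2.0,
    affine: Optional[np.ndarray] = None,
) -> TensorFitResult:
    """Ordinary least squares tensor fit on log-signals, per voxel.

    Parameters
    ----------
    signals : (nx, ny, nz, N) array
        DWI signal; N must match the scheme length.
    mask : (nx, ny, nz) bool array, optional
        Voxels to fit; outside voxels are zeroed. Defaults to all voxels.

    Notes
    -----
    Signals ≤ 0 (possible under magnitude noise) are floored to a tiny
    positive value before the log. Negative eigenvalues of the fitted
    tensor are clamped to zero and the affected voxel count reported;
    in-mask voxels with no usable signal at all are flagged invalid and
    excluded from downstream ROI means.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 4 or signals.shape[-1] != scheme.n:
        raise ValueError(
            f"signals shape {signals.shape} does not match scheme length {scheme.n}"
        )
    shape = signals.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match signal grid")

    b_scale = float(scheme.bvals.max())
    X = design_matrix(scheme, b_scale=b_scale)
    pinv = np.linalg.pinv(X)  # (7, N)

    vox = signals[mask]  # (M, N)
    invalid_rows = np.all(vox <= 0, axis=1)
    floor = np.finfo(float).tiny ** 0.5
    logs = np.log(np.maximum(vox, floor))
    coefs = logs @ pinv.T  # (M, 7)

    d = np.zeros(shape + (6,), dtype=float)
    d[mask] = coefs[:, 1:] / b_scale
    d[mask & _scatter(invalid_rows, mask, shape)] = 0.0

    s0 = np.zeros(shape)
    s0[mask] = np.exp(coefs[:, 0])

    field = TensorField(d=d, voxel_size=voxel_size, affine=affine, s0=s0)
    n_clamped = _clamp_negative_eigenvalues(field, mask)

    invalid = _scatter(invalid_rows, mask, shape)
    field.d[invalid] = 0.0
    return TensorFitResult(field=field, n_clamped=n_clamped, invalid=invalid, mask=mask)


def _scatter(rows: np.ndarray, mask: np.ndarray, shape: tuple) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    out[mask] = rows
    return out


def _clamp_negative_eigenvalues(field: TensorField, mask: np.ndarray) -> int:
    """Clamp negative eigenvalues to 0 in place; return affected voxel count."""
    m = field.as_matrices()[mask]
    evals = np.linalg.eigvalsh(m)
    bad = evals[:, 0] < 0  # ascending order: smallest first
    n_bad = int(bad.sum())
    if n_bad:
        w, v = np.linalg.eigh(m[bad])
        w = np.clip(w, 0.0, None)
        fixed = np.einsum("...ij,...j,...kj->...ik", v, w, v)
        m[bad] = fixed
        full = field.as_matrices()
        full[mask] = m
        field.d = TensorField.from_matrices(full).d
    return n_bad


def tensor_metrics(field: TensorField, valid: Optional[np.ndarray] = None) -> ScalarMaps:
    """Eigen-decomposition scalar maps: FA, MD, principal direction, color FA.

    FA = sqrt(3/2) * ||λ - λ̄|| / ||λ||; MD = mean eigenvalue. The principal
    eigenvector sign is canonicalized so its largest-magnitude component is
    non-negative; color FA is |principal direction| * FA per RGB channel.
    Non-finite tensors are flagged invalid and zeroed in every map.
    """
    m = field.as_matrices()
    finite = np.all(np.isfinite(m), axis=(-2, -1))
    if valid is not None:
        finite = finite & valid
    safe = np.where(finite[..., None, None], m, np.eye(3))
    evals, evecs = np.linalg.eigh(safe)

    md = evals.mean(axis=-1)
    dev = evals - md[..., None]
    num = np.sqrt((dev * dev).sum(axis=-1))
    den = np.sqrt((evals * evals).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    pd = evecs[..., :, 2]  # eigenvector of the largest eigenvalue
    idx = np.argmax(np.abs(pd), axis=-1, keepdims=True)
    sign = np.sign(np.take_along_axis(pd, idx, axis=-1))
    sign = np.where(sign == 0, 1.0, sign)
    pd = pd * sign

    color = np.abs(pd) * fa[..., None]

    for arr in (fa, md):
        arr[~finite] = 0.0
    pd[~finite] = 0.0
    color[~finite] = 0.0
    return ScalarMaps(fa=fa, md=md, principal_direction=pd,
                      color_fa=np.clip(color, 0.0, 1.0), valid=finite)


def diffusivity_maps(field: TensorField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axis-wise diffusivities (Dxx, Dyy, Dzz): the tensor diagonal in the
    image frame. These are not eigenvalues — for a tensor whose principal
    axis is oblique to the grid, Dxx differs from the largest eigenvalue."""
    return field.d[..., 0].copy(), field.d[..., 1].copy(), field.d[..., 2].copy()
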