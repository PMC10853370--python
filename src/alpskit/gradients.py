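"""Diffusion-sensitizing gradient schemes.

A :class:`GradientScheme` couples b-values (s/mm²) with unit gradient
directions and is shared by the signal simulator and the tensor fitter, so
both sides of the pipeline agree bit-for-bit on the acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GradientScheme", "fibonacci_directions", "make_gradient_scheme"]

_UNIT_NORM_TOL = 1e-8


@dataclass(frozen=True)
class GradientScheme:
    """b-values and unit gradient directions of a DWI acquisition.

    Parameters
    ----------
    bvals : (N,) array of b-values in s/mm². At least one must be 0.
    bvecs : (N, 3) array of direction cosines. Rows with b > 0 must be unit
        norm; rows with b = 0 must be the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvals/bvecs shape mismatch: {bvals.shape} vs {bvecs.shape}"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dwi = bvals > 0
        if not np.any(~dwi):
            raise ValueError("scheme needs at least one b=0 entry")
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(np.abs(norms[dwi] - 1.0) > _UNIT_NORM_TOL):
            raise ValueError("b>0 gradient directions must be unit norm")
        if np.any(norms[~dwi] > _UNIT_NORM_TOL):
            raise ValueError("b=0 entries must carry the zero vector")
        if dwi.sum() < 6:
            raise ValueError(
                "tensor identifiability requires >= 6 b>0 directions, "
                f"got {int(dwi.sum())}"
            )

    @property
    def n(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors on the sphere.

    Spherical Fibonacci lattice: point k sits at height
    z_k = 1 - (2k+1)/n and azimuth k times the golden angle pi*(3-sqrt(5)).
    Reproducible bit-for-bit for a given ``n``.
    """
    if n < 1:
        raise ValueError("need n >= 1 directions")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = k * np.pi * (3.0 - np.sqrt(5.0))
    vecs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def make_gradient_scheme(n_directions: int, b: float = 1000.0) -> GradientScheme:
    """Build the default single-shell scheme: one b=0 plus ``n_directions``
    Fibonacci-lattice directions at b-value ``b`` (s/mm²).

    Raises
    ------
    ValueError
        If ``n_directions`` < 6 (the tensor would not be identifiable).
    """
    if n_directions < 6:
        raise ValueError(
            "tensor identifiability requires >= 6 directions, "
            f"got {n_directions}"
        )
    if b <= 0:
        raise ValueError("shell b-value must be positive")
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros(3), fibonacci_directions(n_directions)])
    return GradientScheme(bvals=bvals, bvecs=bvecs)
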