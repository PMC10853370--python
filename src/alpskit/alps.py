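"""ALPS index from spherical ROIs on axis-wise diffusivity maps.

The index quantifies diffusivity along the perivascular (x) axis relative
to diffusivity perpendicular to the fibers:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

computed per hemisphere from 5 mm spherical ROIs in the projection- and
association-fiber areas; the wholebrain value is the mean of the two
hemispheres. Values near 1 mean no preferential perivascular diffusion;
lower values indicate poorer presumed glymphatic transport.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "Sphere",
    "RoiSet",
    "HemisphereAlps",
    "AlpsResult",
    "sphere_mask",
    "extract_roi_means",
    "alps_index",
    "alps_bilateral",
]

HEMISPHERES = ("left", "right")
REGIONS = ("projection", "association")


@dataclass(frozen=True)
class Sphere:
    center: Tuple[float, float, float]  # mm
    diameter: float = 5.0               # mm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("sphere diameter must be positive")


@dataclass
class RoiSet:
    """The four analysis spheres: {left, right} x {projection, association}."""

    spheres: Dict[Tuple[str, str], Sphere]

    def __post_init__(self) -> None:
        expected = {(h, r) for h in HEMISPHERES for r in REGIONS}
        if set(self.spheres) != expected:
            raise ValueError(f"RoiSet needs exactly the spheres {sorted(expected)}")

    @classmethod
    def from_centers(
        cls, centers: Dict[Tuple[str, str], Tuple[float, float, float]],
        diameter: float = 5.0,
    ) -> "RoiSet":
        return cls({k: Sphere(tuple(c), diameter) for k, c in centers.items()})

    def to_json(self) -> str:
        return json.dumps(
            {
                f"{h}:{r}": {"center_mm": list(s.center), "diameter_mm": s.diameter}
                for (h, r), s in self.spheres.items()
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RoiSet":
        d = json.loads(text)
        spheres = {}
        for key, v in d.items():
            h, r = key.split(":")
            spheres[(h, r)] = Sphere(tuple(v["center_mm"]), v["diameter_mm"])
        return cls(spheres)


@dataclass
class HemisphereAlps:
    """ROI-mean diffusivities (mm²/s) and the ALPS index of one hemisphere."""

    dx_proj: float
    dy_proj: float
    dx_assoc: float
    dz_assoc: float
    alps: float
    voxel_counts: Dict[str, int] = field(default_factory=dict)


@dataclass
class AlpsResult:
    left: HemisphereAlps
    right: HemisphereAlps
    wholebrain: float

    def to_dict(self) -> dict:
        return asdict(self)


def _voxel_coords_mm(shape, affine) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def sphere_mask(
    center, diameter: float, shape, affine: Optional[np.ndarray] = None,
    voxel_size: float = 2.0,
) -> np.ndarray:
    """Voxels whose *centers* lie within the closed ball.

    The closed-ball voxel-center rule is the discretization contract: a
    5 mm sphere on a 2 mm grid centered on a voxel center selects exactly
    7 voxels (the center and its six face neighbors).

    Raises
    ------
    ValueError
        If the sphere extends outside the image or selects no voxel.
    """
    if affine is None:
        affine = np.diag([voxel_size] * 3 + [1.0])
    center = np.asarray(center, dtype=float)
    radius = diameter / 2.0
    inv = np.linalg.inv(affine)
    c_vox = inv[:3, :3] @ center + inv[:3, 3]
    scale = np.linalg.norm(inv[:3, :3], axis=1)  # mm -> voxel units per axis
    lo = c_vox - radius * scale
    hi = c_vox + radius * scale
    if np.any(lo < -0.5) or np.any(hi > np.asarray(shape) - 0.5):
        raise ValueError(f"sphere at {center.tolist()} extends outside the image")
    coords = _voxel_coords_mm(shape, affine)
    d2 = ((coords - center) ** 2).sum(axis=-1)
    mask = d2 <= radius**2
    if not mask.any():
        raise ValueError(
            f"sphere at {center.tolist()} (diameter {diameter} mm) contains "
            "no voxel center; check placement against the voxel grid"
        )
    return mask


def extract_roi_means(
    dxx: np.ndarray,
    dyy: np.ndarray,
    dzz: np.ndarray,
    rois: RoiSet,
    affine: Optional[np.ndarray] = None,
    voxel_size: float = 2.0,
    valid: Optional[np.ndarray] = None,
    max_invalid_fraction: float = 0.5,
) -> Dict[str, Dict[str, float]]:
    """Arithmetic ROI means of the axis-wise diffusivities.

    Per hemisphere, returns Dxx in the projection ROI (``dx_proj``), Dyy
    there (``dy_proj``), Dxx in the association ROI (``dx_assoc``) and Dzz
    there (``dz_assoc``), plus the voxel counts used. Voxels flagged
    invalid are excluded; an ROI whose invalid fraction exceeds
    ``max_invalid_fraction`` raises a quality-control error.
    """
    shape = dxx.shape
    if dyy.shape != shape or dzz.shape != shape:
        raise ValueError("diffusivity maps must share one grid")
    out: Dict[str, Dict[str, float]] = {}
    for h in HEMISPHERES:
        masks = {}
        for r in REGIONS:
            s = rois.spheres[(h, r)]
            m = sphere_mask(s.center, s.diameter, shape, affine, voxel_size)
            n_total = int(m.sum())
            if valid is not None:
                m = m & valid
            n_used = int(m.sum())
            if n_used < n_total * (1.0 - max_invalid_fraction) or n_used == 0:
                raise ValueError(
                    f"ROI ({h}, {r}): {n_total - n_used}/{n_total} voxels "
                    "invalid — exceeds the quality-control limit"
                )
            masks[r] = (m, n_used)
        proj_m, n_proj = masks["projection"]
        assoc_m, n_assoc = masks["association"]
        out[h] = {
            "dx_proj": float(dxx[proj_m].mean()),
            "dy_proj": float(dyy[proj_m].mean()),
            "dx_assoc": float(dxx[assoc_m].mean()),
            "dz_assoc": float(dzz[assoc_m].mean()),
            "n_proj": n_proj,
            "n_assoc": n_assoc,
        }
    return out


def alps_index(dx_proj: float, dx_assoc: float, dy_proj: float, dz_assoc: float) -> float:
    """mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    vals = (dx_proj, dx_assoc, dy_proj, dz_assoc)
    if any(v <= 0 for v in vals):
        raise ValueError(f"ALPS inputs must be positive, got {vals}")
    return (dx_proj + dx_assoc) / (dy_proj + dz_assoc)


def alps_bilateral(
    dxx: np.ndarray,
    dyy: np.ndarray,
    dzz: np.ndarray,
    rois: RoiSet,
    affine: Optional[np.ndarray] = None,
    voxel_size: float = 2.0,
    valid: Optional[np.ndarray] = None,
) -> AlpsResult:
    """Left, right, and wholebrain ALPS from one subject's maps.

    Hemispheres are computed independently; wholebrain is their mean.
    """
    means = extract_roi_means(dxx, dyy, dzz, rois, affine, voxel_size, valid)
    hemis = {}
    for h in HEMISPHERES:
        m = means[h]
        idx = alps_index(m["dx_proj"], m["dx_assoc"], m["dy_proj"], m["dz_assoc"])
        hemis[h] = HemisphereAlps(
            dx_proj=m["dx_proj"],
            dy_proj=m["dy_proj"],
            dx_assoc=m["dx_assoc"],
            dz_assoc=m["dz_assoc"],
            alps=idx,
            voxel_counts={"projection": m["n_proj"], "association": m["n_assoc"]},
        )
    return AlpsResult(
        left=hemis["left"],
        right=hemis["right"],
        wholebrain=0.5 * (hemis["left"].alps + hemis["right"].alps),
    )
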