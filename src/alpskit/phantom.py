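"""Synthetic DWI phantoms with known ground-truth ALPS.

The phantom reproduces the geometric premise of the ALPS method at the
level of the lateral ventricle body: projection fibers run
inferior–superior (z), association fibers anterior–posterior (y), and the
perivascular space left–right (x), perpendicular to both. Each fiber
region is a homogeneous sphere carrying a diagonal tensor; the background
is isotropic. Because region tensors are diagonal and axis-aligned, the
ground-truth ALPS index of every subject is available in closed form, so
the whole estimation pipeline can be validated against known truth.

Glymphatic impairment is modelled as a multiplicative attenuation of the
x-axis diffusivity inside the projection and association regions — the
component the ALPS numerator averages — lowering the index exactly the
way reduced perivascular diffusivity would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .gradients import GradientScheme, make_gradient_scheme
from .tensorfit import TensorField

__all__ = [
    "PhantomSpec",
    "CohortSimSpec",
    "DWIStudy",
    "GROUPS",
    "build_tensor_field",
    "simulate_dwi",
    "simulate_cohort",
    "iter_cohort",
    "simulate_cohort_table",
    "ground_truth_alps",
    "default_phantom_spec",
    "small_phantom_spec",
    "default_cohort_spec",
]

GROUPS = ("pre-RT", "post-RT-RE-", "post-RT-RE+")

HEMISPHERES = ("left", "right")
REGIONS = ("projection", "association")

_D_MAX = 4e-3  # physical water diffusivity ceiling, mm²/s


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of one synthetic subject.

    ``region_centers`` maps ``(hemisphere, region)`` to a 3-vector in mm;
    each region is a sphere of ``region_radius`` mm carrying the diagonal
    tensor of its fiber population. Diffusivities are mm²/s, signals are
    arbitrary units, ``noise_sigma`` is the per-channel Gaussian sigma of
    the Rician noise model (SNR = s0 / noise_sigma).
    """

    grid_shape: Tuple[int, int, int] = (32, 32, 20)
    voxel_size: float = 2.0
    region_centers: Dict[Tuple[str, str], Tuple[float, float, float]] = field(
        default_factory=lambda: {
            ("left", "projection"): (20.0, 26.0, 20.0),
            ("left", "association"): (20.0, 40.0, 20.0),
            ("right", "projection"): (44.0, 26.0, 20.0),
            ("right", "association"): (44.0, 40.0, 20.0),
        }
    )
    region_radius: float = 6.0
    projection_diag: Tuple[float, float, float] = (1.0e-3, 0.7e-3, 1.7e-3)
    association_diag: Tuple[float, float, float] = (1.0e-3, 1.7e-3, 0.7e-3)
    background_diffusivity: float = 0.8e-3
    s0: float = 1000.0
    noise_sigma: float = 1000.0 / 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        diffs = (*self.projection_diag, *self.association_diag,
                 self.background_diffusivity)
        if not all(0.0 < d < _D_MAX for d in diffs):
            raise ValueError(
                f"diffusivities must lie in (0, {_D_MAX}) mm²/s, got {diffs}"
            )
        if self.projection_diag[2] != max(self.projection_diag):
            raise ValueError("projection tensor must be largest along z")
        if self.association_diag[1] != max(self.association_diag):
            raise ValueError("association tensor must be largest along y")
        if self.s0 < 0 or self.noise_sigma < 0:
            raise ValueError("s0 and noise_sigma must be non-negative")
        if set(self.region_centers) != {
            (h, r) for h in HEMISPHERES for r in REGIONS
        }:
            raise ValueError("region_centers must cover {left,right}x{projection,association}")
        extent = np.asarray(self.grid_shape) * self.voxel_size
        for key, c in self.region_centers.items():
            c = np.asarray(c, dtype=float)
            if np.any(c - self.region_radius < -self.voxel_size / 2) or np.any(
                c + self.region_radius > extent - self.voxel_size / 2
            ):
                raise ValueError(f"region sphere {key} extends outside the grid")

    def region_diag(self, region: str) -> np.ndarray:
        return np.asarray(
            self.projection_diag if region == "projection" else self.association_diag,
            dtype=float,
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["region_centers"] = {f"{h}:{r}": list(v) for (h, r), v in
                               self.region_centers.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["region_centers"] = {
            tuple(k.split(":")): tuple(v) for k, v in d["region_centers"].items()
        }
        d["grid_shape"] = tuple(d["grid_shape"])
        d["projection_diag"] = tuple(d["projection_diag"])
        d["association_diag"] = tuple(d["association_diag"])
        return cls(**d)


@dataclass
class CohortSimSpec:
    """Three-group cohort layout with a planted glymphatic effect.

    ``attenuations`` multiplies the x-axis diffusivity inside the
    projection and association regions per group; 1.0 means no impairment.
    ``between_subject_cv`` is the coefficient of variation of the
    multiplicative per-subject, per-region, per-axis tissue variability.
    The dose model draws an ipsilateral maximum radiotherapy dose (MDRT,
    Gy) for post-RT subjects and couples it negatively to the subject's
    x-attenuation with slope ``dose_slope`` (attenuation units per dose
    SD), planting a recoverable negative dose–ALPS correlation.
    """

    group_sizes: Tuple[int, int, int] = (35, 58, 16)
    attenuations: Tuple[float, float, float] = (1.0, 0.85, 0.70)
    between_subject_cv: float = 0.05
    dose_mean: float = 67.0
    dose_sd: float = 7.6
    dose_slope: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValueError("each of the three groups needs n >= 2")
        if any(not 0.0 < a <= 1.0 for a in self.attenuations):
            raise ValueError("attenuations must lie in (0, 1]")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSimSpec":
        d = json.loads(text)
        d["group_sizes"] = tuple(d["group_sizes"])
        d["attenuations"] = tuple(d["attenuations"])
        return cls(**d)


@dataclass
class DWIStudy:
    """One subject's 4-D DWI volume plus its acquisition scheme and mask."""

    signals: np.ndarray            # (nx, ny, nz, N)
    scheme: GradientScheme
    mask: np.ndarray               # (nx, ny, nz) bool
    voxel_size: float
    affine: np.ndarray
    subject_id: str = ""


# ---------------------------------------------------------------------------
# field construction


def _voxel_centers_mm(shape, voxel_size) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = [np.arange(n) * voxel_size for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def region_masks(spec: PhantomSpec) -> Dict[Tuple[str, str], np.ndarray]:
    """Boolean voxel masks of the four fiber-region spheres (disjoint)."""
    xs, ys, zs = _voxel_centers_mm(spec.grid_shape, spec.voxel_size)
    masks = {}
    for key, c in spec.region_centers.items():
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        masks[key] = d2 <= spec.region_radius**2
    keys = list(masks)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"region spheres {a} and {b} overlap")
    return masks


def build_tensor_field(
    spec: PhantomSpec,
    region_diags: Optional[Dict[Tuple[str, str], np.ndarray]] = None,
    masks: Optional[Dict[Tuple[str, str], np.ndarray]] = None,
) -> Tuple[TensorField, Dict[Tuple[str, str], np.ndarray]]:
    """Materialize the phantom tensor field.

    ``region_diags`` optionally overrides the per-region diagonal (used by
    the cohort simulator to inject per-subject variability); ``masks``
    lets callers reuse precomputed geometry across subjects.
    """
    spec.validate()
    if masks is None:
        masks = region_masks(spec)
    d = np.zeros(tuple(spec.grid_shape) + (6,), dtype=float)
    d[..., :3] = spec.background_diffusivity
    for (hemi, region), mask in masks.items():
        diag = (
            region_diags[(hemi, region)]
            if region_diags is not None
            else spec.region_diag(region)
        )
        d[mask, :3] = np.asarray(diag, dtype=float)
    field = TensorField(d=d, voxel_size=spec.voxel_size)
    return field, masks


def ground_truth_alps(diags: Dict[Tuple[str, str], np.ndarray]) -> Dict[str, float]:
    """Closed-form ALPS from the configured region diagonals.

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc), per
    hemisphere; wholebrain is the mean of the two.
    """
    out = {}
    for h in HEMISPHERES:
        proj = np.asarray(diags[(h, "projection")], dtype=float)
        assoc = np.asarray(diags[(h, "association")], dtype=float)
        out[h] = float((proj[0] + assoc[0]) / (proj[1] + assoc[2]))
    out["wholebrain"] = 0.5 * (out["left"] + out["right"])
    return out


# ---------------------------------------------------------------------------
# signal simulation


def simulate_dwi(
    field: TensorField,
    scheme: GradientScheme,
    s0: float,
    sigma: float,
    seed: int,
    mask: Optional[np.ndarray] = None,
    subject_id: str = "",
) -> DWIStudy:
    """Monoexponential tensor signal with Rician noise.

    Noiseless signal per voxel and volume is ``S = s0 * exp(-b g' D g)``;
    Rician noise is the magnitude of ``(S + N(0, σ²)) + i N(0, σ²)``. The
    seed fully determines the output.
    """
    if s0 < 0 or sigma < 0:
        raise ValueError("s0 and sigma must be non-negative")
    b = scheme.bvals
    g = scheme.bvecs
    # g' D g expanded on the six unique elements
    quad = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    )  # (N, 6)
    adc = field.d @ quad.T  # (nx, ny, nz, N)
    signal = s0 * np.exp(-b * adc)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        real = signal + rng.normal(0.0, sigma, signal.shape)
        imag = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt(real * real + imag * imag)
    if mask is None:
        mask = np.ones(field.shape, dtype=bool)
    return DWIStudy(
        signals=signal,
        scheme=scheme,
        mask=mask,
        voxel_size=field.voxel_size,
        affine=field.affine,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# cohort simulation


def _subject_params(
    spec: CohortSimSpec, phantom: PhantomSpec, rng: np.random.Generator
) -> Iterator[dict]:
    """Draw per-subject tissue parameters, dose covariates and truth ALPS."""
    sid = 0
    for group, n, atten in zip(GROUPS, spec.group_sizes, spec.attenuations):
        for _ in range(n):
            doses = {}
            diags = {}
            for h in HEMISPHERES:
                if group == "pre-RT":
                    dose = np.nan
                    z = 0.0
                else:
                    z = rng.standard_normal()
                    dose = spec.dose_mean + spec.dose_sd * z
                doses[h] = dose
                # per-hemisphere attenuation: group base, subject noise,
                # negative coupling to ipsilateral dose
                a = atten * (
                    1.0 + spec.between_subject_cv * rng.standard_normal()
                ) - spec.dose_slope * z
                a = float(np.clip(a, 0.05, 1.0))
                for r in REGIONS:
                    base = phantom.region_diag(r)
                    fac = 1.0 + spec.between_subject_cv * rng.standard_normal(3)
                    diag = base * np.clip(fac, 0.2, None)
                    diag[0] *= a
                    diags[(h, r)] = np.clip(diag, 1e-6, _D_MAX * 0.999)
            truth = ground_truth_alps(diags)
            yield {
                "subject_id": f"sub-{sid:03d}",
                "group": group,
                "diags": diags,
                "dose_left": doses["left"],
                "dose_right": doses["right"],
                "truth_alps_left": truth["left"],
                "truth_alps_right": truth["right"],
                "truth_alps_wholebrain": truth["wholebrain"],
            }
            sid += 1


def _truth_row(p: dict, seed: int) -> dict:
    return {
        "subject_id": p["subject_id"],
        "group": p["group"],
        "seed": seed,
        "truth_alps_left": p["truth_alps_left"],
        "truth_alps_right": p["truth_alps_right"],
        "truth_alps_wholebrain": p["truth_alps_wholebrain"],
        "mdrt_left": p["dose_left"],
        "mdrt_right": p["dose_right"],
    }


def iter_cohort(
    spec: CohortSimSpec,
    phantom: PhantomSpec,
    scheme: Optional[GradientScheme] = None,
) -> Iterator[Tuple[DWIStudy, dict]]:
    """Yield one simulated subject at a time (memory-friendly).

    The master seed deterministically spawns one child seed per subject via
    ``np.random.SeedSequence``, so any subject can be regenerated alone.
    """
    if scheme is None:
        scheme = make_gradient_scheme(30, 1000.0)
    ss = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    n_total = sum(spec.group_sizes)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_total + 1)[1:]]
    masks = region_masks(phantom)
    for p, seed in zip(_subject_params(spec, phantom, param_rng), child_seeds):
        field, _ = build_tensor_field(phantom, region_diags=p["diags"], masks=masks)
        study = simulate_dwi(
            field, scheme, phantom.s0, phantom.noise_sigma, seed,
            subject_id=p["subject_id"],
        )
        yield study, _truth_row(p, seed)


def simulate_cohort(
    spec: CohortSimSpec,
    phantom: PhantomSpec,
    scheme: Optional[GradientScheme] = None,
) -> Tuple[List[DWIStudy], pd.DataFrame]:
    """Simulate the full cohort; returns studies plus the ground-truth table."""
    studies, rows = [], []
    for study, row in iter_cohort(spec, phantom, scheme):
        studies.append(study)
        rows.append(row)
    return studies, pd.DataFrame(rows)


def simulate_cohort_table(spec: CohortSimSpec, phantom: PhantomSpec) -> pd.DataFrame:
    """Ground-truth cohort table only — no imaging.

    Used for table-level calibration studies (e.g. null type-I rate over
    many replicates) where simulating and fitting volumes would add
    nothing: the between-subject variability already lives in the table.
    """
    ss = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    rows = [_truth_row(p, spec.seed) for p in _subject_params(spec, phantom, param_rng)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default configurations


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Full-size phantom: 32x32x20 voxels at 2 mm (64x64x40 mm)."""
    return PhantomSpec(**overrides)


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Reduced phantom (16x16x10 voxels) for examples and fast studies.

    Region geometry scales down; tissue parameters are unchanged, so ALPS
    ground truth is identical to the full-size phantom.
    """
    params = dict(
        grid_shape=(16, 16, 10),
        region_centers={
            ("left", "projection"): (10.0, 12.0, 10.0),
            ("left", "association"): (10.0, 20.0, 10.0),
            ("right", "projection"): (22.0, 12.0, 10.0),
            ("right", "association"): (22.0, 20.0, 10.0),
        },
        region_radius=3.0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def default_cohort_spec(**overrides) -> CohortSimSpec:
    return CohortSimSpec(**overrides)
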