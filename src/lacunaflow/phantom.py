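"""Synthetic longitudinal T1 phantom with known incident-lacune ground truth.

The phantom is a deliberately simple digital head: an ellipsoidal brain with
a dark CSF rim, a grey-matter shell and a bright white-matter core, two deep
ventricles, and a sulcal CSF channel cutting from the surface into the white
matter.  Into this anatomy it inserts, with exact voxel-level ground truth:

* *baseline lacunes* — CSF cavities present at both time points;
* *incident lacunes* — white matter at baseline that turns to CSF at
  follow-up (the signal change the pipeline detects);
* *extensions* — incident-like cavities abutting a baseline lacune;
* *perivascular confounders* — sub-3 mm incident-like signal changes
  mimicking perivascular spaces;
* *sulcal-widening confounders* — follow-up CSF appearing at the wall of a
  sulcal channel, mimicking sulcus enlargement with brain atrophy.

Follow-up CSF can additionally drift in intensity (scanner-to-scanner CSF
signal variation), and both images receive independent seeded Gaussian
noise.  Geometry depends only on the spec, never on the seed, so two seeds
give the same anatomy with different noise fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volume import BinaryMask, ImageVolume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomData",
    "rasterize_lesion",
    "generate_pair",
    "default_phantom_spec",
]

LESION_KINDS = (
    "incident",
    "baseline_lacune",
    "extension",
    "perivascular_confounder",
    "sulcal_widening_confounder",
)


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic lesion: where, how big, what kind, what shape."""

    center: tuple[int, int, int]
    diameter_mm: float
    kind: str
    shape: str = "sphere"  # sphere | ovoid
    axes_mm: tuple[float, float, float] | None = None  # ovoid semi-diameters

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.shape not in ("sphere", "ovoid"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.shape == "ovoid" and self.axes_mm is None:
            object.__setattr__(
                self, "axes_mm", (self.diameter_mm, 0.6 * self.diameter_mm, 0.6 * self.diameter_mm)
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic baseline/follow-up pair."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    csf_mean: float = 10.0
    gm_mean: float = 60.0
    wm_mean: float = 100.0
    noise_sigma: float = 2.0  # 2% of the default white-matter intensity
    csf_drift: float = 0.0
    seed: int = 0
    lesions: tuple[LesionSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if not (self.csf_mean < self.gm_mean < self.wm_mean):
            raise ValueError("need csf_mean < gm_mean < wm_mean")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomData:
    """Everything :func:`generate_pair` produces, with exact ground truth."""

    baseline: ImageVolume
    followup: ImageVolume
    brain_mask: BinaryMask
    wm_mask: BinaryMask
    ventricles: BinaryMask
    basal_ganglia: BinaryMask
    baseline_lacunes: BinaryMask
    truth: list[tuple[LesionSpec, BinaryMask]]
    marks: pd.DataFrame
    spec: PhantomSpec

    def truth_of_kind(self, kind: str) -> list[BinaryMask]:
        return [m for s, m in self.truth if s.kind == kind]


def rasterize_lesion(
    center: tuple[int, int, int],
    diameter_mm: float,
    shape: str,
    spacing: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
    axes_mm: tuple[float, float, float] | None = None,
) -> BinaryMask:
    """Voxels whose centre lies strictly inside the sphere/ovoid.

    Strict containment keeps the caliper read-out of the rasterized set
    within one voxel of the nominal diameter: a 1 mm sphere at 1 mm spacing
    is a single voxel, a 2 mm one still collapses to its centre voxel.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    spacing_arr = np.asarray(spacing, dtype=float)
    if shape == "sphere":
        semi = np.full(3, diameter_mm / 2.0)
    elif shape == "ovoid":
        semi = np.asarray(axes_mm if axes_mm is not None else (diameter_mm,) * 3) / 2.0
    else:
        raise ValueError(f"unknown lesion shape {shape!r}")
    coords = np.indices(grid_shape, dtype=float)
    offs = [
        (coords[ax] - center[ax]) * spacing_arr[ax] / semi[ax] for ax in range(3)
    ]
    inside = offs[0] ** 2 + offs[1] ** 2 + offs[2] ** 2 < 1.0
    if not inside.any():
        raise ValueError(f"lesion of diameter {diameter_mm} mm rasterizes to nothing")
    return BinaryMask(data=inside.astype(np.uint8), spacing=tuple(spacing))


def _ellipsoid_rho(grid_shape, spacing, center, semi_axes_mm) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    total = np.zeros(grid_shape, dtype=float)
    for ax in range(3):
        total += ((coords[ax] - center[ax]) * spacing[ax] / semi_axes_mm[ax]) ** 2
    return np.sqrt(total)


def _build_anatomy(spec: PhantomSpec):
    """Lesion-free anatomy: tissue label volume and the anatomical masks.

    Tissue codes: 0 background, 1 CSF, 2 GM, 3 WM.  The white-matter mask
    (which stands in for the template WM-including-basal-ganglia mask)
    excludes ventricles and the sulcal channel; ventricles are deliberately
    not connected to the surface CSF so the external CSF is the largest
    connected component.
    """
    shape = spec.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    semi = tuple(0.85 * (s - 1) / 2.0 * sp for s, sp in zip(shape, spec.spacing))
    rho = _ellipsoid_rho(shape, spec.spacing, center, semi)

    brain = rho <= 1.0
    rim = brain & (rho > 0.94)
    gm = brain & (rho > 0.84) & (rho <= 0.94)
    wm = rho <= 0.84

    # two deep ventricles, separate from the surface CSF
    cx, cy, cz = center
    vents = np.zeros(shape, dtype=bool)
    for dy in (-9.0, 9.0):
        vents |= (
            _ellipsoid_rho(
                shape, spec.spacing, (cx, cy + dy / spec.spacing[1], cz), (4.0, 8.0, 3.0)
            )
            < 1.0
        )
    vents &= rho <= 0.6  # keep them deep

    # a sulcal CSF channel cutting from the rim into the white matter
    coords = np.indices(shape, dtype=float)
    band = np.abs(coords[1] - cy) * spec.spacing[1] <= 1.0
    channel = band & (rho > 0.70) & brain & (coords[0] >= cx + 8.0 / spec.spacing[0])

    # basal ganglia: two deep nuclei inside the white matter
    bg = np.zeros(shape, dtype=bool)
    for dx in (-10.0, 10.0):
        bg |= (
            _ellipsoid_rho(
                shape, spec.spacing, (cx + dx / spec.spacing[0], cy, cz), (5.0, 5.0, 5.0)
            )
            < 1.0
        )
    bg &= wm & ~vents & ~channel

    tissue = np.zeros(shape, dtype=np.uint8)
    tissue[wm] = 3
    tissue[gm] = 2
    tissue[rim] = 1
    tissue[vents] = 1
    tissue[channel] = 1

    wm_mask = wm & ~vents & ~channel
    return tissue, brain, wm_mask, vents, bg, channel, rho


def _tissue_image(tissue: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    means = {0: 0.0, 1: spec.csf_mean, 2: spec.gm_mean, 3: spec.wm_mean}
    out = np.zeros(tissue.shape, dtype=np.float64)
    for code, mean in means.items():
        out[tissue == code] = mean
    return out


def generate_pair(spec: PhantomSpec) -> PhantomData:
    """Generate the co-registered baseline/follow-up pair with ground truth.

    Baseline lacunes are CSF at both time points; incident, extension and
    confounder lesions keep the baseline anatomy and turn to CSF on
    follow-up.  One consensus mark per incident lesion is placed at the
    truth-centroid voxel (on its axial slice, as an expert would mark it).
    """
    tissue, brain, wm_mask, vents, bg, channel, rho = _build_anatomy(spec)
    shape = spec.grid_shape

    truth: list[tuple[LesionSpec, BinaryMask]] = []
    occupied = np.zeros(shape, dtype=bool)
    for les in spec.lesions:
        mask = rasterize_lesion(
            les.center, les.diameter_mm, les.shape, spec.spacing, shape, les.axes_mm
        )
        vox = mask.as_bool()
        if not brain[vox].all():
            raise ValueError(f"lesion at {les.center} extends outside the brain")
        if (occupied & vox).any():
            raise ValueError(f"lesion at {les.center} overlaps another lesion")
        occupied |= vox
        truth.append((les, mask))

    tissue_base = tissue.copy()
    tissue_fu = tissue.copy()
    baseline_lacunes = np.zeros(shape, dtype=bool)
    for les, mask in truth:
        vox = mask.as_bool()
        if les.kind == "baseline_lacune":
            tissue_base[vox] = 1
            tissue_fu[vox] = 1
            baseline_lacunes |= vox
        else:
            # incident-like: anatomy at baseline, CSF at follow-up
            tissue_fu[vox] = 1

    base_img = _tissue_image(tissue_base, spec)
    fu_img = _tissue_image(tissue_fu, spec)
    fu_img[tissue_fu == 1] += spec.csf_drift

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        base_img = base_img + rng.normal(0.0, spec.noise_sigma, shape)
        fu_img = fu_img + rng.normal(0.0, spec.noise_sigma, shape)

    def _mask(arr: np.ndarray) -> BinaryMask:
        return BinaryMask(data=arr.astype(np.uint8), spacing=spec.spacing)

    mark_rows = []
    for les, mask in truth:
        if les.kind != "incident":
            continue
        centroid = np.argwhere(mask.as_bool()).mean(axis=0)
        mark_rows.append(
            {
                "patient_id": "phantom",
                "x": int(round(centroid[0])),
                "y": int(round(centroid[1])),
                "z": int(round(centroid[2])),
                "source": "consensus",
            }
        )
    marks = pd.DataFrame(mark_rows, columns=["patient_id", "x", "y", "z", "source"])

    return PhantomData(
        baseline=ImageVolume(data=base_img, spacing=spec.spacing),
        followup=ImageVolume(data=fu_img, spacing=spec.spacing),
        brain_mask=_mask(brain),
        wm_mask=_mask(wm_mask),
        ventricles=_mask(vents),
        basal_ganglia=_mask(bg),
        baseline_lacunes=_mask(baseline_lacunes),
        truth=truth,
        marks=marks,
        spec=spec,
    )


def default_phantom_spec(seed: int = 0, noise_sigma: float = 2.0) -> PhantomSpec:
    """The reference 96-cubed phantom exercising every pipeline gate.

    Three incident lacunes (4, 6 and 10 mm) deep in the white matter, one
    baseline lacune with a 5 mm extension abutting it, a 2 mm perivascular
    confounder and a 7 mm sulcal-widening confounder sitting on the sulcal
    channel wall.  Noise defaults to 2% of the white-matter intensity.
    """
    lesions = (
        LesionSpec(center=(30, 38, 44), diameter_mm=4.0, kind="incident"),
        LesionSpec(center=(62, 36, 40), diameter_mm=6.0, kind="incident"),
        LesionSpec(center=(48, 48, 30), diameter_mm=10.0, kind="incident"),
        LesionSpec(center=(34, 58, 52), diameter_mm=6.0, kind="baseline_lacune"),
        LesionSpec(center=(39, 58, 52), diameter_mm=5.0, kind="extension"),
        LesionSpec(center=(56, 60, 38), diameter_mm=2.0, kind="perivascular_confounder"),
        LesionSpec(center=(76, 47, 47), diameter_mm=7.0, kind="sulcal_widening_confounder"),
    )
    return PhantomSpec(seed=seed, noise_sigma=noise_sigma, lesions=lesions)
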