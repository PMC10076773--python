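"""NIfTI volume and mask containers plus tabular I/O.

Everything downstream of this module assumes a single common voxel grid
(the processing space; clinically this is the 1 mm isotropic MNI grid the
images were registered to).  Volumes carry their spacing and an orientation
tag read from the NIfTI header; all geometry (diameters, distances) is
computed in millimetres via the spacing.  Voxel coordinates are 0-based
indices in the stored axis order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "assert_common_grid",
    "read_marks",
    "write_marks",
    "write_report",
]

#: absolute tolerance (mm) when comparing spacings of two grids
GRID_TOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _orientation_from_affine(affine: np.ndarray) -> str:
    return "".join(nib.orientations.aff2axcodes(affine))


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    spacing:
        Per-axis voxel size in mm, strictly positive.
    affine:
        4x4 voxel-to-world matrix (kept so files round-trip exactly).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D data of shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def orientation(self) -> str:
        return _orientation_from_affine(self.affine)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        return type(self)(data=data, spacing=self.spacing, affine=self.affine.copy())


@dataclass
class BinaryMask(ImageVolume):
    """A 3D mask over {0, 1} on the same kind of grid as :class:`ImageVolume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        uniq = np.unique(self.data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad headers
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D of shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), spacing, np.asarray(img.affine)


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI (.nii/.nii.gz) scalar volume."""
    data, spacing, affine = _load_nifti(path)
    return ImageVolume(data=data, spacing=spacing, affine=affine)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI binary mask.

    Float-valued files (interpolation residue from upstream resampling) are
    binarized at > 0.5 with a warning.
    """
    data, spacing, affine = _load_nifti(path)
    uniq = np.unique(data)
    if not np.isin(uniq, (0, 1)).all():
        warnings.warn(
            f"{path}: mask is not strictly 0/1; binarizing at > 0.5", stacklevel=2
        )
        data = (data > 0.5).astype(np.uint8)
    return BinaryMask(data=data, spacing=spacing, affine=affine)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume (or mask) as NIfTI-1, preserving the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


write_mask = write_volume


def assert_common_grid(volumes: list[ImageVolume]) -> None:
    """Check that all volumes live on one grid (shape, spacing, orientation).

    Raises :class:`GridMismatchError` naming the offending pair and axis.
    The check is symmetric: the outcome does not depend on volume order.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two volumes to compare")
    ref = volumes[0]
    for i, vol in enumerate(volumes[1:], start=1):
        for ax in range(3):
            if ref.grid_shape[ax] != vol.grid_shape[ax]:
                raise GridMismatchError(
                    f"volumes 0 and {i} differ in shape on axis {ax + 1}: "
                    f"{ref.grid_shape[ax]} vs {vol.grid_shape[ax]}"
                )
            if abs(ref.spacing[ax] - vol.spacing[ax]) > GRID_TOL_MM:
                raise GridMismatchError(
                    f"volumes 0 and {i} differ in spacing on axis {ax + 1}: "
                    f"{ref.spacing[ax]} vs {vol.spacing[ax]} mm"
                )
        if ref.orientation != vol.orientation:
            raise GridMismatchError(
                f"volumes 0 and {i} differ in orientation: "
                f"{ref.orientation} vs {vol.orientation}"
            )


MARK_COLUMNS = ["patient_id", "x", "y", "z", "source"]
MARK_SOURCES = {"rater1", "rater2", "consensus"}


def read_marks(path: str | Path, grid_shape: tuple[int, int, int] | None = None) -> pd.DataFrame:
    """Read a gold-standard mark table (CSV/TSV with header patient_id,x,y,z,source).

    Coordinates are 0-based voxel indices; if ``grid_shape`` is given every
    mark is validated to lie inside it.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in MARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df[MARK_COLUMNS].copy()
    if len(df):
        for c in ("x", "y", "z"):
            vals = df[c].to_numpy()
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{path}: non-integer voxel coordinate in column {c}")
            df[c] = np.round(vals).astype(int)
        bad_src = set(df["source"]) - MARK_SOURCES
        if bad_src:
            raise ValueError(f"{path}: unknown source tag(s) {sorted(bad_src)}")
        for row_no, (_, row) in enumerate(df.iterrows(), start=2):  # header is line 1
            coord = (row["x"], row["y"], row["z"])
            if any(c < 0 for c in coord):
                raise ValueError(f"{path}: negative coordinate {coord} at line {row_no}")
            if grid_shape is not None and any(
                c >= s for c, s in zip(coord, grid_shape)
            ):
                raise ValueError(
                    f"{path}: coordinate {coord} outside grid {grid_shape} at line {row_no}"
                )
    else:
        df = df.astype({"patient_id": str, "x": int, "y": int, "z": int, "source": str})
    return df


def write_marks(marks: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    marks[MARK_COLUMNS].to_csv(path, index=False)


def write_report(clusters, path: str | Path) -> pd.DataFrame:
    """Write the per-cluster audit report CSV.

    One row per cluster: id, label, diameter (mm), centroid, voxel count,
    volume (mm^3) and rejection reason.  Returns the DataFrame written.
    """
    rows = []
    for c in clusters:
        cx, cy, cz = c.centroid
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "label": c.label,
                "diameter_mm": round(float(c.diameter_mm), 4),
                "centroid_x": round(float(cx), 2),
                "centroid_y": round(float(cy), 2),
                "centroid_z": round(float(cz), 2),
                "n_voxels": len(c.voxels),
                "volume_mm3": round(float(c.volume_mm3), 4),
                "rejection_reason": c.rejection_reason,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "label",
            "diameter_mm",
            "centroid_x",
            "centroid_y",
            "centroid_z",
            "n_voxels",
            "volume_mm3",
            "rejection_reason",
        ],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df
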