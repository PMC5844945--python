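"""3D dose/image grids and organ masks on an LPS voxel lattice.

All volumes in this package live on a regular 3D lattice in the LPS
(left-posterior-superior) convention: axis 0 runs right-to-left (x), axis 1
anterior-to-posterior (y), and axis 2 inferior-to-superior (z).  Array index
``(i, j, k)`` maps to the physical voxel-center position
``origin + spacing * (i, j, k)`` in millimetres.  Dose is always in Gy.

The module provides grid containers with validated geometry, trilinear
resampling to isotropic resolution, contour rasterization, sagittal
lateralization (the ipsi/contra flip), and file I/O for DICOM-RT objects and
NRRD volumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid3D",
    "DoseGrid",
    "ImageGrid",
    "OrganMask",
    "LateralizationResult",
    "GridError",
    "resample_to_isotropic",
    "resample_mask",
    "rasterize_mask",
    "lateralize",
    "read_volume",
    "write_volume",
    "read_rt_dose",
    "read_rt_structures",
    "read_rt_dose_and_structures",
]

AXIS_NAMES = ("x", "y", "z")


class GridError(ValueError):
    """Invalid grid geometry or incompatible volumes."""


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 3:
        raise GridError(f"{name} must have exactly 3 components, got {arr.size}")
    return tuple(arr)


@dataclass
class Grid3D:
    """A scalar field on a regular 3D lattice (LPS axis order, mm units)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GridError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be positive on all axes, got {self.spacing}")
        self._validate_values()

    def _validate_values(self) -> None:
        if not np.isfinite(self.values).all():
            raise GridError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size spanned by voxel centers along each axis (mm)."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates along ``axis`` (mm)."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) coordinate arrays of every voxel center."""
        return np.meshgrid(*(self.axis_coordinates(a) for a in range(3)), indexing="ij")

    def same_geometry(self, other: "Grid3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def flip_sagittal(self) -> "Grid3D":
        """Mirror the volume through the sagittal (x = const) mid-plane.

        Voxel data are reversed along the x axis; the lattice geometry is
        unchanged, so voxel ``i`` takes the value formerly at ``n-1-i``.
        """
        return dataclasses.replace(self, values=self.values[::-1].copy())


@dataclass
class DoseGrid(Grid3D):
    """Absorbed-dose field in Gy; values must be finite and non-negative."""

    def _validate_values(self) -> None:
        super()._validate_values()
        if (self.values < 0).any():
            raise GridError("dose values must be non-negative (Gy)")


@dataclass
class ImageGrid(Grid3D):
    """Intensity (e.g. CT Hounsfield) field; any finite values allowed."""


@dataclass
class OrganMask(Grid3D):
    """Binary organ segmentation tied to a grid geometry.

    ``laterality`` tags the anatomical side ('left'/'right'); ``role`` is
    assigned by :func:`lateralize` ('ipsi'/'contra') and is 'unassigned'
    before that.
    """

    laterality: str = "unassigned"
    role: str = "unassigned"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        super().__post_init__()
        if self.laterality not in ("left", "right", "unassigned"):
            raise GridError(f"unknown laterality {self.laterality!r}")
        if self.role not in ("ipsi", "contra", "unassigned"):
            raise GridError(f"unknown role {self.role!r}")

    def _validate_values(self) -> None:
        pass  # booleans are always finite

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume(self) -> float:
        """Mask volume in mm^3."""
        return self.voxel_count * self.voxel_volume

    def require_nonempty(self) -> None:
        if self.voxel_count == 0:
            raise GridError("mask is empty")

    def voxel_centers(self) -> np.ndarray:
        """(n, 3) physical coordinates (mm) of all set voxels."""
        idx = np.argwhere(self.values)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class LateralizationResult:
    """Outcome of the sagittal-flip lateralization of a patient's volumes."""

    dose: DoseGrid
    ipsi_mask: OrganMask
    contra_mask: OrganMask
    flipped: bool
    image: ImageGrid | None = None
    mean_dose_ipsi: float = field(default=np.nan)
    mean_dose_contra: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# resampling


def resample_to_isotropic(grid: Grid3D, target: float = 1.0) -> Grid3D:
    """Trilinearly resample a grid to isotropic ``target`` mm spacing.

    The physical extent covered by voxel centers is preserved to within one
    voxel: the new lattice starts at the same origin and extends with
    ``target`` steps as far as the original extent allows.

    Raises
    ------
    GridError
        If ``target`` is not positive or an axis has a single slice (the
        interpolation would be undefined along it).
    """
    if target <= 0:
        raise GridError(f"target spacing must be positive, got {target}")
    for axis, n in enumerate(grid.shape):
        if n < 2:
            raise GridError(
                f"cannot resample along degenerate axis {AXIS_NAMES[axis]!r} "
                f"(size {n})"
            )
    new_axes = []
    for axis in range(3):
        extent = grid.extent[axis]
        n_new = int(np.floor(extent / target + 1e-9)) + 1
        new_axes.append(np.arange(n_new) * target)
    # index coordinates of the new voxel centers in the old lattice
    idx = np.meshgrid(
        *(ax / grid.spacing[a] for a, ax in enumerate(new_axes)), indexing="ij"
    )
    values = ndimage.map_coordinates(
        np.asarray(grid.values, dtype=float), np.stack(idx), order=1, mode="nearest"
    )
    if isinstance(grid, DoseGrid):
        values = np.clip(values, 0.0, None)
    return dataclasses.replace(
        grid, values=values, spacing=(target, target, target), origin=grid.origin
    )


def resample_mask(mask: OrganMask, target: float = 1.0) -> OrganMask:
    """Resample a binary mask to isotropic spacing.

    The mask is interpolated trilinearly as a 0/1 field and re-thresholded at
    0.5, which behaves as nearest-neighbour assignment at voxel centers and
    avoids fractional masks.
    """
    cont = Grid3D(mask.values.astype(float), mask.spacing, mask.origin)
    res = resample_to_isotropic(cont, target)
    return OrganMask(
        res.values >= 0.5,
        res.spacing,
        res.origin,
        laterality=mask.laterality,
        role=mask.role,
    )


# ---------------------------------------------------------------------------
# contour rasterization


def rasterize_mask(
    contours: Sequence[tuple[float, np.ndarray]],
    geometry: Grid3D,
    laterality: str = "unassigned",
) -> OrganMask:
    """Rasterize planar closed contours into a binary mask on ``geometry``.

    Parameters
    ----------
    contours
        Sequence of ``(z_mm, polygon)`` pairs where ``polygon`` is an (n, 2)
        array of (x, y) vertices in mm describing a closed simple polygon on
        the axial slice at ``z_mm``.  Several polygons may share a slice;
        overlapping regions combine by the even-odd rule (a point inside an
        even number of polygons is outside the structure).
    geometry
        Grid whose lattice the mask is rasterized onto.

    A voxel is set iff its center lies strictly inside the slice's polygon
    set.  Self-intersecting or degenerate polygons raise :class:`GridError`
    naming the slice.
    """
    import shapely
    from shapely.geometry import Polygon

    values = np.zeros(geometry.shape, dtype=bool)
    zs = geometry.axis_coordinates(2)
    xs = geometry.axis_coordinates(0)
    ys = geometry.axis_coordinates(1)
    xg, yg = np.meshgrid(xs, ys, indexing="ij")
    for slice_no, (z_mm, poly) in enumerate(contours):
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise GridError(f"contour {slice_no}: polygon needs >= 3 (x, y) vertices")
        shp = Polygon(poly)
        if not shp.is_valid or not shp.is_simple:
            raise GridError(f"contour {slice_no}: polygon is self-intersecting or degenerate")
        if not (zs[0] - geometry.spacing[2] / 2 <= z_mm <= zs[-1] + geometry.spacing[2] / 2):
            raise GridError(f"contour {slice_no}: slice z={z_mm} outside grid extent")
        k = int(np.argmin(np.abs(zs - z_mm)))
        inside = shapely.contains_xy(shp, xg.ravel(), yg.ravel()).reshape(xg.shape)
        values[:, :, k] ^= inside  # even-odd combination across polygons
    return OrganMask(values, geometry.spacing, geometry.origin, laterality=laterality)


# ---------------------------------------------------------------------------
# lateralization


def mean_dose(dose: DoseGrid, mask: OrganMask) -> float:
    """Arithmetic mean dose (Gy) over the mask voxels."""
    mask.require_nonempty()
    if dose.shape != mask.shape:
        raise GridError("dose and mask shapes differ")
    return float(dose.values[mask.values].mean())


def lateralize(
    dose: DoseGrid,
    left: OrganMask,
    right: OrganMask,
    image: ImageGrid | None = None,
) -> LateralizationResult:
    """Assign ipsi/contra roles, flipping sagittally when needed.

    The ipsilateral gland is the one with the higher mean dose.  To give all
    patients a common spatial frame, the whole volume set is mirrored through
    the sagittal plane when the *right* gland has the strictly higher mean
    dose, so the ipsilateral gland always ends up on the patient's left.
    Equal mean doses do not trigger a flip (the left gland is ipsi).
    """
    for name, m in (("left", left), ("right", right)):
        if not dose.same_geometry(m):
            raise GridError(f"{name} mask geometry does not match the dose grid")
        m.require_nonempty()
    md_left = mean_dose(dose, left)
    md_right = mean_dose(dose, right)
    flipped = md_right > md_left
    if flipped:
        dose = dose.flip_sagittal()
        left = left.flip_sagittal()
        right = right.flip_sagittal()
        image = image.flip_sagittal() if image is not None else None
        ipsi, contra = right, left
        md_ipsi, md_contra = md_right, md_left
    else:
        ipsi, contra = left, right
        md_ipsi, md_contra = md_left, md_right
    ipsi = dataclasses.replace(ipsi, role="ipsi")
    contra = dataclasses.replace(contra, role="contra")
    return LateralizationResult(
        dose=dose,
        ipsi_mask=ipsi,
        contra_mask=contra,
        flipped=bool(flipped),
        image=image,
        mean_dose_ipsi=md_ipsi,
        mean_dose_contra=md_contra,
    )


# ---------------------------------------------------------------------------
# file I/O

def write_volume(path: str | Path, grid: Grid3D) -> None:
    """Write a grid or mask to an NRRD file (LPS geometry preserved)."""
    import SimpleITK as sitk

    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    # SimpleITK arrays are indexed (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path: str | Path, kind: str = "auto") -> Grid3D:
    """Read an NRRD (or other ITK-readable) volume.

    ``kind`` selects the container: 'dose', 'image', 'mask', or 'auto'
    (mask for integer 0/1 data, image otherwise).
    """
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    if kind == "auto":
        uniq = np.unique(values)
        kind = "mask" if uniq.size <= 2 and set(uniq).issubset({0, 1}) else "image"
    if kind == "mask":
        return OrganMask(values.astype(bool), spacing, origin)
    if kind == "dose":
        return DoseGrid(values.astype(float), spacing, origin)
    if kind == "image":
        return ImageGrid(values.astype(float), spacing, origin)
    raise GridError(f"unknown volume kind {kind!r}")


def read_rt_dose(path: str | Path) -> DoseGrid:
    """Read a DICOM RTDOSE object into a :class:`DoseGrid` (Gy).

    The stored integer grid is multiplied by DoseGridScaling; a missing
    scaling tag or a non-axis-aligned orientation raises :class:`GridError`.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "DoseGridScaling" not in ds:
        raise GridError("RTDOSE is missing DoseGridScaling; cannot convert to Gy")
    orient = np.asarray(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0]):
        raise GridError(f"unsupported image orientation {orient.tolist()}; expected axis-aligned LPS")
    # pixel_array is (frames=z, rows=y, cols=x)
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    values = values.transpose(2, 1, 0)
    dx, dy = (float(v) for v in ds.PixelSpacing)  # (row, col) = (y, x)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz_steps = np.diff(offsets)
    if offsets.size < 2 or not np.allclose(dz_steps, dz_steps[0]):
        raise GridError("RTDOSE frame offsets are not uniform")
    spacing = (dy, dx, float(dz_steps[0]))
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, spacing, origin)


def read_rt_structures(path: str | Path) -> dict[str, list[tuple[float, np.ndarray]]]:
    """Read a DICOM RTSTRUCT into named contour stacks.

    Returns a mapping from ROI name to a list of ``(z_mm, (n, 2) xy-vertex
    array)`` pairs suitable for :func:`rasterize_mask`.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    out: dict[str, list[tuple[float, np.ndarray]]] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        stack: list[tuple[float, np.ndarray]] = []
        for contour in getattr(rc, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            zs = pts[:, 2]
            if not np.allclose(zs, zs[0]):
                raise GridError(f"ROI {name!r}: non-planar contour")
            stack.append((float(zs[0]), pts[:, :2]))
        out[name] = stack
    return out


def read_rt_dose_and_structures(
    dose_path: str | Path, struct_path: str | Path
) -> tuple[DoseGrid, dict[str, list[tuple[float, np.ndarray]]]]:
    """Convenience loader for a patient's RTDOSE + RTSTRUCT pair."""
    return read_rt_dose(dose_path), read_rt_structures(struct_path)
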