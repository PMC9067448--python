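"""Raster and mesh input/output plus maximum-intensity-projection rendering.

The pipeline's raster currency is :class:`ImageVolume`: a 3-D scalar grid with
physical voxel spacing and a world origin, always expressed in RAS
(right-anterior-superior) millimetres.  DICOM's native LPS frame is converted
on read so every downstream module works in a single world frame.  Voxel
indices are 0-based and voxel *centres* carry the world coordinate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import trimesh


class FormatError(ValueError):
    """File could not be parsed as the expected format."""


class DimensionalityError(ValueError):
    """Input raster does not have exactly three dimensions."""


class EmptyGeometryError(ValueError):
    """Mesh or mask contains no geometry to operate on."""


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular grid in world millimetres.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    spacing : tuple of float
        Per-axis voxel size in mm; all strictly positive.
    origin : tuple of float
        World (RAS, mm) position of the centre of voxel (0, 0, 0).
    axis_orientation : ndarray, shape (3, 3)
        Direction cosines mapping array axes to world axes.  Identity means
        array axis 0 runs along +R, 1 along +A, 2 along +S.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.axis_orientation = np.asarray(self.axis_orientation, dtype=float)
        if self.axis_orientation.shape != (3, 3):
            raise ValueError("axis_orientation must be a 3x3 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (RAS)."""
        aff = np.eye(4)
        aff[:3, :3] = self.axis_orientation @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ (self.axis_orientation @ np.diag(self.spacing)).T + np.asarray(
            self.origin
        )

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        m = np.linalg.inv(self.axis_orientation @ np.diag(self.spacing))
        return (xyz - np.asarray(self.origin)) @ m.T

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))


@dataclass
class SurfaceMesh:
    """Triangle mesh in world millimetres (counter-clockwise outward normals)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if len(self.faces) and np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ):
            raise ValueError("degenerate face repeats a vertex")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        """Total surface area (mm^2) as the sum of triangle areas."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def enclosed_volume(self) -> float:
        """Signed enclosed volume (mm^3) via the divergence theorem."""
        tri = self.vertices[self.faces]
        return float(
            np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
        )


def read_nifti(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI-1 volume into the RAS world frame.

    Spacing and origin are taken from the file's affine.  Integer intensities
    are preserved bit-exactly.  4-D images are rejected: the pipeline is
    defined on single-echo 3-D data.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read NIfTI file {path!r}: {exc}") from exc
    shape = img.shape
    if len(shape) != 3:
        raise DimensionalityError(
            f"expected a 3-D NIfTI volume, got shape {tuple(shape)}"
        )
    data = np.asanyarray(img.dataobj)
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    orientation = lin / spacing
    return ImageVolume(
        data=data,
        spacing=tuple(spacing),
        origin=tuple(aff[:3, 3]),
        axis_orientation=orientation,
    )


def write_nifti(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with its full RAS affine."""
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    nib.save(img, str(path))


def read_dicom_series(directory: str | os.PathLike) -> ImageVolume:
    """Assemble a single DICOM series directory into a 3-D volume.

    Slices are sorted by their through-plane position (projection of
    ImagePositionPatient onto the slice normal); through-plane spacing is
    inferred from the sorted positions and must be uniform to 1e-3 mm.
    DICOM stores world coordinates in LPS; they are converted to RAS here.

    Raises
    ------
    FormatError
        If the directory holds files from more than one series, or no
        readable slices.
    ValueError
        If inter-slice gaps are non-uniform beyond tolerance.
    """
    directory = Path(directory)
    slices = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM slices in {directory}")
    uids = {ds.SeriesInstanceUID for ds in slices}
    if len(uids) > 1:
        raise FormatError(
            f"directory contains {len(uids)} series (UIDs {sorted(uids)}); "
            "expected exactly one"
        )
    first = slices[0]
    row = np.array(first.ImageOrientationPatient[:3], dtype=float)
    col = np.array(first.ImageOrientationPatient[3:], dtype=float)
    normal = np.cross(row, col)
    slices.sort(key=lambda ds: float(np.dot(normal, ds.ImagePositionPatient)))
    positions = np.array(
        [np.dot(normal, np.asarray(ds.ImagePositionPatient, float)) for ds in slices]
    )
    if len(slices) > 1:
        gaps = np.diff(positions)
        if np.ptp(gaps) > 1e-3:
            raise ValueError(f"non-uniform slice spacing: gaps range {gaps.min()}..{gaps.max()} mm")
        dz = float(gaps.mean())
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    dr, dc = (float(v) for v in first.PixelSpacing)
    # stack as (row, column, slice); pixel_array is (rows, cols)
    data = np.stack([ds.pixel_array for ds in slices], axis=-1)
    lps_to_ras = np.diag([-1.0, -1.0, 1.0])
    orientation = np.column_stack([row, col, normal])
    orientation = lps_to_ras @ orientation
    origin = lps_to_ras @ np.asarray(first.ImagePositionPatient, dtype=float)
    return ImageVolume(
        data=data,
        spacing=(dr, dc, dz),
        origin=tuple(origin),
        axis_orientation=orientation,
    )


def write_stl(
    mesh: SurfaceMesh, path: str | os.PathLike, mode: str = "binary"
) -> None:
    """Export a mesh as STL (binary by default, ``mode='ascii'`` for text)."""
    if mesh.n_faces == 0:
        raise EmptyGeometryError("cannot export a mesh with no faces")
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = trimesh.exchange.stl.export_stl_ascii(tm) if mode == "ascii" else (
        trimesh.exchange.stl.export_stl(tm)
    )
    flags = "w" if isinstance(data, str) else "wb"
    with open(path, flags) as fh:
        fh.write(data)


def read_stl(path: str | os.PathLike) -> SurfaceMesh:
    tm = trimesh.load_mesh(str(path), process=False)
    if tm.faces.shape[0] == 0:
        raise EmptyGeometryError(f"{path} contains no triangles")
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def maximum_intensity_projection(volume: ImageVolume, axis: int) -> np.ndarray:
    """Collapse a volume along ``axis`` by taking the per-ray maximum.

    The MIP is the standard visual-verification rendering for bright-blood
    angiography: arteries survive the projection while background is
    suppressed.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis!r}")
    return np.max(volume.data, axis=axis)


def write_mip_png(volume: ImageVolume, path: str | os.PathLike, axis: int = 2) -> None:
    """Render a MIP to an 8-bit grayscale PNG (min-max intensity scaled)."""
    import imageio.v3 as iio

    mip = maximum_intensity_projection(volume, axis).astype(float)
    lo, hi = mip.min(), mip.max()
    scaled = np.zeros_like(mip) if hi == lo else (mip - lo) / (hi - lo)
    iio.imwrite(str(path), (scaled * 255).astype(np.uint8).T[::-1])
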