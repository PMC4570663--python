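"""Domain containers and file IO for CT volumes and SEM-EDX element maps.

Conventions used throughout the package:

* A grayscale volume is indexed ``data[j, i, k]`` with ``i`` along x
  (column), ``j`` along y (row) and ``k`` along z (slice), all 0-based.
* Windows are half-open and origins 0-based.
* Physical coordinates are ``index * voxel_size_um`` at voxel centers.
"""

from __future__ import annotations

import csv
import glob
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEFAULT_ELEMENTS = ("C", "Si", "Fe", "O")
DEFAULT_VOXEL_SIZE_UM = 15.8


class DataError(ValueError):
    """Raised for malformed input files or invariant violations."""


@dataclass
class GrayscaleVolume:
    """8-bit X-ray CT attenuation volume.

    Parameters
    ----------
    data:
        3D integer array, shape ``(rows, cols, slices)``, values in [0, 255].
    voxel_size_um:
        Edge length of a cubic voxel in micrometers.
    """

    data: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DataError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if self.voxel_size_um <= 0:
            raise DataError("voxel_size_um must be positive")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise DataError("volume intensities must be integer-valued")
        if self.data.min() < 0 or self.data.max() > 255:
            raise DataError("volume intensities must lie in [0, 255]")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slice(self, k: int) -> np.ndarray:
        """Axis-aligned slice ``k`` as a 2D (rows, cols) array."""
        return self.data[:, :, k]


@dataclass
class ElementMap:
    """Per-pixel characteristic X-ray counts for one element on one cut face."""

    element: str
    data: np.ndarray
    pixel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("element map must be 2D")
        if self.pixel_size_um <= 0:
            raise DataError("pixel_size_um must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise DataError("mask shape must equal data shape")
            self.mask = self.mask & np.isfinite(self.data)
        valid = self.data[self.mask]
        if valid.size and valid.min() < 0:
            raise DataError(f"element map {self.element!r} contains negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class Face:
    """One scanned cut face: element maps plus its nominal position."""

    face_id: str
    z: float
    maps: dict[str, ElementMap] = field(default_factory=dict)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted(self.maps))


@dataclass
class LayerSet:
    """Ordered collection of scanned faces with the cutting geometry.

    ``slice_thickness`` and ``kerf`` are expressed in CT layers; in the
    reference geometry a slice spans 15 layers and the saw kerf 50, so the
    two faces of one slice plus a face of the next slice are 65 apart.
    """

    faces: list[Face]
    slice_thickness: float = 15.0
    kerf: float = 50.0

    def __post_init__(self) -> None:
        zs = [f.z for f in self.faces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise DataError("face z positions must be strictly increasing")
        if self.faces:
            ref = self.faces[0].elements
            for f in self.faces:
                if f.elements != ref:
                    raise DataError(
                        f"face {f.face_id!r} carries elements {f.elements}, expected {ref}"
                    )

    def __len__(self) -> int:
        return len(self.faces)

    @property
    def elements(self) -> tuple[str, ...]:
        return self.faces[0].elements if self.faces else ()


# ---------------------------------------------------------------------------
# Volume IO


def read_volume(path_pattern: str, voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> GrayscaleVolume:
    """Read an 8-bit grayscale slice stack into a volume.

    ``path_pattern`` is either a glob matching numbered single-channel 8-bit
    images (lexicographic order defines ``k``) or a single multi-page TIFF.
    """
    import imageio.v3 as iio

    if os.path.isfile(path_pattern) and path_pattern.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path_pattern)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.dtype != np.uint8:
            raise DataError(f"{path_pattern}: expected 8-bit data, got {arr.dtype}")
        return GrayscaleVolume(np.moveaxis(arr, 0, 2), voxel_size_um)

    files = sorted(glob.glob(path_pattern))
    if not files:
        raise DataError(f"no files match {path_pattern!r}")
    slices = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3 and img.shape[2] in (3, 4) and np.ptp(img, axis=2).max() == 0:
            img = img[:, :, 0]  # grayscale saved as RGB
        if img.ndim != 2:
            raise DataError(f"{f}: not a single-channel image (shape {img.shape})")
        if img.dtype != np.uint8:
            raise DataError(f"{f}: expected 8-bit image, got {img.dtype}")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise DataError(f"{f}: dimensions {img.shape} differ from first slice {shape}")
        slices.append(img)
    return GrayscaleVolume(np.stack(slices, axis=2), voxel_size_um)


def write_volume(volume: GrayscaleVolume, directory: str, prefix: str = "slice", fmt: str = "png") -> list[str]:
    """Write a volume as a numbered 8-bit image stack; returns the file list."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    width = max(4, len(str(volume.n_slices)))
    paths = []
    for k in range(volume.n_slices):
        p = os.path.join(directory, f"{prefix}_{k:0{width}d}.{fmt}")
        iio.imwrite(p, np.ascontiguousarray(volume.data[:, :, k]))
        paths.append(p)
    return paths


def write_prediction_block(block: np.ndarray, path: str, per_slice_csv: Optional[str] = None) -> None:
    """Write a predicted 3D concentration block as a 32-bit float TIFF stack.

    ``block`` has shape (rows, cols, slices). With ``per_slice_csv`` set, each
    slice is additionally written as ``<per_slice_csv>_<k>.csv``.
    """
    import tifffile

    arr = np.moveaxis(np.asarray(block, dtype=np.float32), 2, 0)
    tifffile.imwrite(path, arr)
    if per_slice_csv is not None:
        for k in range(arr.shape[0]):
            np.savetxt(f"{per_slice_csv}_{k:04d}.csv", arr[k], delimiter=",", fmt="%.6g")


# ---------------------------------------------------------------------------
# Element-map IO


def read_element_map(
    path: str,
    element: str,
    pixel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    mask_path: Optional[str] = None,
) -> ElementMap:
    """Read a plain-CSV matrix of X-ray counts.

    Empty cells become masked-out pixels; negative or non-numeric cells are
    rejected. An optional companion CSV of 0/1 marks valid pixels.
    """
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    with open(path, newline="") as fh:
        for ln, rec in enumerate(csv.reader(fh)):
            if not rec:
                continue
            vals, ok = [], []
            for cn, cell in enumerate(rec):
                cell = cell.strip()
                if cell == "":
                    vals.append(np.nan)
                    ok.append(False)
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    raise DataError(f"{path}: non-numeric cell {cell!r} at row {ln}, col {cn}")
                if v < 0:
                    raise DataError(f"{path}: negative count {v} at row {ln}, col {cn}")
                vals.append(v)
                ok.append(True)
            if rows and len(vals) != len(rows[0]):
                raise DataError(f"{path}: ragged row {ln} (length {len(vals)} != {len(rows[0])})")
            rows.append(vals)
            mask_rows.append(ok)
    if not rows:
        raise DataError(f"{path}: empty file")
    data = np.array(rows, dtype=float)
    mask = np.array(mask_rows, dtype=bool)
    if mask_path is not None:
        m = np.loadtxt(mask_path, delimiter=",", dtype=float)
        if m.shape != data.shape:
            raise DataError(f"{mask_path}: mask shape {m.shape} != data shape {data.shape}")
        mask &= m.astype(bool)
    return ElementMap(element=element, data=data, pixel_size_um=pixel_size_um, mask=mask)


def write_element_map(emap: ElementMap, path: str, mask_path: Optional[str] = None) -> None:
    """Write an element map as CSV (masked-out pixels become empty cells)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for j in range(emap.data.shape[0]):
            row = []
            for i in range(emap.data.shape[1]):
                row.append(f"{emap.data[j, i]:.10g}" if emap.mask[j, i] else "")
            w.writerow(row)
    if mask_path is not None:
        np.savetxt(mask_path, emap.mask.astype(int), delimiter=",", fmt="%d")


def read_face(directory: str, face_id: str, z: float,
              elements: Sequence[str] = DEFAULT_ELEMENTS,
              pixel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> Face:
    """Read ``<faceid>_<element>.csv`` maps for one face from ``directory``."""
    maps = {}
    for el in elements:
        p = os.path.join(directory, f"{face_id}_{el}.csv")
        if not os.path.exists(p):
            raise DataError(f"missing element map file {p}")
        mp = os.path.join(directory, f"{face_id}_{el}_mask.csv")
        maps[el] = read_element_map(p, el, pixel_size_um, mp if os.path.exists(mp) else None)
    return Face(face_id=face_id, z=z, maps=maps)


# ---------------------------------------------------------------------------
# Windows


def crop_region(map_or_slice: np.ndarray, origin: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    """Half-open window ``[r0, r0+rows) x [c0, c0+cols)`` of a 2D array."""
    arr = np.asarray(map_or_slice)
    if arr.ndim != 2:
        raise DataError("crop_region expects a 2D array")
    r0, c0 = origin
    rows, cols = shape
    if r0 < 0 or c0 < 0 or rows < 1 or cols < 1 or r0 + rows > arr.shape[0] or c0 + cols > arr.shape[1]:
        raise DataError(
            f"crop window origin={origin} shape={shape} exceeds array bounds {arr.shape}"
        )
    return arr[r0 : r0 + rows, c0 : c0 + cols]
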