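"""Voxel data model shared by every stage of the mandible FE pipeline.

A model is a labeled, isometric 3-D voxel image: every voxel is VOID (air,
meshed as nothing), BONE (cortical bone) or INCISOR (dental tissue).  The
grid is the direct source of the hexahedral FE mesh — one trilinear cube
element per non-VOID voxel — so this module also owns the conventions that
keep the geometry, mesh and measurement layers consistent:

* voxel indices are 0-based; slice order in an image stack is ascending z;
* the world frame is in millimetres; the centre of voxel (i, j, k) is at
  ``origin + spacing * (i + 1/2, j + 1/2, k + 1/2)``.

Real segmentations enter as bitmap stacks (:func:`read_image_stack`);
results leave as legacy-VTK STRUCTURED_POINTS files (:func:`write_vtk`)
with labels and solution fields attached as CELL_DATA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage


class Label(enum.IntEnum):
    """Closed three-value voxel label set."""

    VOID = 0
    BONE = 1
    INCISOR = 2


class VoxelModelError(ValueError):
    """Base class for voxel-model domain errors."""


class DimensionError(VoxelModelError):
    """Inconsistent slice shapes or field/grid shape mismatch."""


class LabelError(VoxelModelError):
    """A pixel value has no entry in the label map."""


class EmptyModelError(VoxelModelError):
    """An operation requires at least one non-VOID voxel."""


@dataclass
class VoxelGrid:
    """Labeled isometric voxel image.

    Parameters
    ----------
    labels
        ``(nx, ny, nz)`` uint8 array of :class:`Label` values.
    spacing
        Voxel edge length in mm (isometric; strictly positive).
    origin
        World coordinate (mm) of the corner of voxel ``(0, 0, 0)``.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise DimensionError("labels must be a 3-D array")
        if not self.spacing > 0:
            raise VoxelModelError(f"spacing must be > 0, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise DimensionError("origin must be a 3-vector")
        bad = set(np.unique(self.labels)) - {int(l) for l in Label}
        if bad:
            raise LabelError(f"unknown label values {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_solid(self) -> int:
        return int(np.count_nonzero(self.labels))

    def solid_mask(self) -> np.ndarray:
        return self.labels != Label.VOID

    def voxel_centers(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centres for index array ``(n, 3)``."""
        ijk = np.atleast_2d(np.asarray(ijk))
        return self.origin + self.spacing * (ijk + 0.5)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Voxel index containing each world point (no bounds check)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.spacing).astype(int)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.labels.copy(), self.spacing, self.origin.copy())


@dataclass
class MaterialTable:
    """Isotropic linear-elastic properties per non-VOID label.

    ``young_modulus`` is in MPa; Poisson's ratio is dimensionless and must
    satisfy ``0 <= nu < 0.5``.  The default table assigns cortical bone
    E = 17 GPa, nu = 0.3 and incisor (enamel/dentine average) E = 55 GPa,
    nu = 0.32.
    """

    young_modulus: dict[int, float]
    poisson_ratio: dict[int, float]

    def __post_init__(self) -> None:
        for lab, E in self.young_modulus.items():
            if not E > 0:
                raise VoxelModelError(f"E must be > 0 for label {lab}, got {E}")
        for lab, nu in self.poisson_ratio.items():
            if not (0 <= nu < 0.5):
                raise VoxelModelError(f"nu must be in [0, 0.5) for label {lab}, got {nu}")
        if set(self.young_modulus) != set(self.poisson_ratio):
            raise VoxelModelError("young_modulus and poisson_ratio must cover the same labels")

    @classmethod
    def default(cls) -> "MaterialTable":
        return cls(
            young_modulus={int(Label.BONE): 17000.0, int(Label.INCISOR): 55000.0},
            poisson_ratio={int(Label.BONE): 0.30, int(Label.INCISOR): 0.32},
        )


# ---------------------------------------------------------------------------
# image-stack I/O
# ---------------------------------------------------------------------------

def _read_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) written from a grayscale source
        if not np.all(arr[..., :3] == arr[..., :1]):
            raise LabelError(f"{path} is not grayscale")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise DimensionError(f"{path} is not a 2-D image")
    return arr


def read_image_stack(
    paths: Sequence[str | Path],
    spacing: float,
    label_map: Mapping[int, int | Label],
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> VoxelGrid:
    """Read an ordered bitmap stack into a :class:`VoxelGrid`.

    Slices are stacked in ascending z (list order).  Within a slice, image
    rows map to the y axis and columns to the x axis.  ``label_map`` must
    cover every pixel value present; it is never inferred.
    """
    if not paths:
        raise EmptyModelError("no slices given")
    if not spacing > 0:
        raise VoxelModelError(f"spacing must be > 0, got {spacing}")
    slices = [_read_slice(Path(p)) for p in paths]
    shape0 = slices[0].shape
    for p, s in zip(paths, slices):
        if s.shape != shape0:
            raise DimensionError(f"slice {p} has shape {s.shape}, expected {shape0}")
    lut = np.full(int(max(int(s.max(initial=0)) for s in slices)) + 1, -1, dtype=np.int16)
    for pix, lab in label_map.items():
        lut[int(pix)] = int(lab)
    ny, nx = shape0
    labels = np.empty((nx, ny, len(slices)), dtype=np.uint8)
    for k, s in enumerate(slices):
        mapped = lut[s.astype(np.int64)]
        if (mapped < 0).any():
            missing = sorted(int(v) for v in np.unique(s[mapped < 0]))
            raise LabelError(f"pixel values {missing} missing from label_map")
        labels[:, :, k] = mapped.T
    return VoxelGrid(labels, spacing, np.asarray(origin, dtype=float))


def write_image_stack(
    grid: VoxelGrid,
    directory: str | Path,
    fmt: str = "png",
    value_map: Mapping[int, int] | None = None,
) -> list[Path]:
    """Write the grid as a grayscale bitmap stack (inverse of read_image_stack)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if value_map is None:
        value_map = {int(l): int(l) for l in Label}
    lut = np.zeros(256, dtype=np.uint8)
    for lab, pix in value_map.items():
        lut[int(lab)] = int(pix)
    paths = []
    for k in range(grid.shape[2]):
        img = lut[grid.labels[:, :, k]].T  # rows = y, cols = x
        path = directory / f"slice_{k:04d}.{fmt}"
        if fmt in {"tif", "tiff"}:
            import tifffile

            tifffile.imwrite(path, img)
        else:
            import imageio.v3 as iio

            iio.imwrite(path, img)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# label bookkeeping
# ---------------------------------------------------------------------------

def label_counts(grid: VoxelGrid) -> dict[Label, int]:
    """Voxel count per label; counts always sum to nx*ny*nz."""
    counts = np.bincount(grid.labels.ravel(), minlength=len(Label))
    return {lab: int(counts[int(lab)]) for lab in Label}


_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def largest_component(grid: VoxelGrid, connectivity: int = 6) -> tuple[VoxelGrid, int]:
    """Keep only the largest connected non-VOID component.

    Guarantees a well-posed FE problem (no floating fragments).  Returns the
    cleaned grid and the number of voxels dropped.
    """
    if connectivity not in (6, 26):
        raise VoxelModelError("connectivity must be 6 or 26")
    solid = grid.solid_mask()
    if not solid.any():
        raise EmptyModelError("grid has no non-VOID voxels")
    structure = _STRUCT6 if connectivity == 6 else _STRUCT26
    comp, n = ndimage.label(solid, structure=structure)
    if n == 1:
        return grid.copy(), 0
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    keep = int(sizes.argmax())
    labels = grid.labels.copy()
    labels[comp != keep] = Label.VOID
    dropped = int(solid.sum() - sizes[keep])
    return VoxelGrid(labels, grid.spacing, grid.origin.copy()), dropped


def surface_voxel_mask(grid: VoxelGrid) -> np.ndarray:
    """Solid voxels with at least one VOID 6-neighbour (or on the grid border)."""
    solid = grid.solid_mask()
    padded = np.pad(solid, 1, constant_values=False)
    interior = np.ones_like(solid)
    for axis in range(3):
        for shift in (-1, 1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    return solid & ~interior


# ---------------------------------------------------------------------------
# legacy VTK STRUCTURED_POINTS export / import
# ---------------------------------------------------------------------------

def write_vtk(
    grid: VoxelGrid,
    path: str | Path,
    fields: Mapping[str, np.ndarray] | None = None,
) -> Path:
    """Write the grid (and optional per-voxel fields) as legacy ASCII VTK.

    Labels go out as an integer CELL_DATA scalar array named ``label``;
    each entry of ``fields`` must be shaped ``grid.shape`` (scalar) or
    ``grid.shape + (k,)`` (k-component, written as a FIELD array).
    Round-trips label values exactly through :func:`read_vtk`.
    """
    path = Path(path)
    nx, ny, nz = grid.shape
    fields = dict(fields or {})
    for name, arr in fields.items():
        if arr.shape[:3] != grid.shape:
            raise DimensionError(f"field {name!r} shape {arr.shape} does not match grid {grid.shape}")
    ncells = nx * ny * nz
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("gnawfe voxel model\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {grid.origin[0]:.9g} {grid.origin[1]:.9g} {grid.origin[2]:.9g}\n")
        fh.write(f"SPACING {grid.spacing:.9g} {grid.spacing:.9g} {grid.spacing:.9g}\n")
        fh.write(f"CELL_DATA {ncells}\n")
        fh.write("SCALARS label int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        grid.labels.ravel(order="F").tofile(fh, sep="\n")
        fh.write("\n")
        scalar_fields = {n: a for n, a in fields.items() if a.ndim == 3}
        vector_fields = {n: a for n, a in fields.items() if a.ndim > 3}
        for name, arr in scalar_fields.items():
            fh.write(f"SCALARS {name} double 1\n")
            fh.write("LOOKUP_TABLE default\n")
            np.asarray(arr, dtype=float).ravel(order="F").tofile(fh, sep="\n")
            fh.write("\n")
        if vector_fields:
            fh.write(f"FIELD gnawfe {len(vector_fields)}\n")
            for name, arr in vector_fields.items():
                k = int(np.prod(arr.shape[3:]))
                fh.write(f"{name} {k} {ncells} double\n")
                flat = np.asarray(arr, dtype=float).reshape(nx, ny, nz, k)
                # one row of k components per cell, cells in F order (x fastest)
                flat = flat.transpose(2, 1, 0, 3).reshape(-1, k)
                flat.tofile(fh, sep="\n")
                fh.write("\n")
    return path


def read_vtk(path: str | Path) -> tuple[VoxelGrid, dict[str, np.ndarray]]:
    """Read a file written by :func:`write_vtk` (labels + scalar/FIELD arrays)."""
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5 or "STRUCTURED_POINTS" not in lines[3]:
        raise VoxelModelError(f"{path} is not a gnawfe STRUCTURED_POINTS file")
    header: dict[str, list[float]] = {}
    i = 4
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key in {"DIMENSIONS", "ORIGIN", "SPACING"}:
            header[key] = [float(v) for v in parts[1:4]]
            i += 1
        elif key == "CELL_DATA":
            i += 1
            break
        else:
            i += 1
    nx, ny, nz = (int(v) - 1 for v in header["DIMENSIONS"])
    ncells = nx * ny * nz
    tokens = " ".join(lines[i:]).split()
    grid = None
    fields: dict[str, np.ndarray] = {}
    pos = 0
    while pos < len(tokens):
        tok = tokens[pos].upper()
        if tok == "SCALARS":
            name, dtype = tokens[pos + 1], tokens[pos + 2]
            pos += 4  # SCALARS name type 1
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            data = np.array(tokens[pos : pos + ncells], dtype=float)
            pos += ncells
            arr = data.reshape((nx, ny, nz), order="F")
            if name == "label":
                grid = VoxelGrid(
                    arr.astype(np.uint8),
                    header["SPACING"][0],
                    np.asarray(header["ORIGIN"]),
                )
            else:
                fields[name] = arr
        elif tok == "FIELD":
            nfield = int(tokens[pos + 2])
            pos += 3
            for _ in range(nfield):
                name, k, n = tokens[pos], int(tokens[pos + 1]), int(tokens[pos + 2])
                pos += 4  # name k n dtype
                data = np.array(tokens[pos : pos + k * n], dtype=float)
                pos += k * n
                fields[name] = data.reshape(nz, ny, nx, k).transpose(2, 1, 0, 3)
        else:
            pos += 1
    if grid is None:
        raise VoxelModelError(f"{path} contains no 'label' array")
    return grid, fields
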