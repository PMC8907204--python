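"""Five-model incisor-root manipulation: shortening with bone fill or crypt.

The experimental design compares an unaltered mandible against four
virtually ablated variants: the internal incisor root is shortened to 50%
or 25% of its original length, and the removed dental material is either
replaced with cortical bone or left as an empty, air-filled crypt:

    model 1 — full-length incisor (unaltered)
    model 2 — 50% root, bone fill        model 4 — 50% root, air crypt
    model 3 — 25% root, bone fill        model 5 — 25% root, air crypt

Root length is measured anteroposteriorly along the outer (labial) margin
of the incisor, from the alveolar margin to the deepest distal point of the
root.  An incisor voxel's arc-length coordinate is that of its nearest
labial-margin vertex (ties toward the more mesial vertex), which yields a
cut approximately perpendicular to the tooth's local axis.  Only INCISOR
voxels are ever relabeled; the alveolar wall stays intact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic_mandible import MandibleAnnotation
from .voxel_model import Label, VoxelGrid


class VariantError(ValueError):
    pass


class AnnotationError(VariantError):
    pass


class Fill(enum.Enum):
    BONE_FILL = "bone_fill"
    VOID_CRYPT = "void_crypt"


@dataclass(frozen=True)
class VariantSpec:
    """Root-shortening variant: retained root fraction and fill mode."""

    root_fraction: float
    fill: Fill
    model_index: int

    def __post_init__(self) -> None:
        if not (0 < self.root_fraction <= 1):
            raise VariantError(f"root_fraction must be in (0, 1], got {self.root_fraction}")

    @staticmethod
    def suite() -> list["VariantSpec"]:
        """The standard five-model suite."""
        return [
            VariantSpec(1.0, Fill.BONE_FILL, 1),
            VariantSpec(0.5, Fill.BONE_FILL, 2),
            VariantSpec(0.25, Fill.BONE_FILL, 3),
            VariantSpec(0.5, Fill.VOID_CRYPT, 4),
            VariantSpec(0.25, Fill.VOID_CRYPT, 5),
        ]


def _labial_arc_coords(annotation: MandibleAnnotation) -> tuple[np.ndarray, int]:
    """Cumulative arc length of the labial polyline and the alveolar vertex."""
    poly = np.asarray(annotation.labial_margin, dtype=float)
    if len(poly) < 2:
        raise AnnotationError("labial margin polyline needs at least 2 vertices")
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    d = np.linalg.norm(poly - annotation.alveolar_margin_point, axis=1)
    return cum, int(np.argmin(d))


def measure_root_length(annotation: MandibleAnnotation, tol: float | None = None) -> float:
    """Root length (mm): labial-margin arc length from the vertex nearest the
    alveolar margin to the distal end of the polyline.

    ``tol`` (typically one voxel) bounds how far the alveolar point may sit
    from the polyline; exceeding it raises :class:`AnnotationError`.
    """
    cum, idx = _labial_arc_coords(annotation)
    if tol is not None:
        d = np.linalg.norm(
            np.asarray(annotation.labial_margin)[idx] - annotation.alveolar_margin_point
        )
        if d > tol:
            raise AnnotationError(
                f"alveolar margin point is {d:.3g} mm from the labial margin (tol {tol})"
            )
    return float(cum[-1] - cum[idx])


def incisor_arc_coordinates(
    grid: VoxelGrid, annotation: MandibleAnnotation
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length coordinate (mm from the alveolar margin, positive distal)
    of every INCISOR voxel, via nearest labial-margin vertex projection."""
    iv = np.argwhere(grid.labels == Label.INCISOR)
    if len(iv) == 0:
        return iv, np.empty(0)
    cum, alv_idx = _labial_arc_coords(annotation)
    tree = cKDTree(np.asarray(annotation.labial_margin, dtype=float))
    _, nearest = tree.query(grid.voxel_centers(iv))
    return iv, cum[nearest] - cum[alv_idx]


def cut_point(annotation: MandibleAnnotation, root_fraction: float) -> np.ndarray:
    """World point on the labial margin where a variant's cut surface meets
    it (arc coordinate = root_fraction x root length past the alveolus)."""
    cum, alv_idx = _labial_arc_coords(annotation)
    L = cum[-1] - cum[alv_idx]
    target = cum[alv_idx] + root_fraction * L
    j = int(np.argmin(np.abs(cum - target)))
    return np.asarray(annotation.labial_margin)[j].copy()


def shorten_incisor(
    grid: VoxelGrid, annotation: MandibleAnnotation, spec: VariantSpec
) -> tuple[VoxelGrid, np.ndarray]:
    """Apply one variant: relabel incisor voxels distal to the cut.

    Returns the new grid and the ``(k, 3)`` removed-voxel index set.  The
    total voxel count never changes; with BONE_FILL the non-VOID count is
    conserved as well.
    """
    if not (0 < spec.root_fraction <= 1):
        raise VariantError(f"root_fraction must be in (0, 1], got {spec.root_fraction}")
    out = grid.copy()
    if spec.root_fraction == 1.0:
        return out, np.empty((0, 3), dtype=int)
    iv, coords = incisor_arc_coordinates(grid, annotation)
    if len(iv) == 0:
        raise VariantError("grid contains no INCISOR voxels")
    L = measure_root_length(annotation, tol=grid.spacing)
    removed = iv[coords > spec.root_fraction * L]
    new_label = Label.BONE if spec.fill is Fill.BONE_FILL else Label.VOID
    out.labels[tuple(removed.T)] = new_label
    return out, removed


def build_model_suite(
    grid: VoxelGrid, annotation: MandibleAnnotation
) -> list[tuple[VoxelGrid, VariantSpec]]:
    """Build the ordered five-model suite (model 1 identical to the input)."""
    suite = []
    for spec in VariantSpec.suite():
        variant, _ = shorten_incisor(grid, annotation, spec)
        suite.append((variant, spec))
    return suite


def suite_manifest(
    grid: VoxelGrid, annotation: MandibleAnnotation
) -> list[dict]:
    """JSON-ready description of the suite: fractions, fills, removed voxel
    counts and volumes, and cut positions (cut perpendicular to the local
    tooth axis by nearest-vertex projection)."""
    records = []
    for spec in VariantSpec.suite():
        variant, removed = shorten_incisor(grid, annotation, spec)
        rec = {
            "model_index": spec.model_index,
            "root_fraction": spec.root_fraction,
            "fill": spec.fill.value,
            "removed_voxels": int(len(removed)),
            "removed_volume_mm3": float(len(removed) * grid.spacing**3),
            "cut_rule": "nearest labial-margin vertex (perpendicular to tooth axis)",
        }
        if spec.root_fraction < 1.0:
            rec["cut_point_mm"] = cut_point(annotation, spec.root_fraction).tolist()
        records.append(rec)
    return records
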