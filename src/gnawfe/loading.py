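"""Muscle force estimation and load/constraint construction for incisal biting.

Muscle forces follow the standard physiological cross-sectional area (PCSA)
route: muscle mass is converted to volume with a muscle density of
1.0564 g cm^-3, divided by fibre length to give PCSA in mm^2, and multiplied
by an intrinsic muscle stress of 0.3 N mm^-2 to give force in newtons.
Each muscle pulls from the centroid of its mandibular attachment patch
toward a cranial origin landmark along a straight line (no wrapping), with
the total force divided across the patch's surface nodes.

The bite itself is modelled by the constraint scheme used throughout the
voxel-FE literature on rodent incision: the temporomandibular joints are
fixed in all three axes, and the incisor tip is constrained along the bite
direction only — the normal to the post-incisor occlusal plane.  The bite
force emerges as the reaction at the tip constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hexfem import FEMesh
from .synthetic_mandible import MandibleAnnotation
from .voxel_model import VoxelGrid


class LoadingError(ValueError):
    """Invalid muscle specification, patch or geometry."""


@dataclass
class PhysioConstants:
    """Physiological constants for the mass -> PCSA -> force conversion.

    muscle_density is in g cm^-3, intrinsic_stress in N mm^-2.  The defaults
    are fixed literature values; both can be overridden via config.
    """

    muscle_density: float = 1.0564
    intrinsic_stress: float = 0.3


def compute_pcsa(mass: float, fiber_length: float, constants: PhysioConstants | None = None) -> float:
    """PCSA in mm^2 from muscle mass (g) and fibre length (mm).

    volume = mass / density (cm^3, converted to mm^3); pcsa = volume / fibre
    length.  E.g. 1.0564 g at 10 mm fibres -> 1 cm^3 = 1000 mm^3 -> 100 mm^2.
    """
    constants = constants or PhysioConstants()
    if not mass > 0:
        raise LoadingError(f"mass must be > 0, got {mass}")
    if not fiber_length > 0:
        raise LoadingError(f"fiber_length must be > 0, got {fiber_length}")
    volume_mm3 = mass / constants.muscle_density * 1000.0
    return volume_mm3 / fiber_length


def muscle_force(pcsa: float, constants: PhysioConstants | None = None) -> float:
    """Muscle force in N: PCSA (mm^2) times intrinsic muscle stress."""
    constants = constants or PhysioConstants()
    if not pcsa > 0:
        raise LoadingError(f"pcsa must be > 0, got {pcsa}")
    return pcsa * constants.intrinsic_stress


@dataclass
class MuscleSpec:
    """One masticatory muscle.

    Provide either (mass, fiber_length) or pcsa directly, never both.  The
    attachment patch is named and resolved against the annotation's muscle
    patches; origin_point is the cranial attachment centroid (world mm).
    """

    name: str
    patch_name: str
    origin_point: np.ndarray
    mass: float | None = None  # g
    fiber_length: float | None = None  # mm
    pcsa: float | None = None  # mm^2

    def __post_init__(self) -> None:
        self.origin_point = np.asarray(self.origin_point, dtype=float)
        has_mass = self.mass is not None or self.fiber_length is not None
        if self.pcsa is not None:
            if has_mass:
                raise LoadingError(f"{self.name}: give (mass, fiber_length) or pcsa, not both")
            if not self.pcsa > 0:
                raise LoadingError(f"{self.name}: pcsa must be > 0")
        else:
            if self.mass is None or self.fiber_length is None:
                raise LoadingError(f"{self.name}: need mass and fiber_length (or pcsa)")
            if not (self.mass > 0 and self.fiber_length > 0):
                raise LoadingError(f"{self.name}: mass and fiber_length must be > 0")

    def resolve_pcsa(self, constants: PhysioConstants) -> float:
        if self.pcsa is not None:
            return float(self.pcsa)
        return compute_pcsa(self.mass, self.fiber_length, constants)

    def force(self, constants: PhysioConstants) -> float:
        return muscle_force(self.resolve_pcsa(constants), constants)


def read_muscle_table(source: str | Path | pd.DataFrame) -> list[MuscleSpec]:
    """Read muscle specs from CSV with columns name, patch_name,
    origin_x_mm/origin_y_mm/origin_z_mm and either mass_g + fiber_length_mm
    or pcsa_mm2."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    specs = []
    for _, row in df.iterrows():
        origin = np.array([row["origin_x_mm"], row["origin_y_mm"], row["origin_z_mm"]], dtype=float)
        kwargs: dict = {}
        if "pcsa_mm2" in row and pd.notna(row.get("pcsa_mm2")):
            kwargs["pcsa"] = float(row["pcsa_mm2"])
        else:
            kwargs["mass"] = float(row["mass_g"])
            kwargs["fiber_length"] = float(row["fiber_length_mm"])
        specs.append(
            MuscleSpec(name=str(row["name"]), patch_name=str(row["patch_name"]), origin_point=origin, **kwargs)
        )
    return specs


@dataclass
class LoadCase:
    """Nodal force table plus per-muscle bookkeeping.

    ``forces`` is (n_nodes, 3) in N; ``totals`` maps muscle name to
    (force magnitude N, unit direction).  The vector sum of each muscle's
    nodal forces equals its total force along its direction to 1e-9 relative.
    """

    forces: np.ndarray
    totals: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)

    def scaled(self, k: float) -> "LoadCase":
        return LoadCase(
            forces=self.forces * k,
            totals={n: (f * k, d.copy()) for n, (f, d) in self.totals.items()},
        )


@dataclass
class ConstraintSet:
    """TMJ fixation plus single-direction bite constraint.

    fixed_nodes are fully fixed (all three axes; displacement values in
    ``fixed_values`` if non-zero, used e.g. by the patch test); bite_nodes
    are constrained along ``bite_direction`` only.  The two sets must be
    disjoint and the bite direction is a unit vector.  ``extra_dofs`` may
    pin additional scalar dofs (3*node + axis), e.g. roller supports in the
    verification benchmarks, with optional prescribed ``extra_values``.
    """

    fixed_nodes: np.ndarray
    bite_nodes: np.ndarray | None = None
    bite_direction: np.ndarray | None = None
    fixed_values: np.ndarray | None = None
    extra_dofs: np.ndarray | None = None
    extra_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)
        if self.bite_nodes is not None:
            self.bite_nodes = np.asarray(self.bite_nodes, dtype=int)
            if self.bite_direction is None:
                raise LoadingError("bite_nodes given without bite_direction")
            d = np.asarray(self.bite_direction, dtype=float)
            n = np.linalg.norm(d)
            if not n > 0:
                raise LoadingError("bite_direction must be a non-zero vector")
            self.bite_direction = d / n
            if np.intersect1d(self.fixed_nodes, self.bite_nodes).size:
                raise LoadingError("fixed and bite node sets must be disjoint")

    @property
    def n_scalar_constraints(self) -> int:
        n = 3 * len(self.fixed_nodes)
        if self.bite_nodes is not None:
            n += len(self.bite_nodes)
        return n


def _patch_face_areas_per_node(mesh: FEMesh, patch_voxels: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Exposed-face area share per patch surface node (area-weighted option).

    Each exterior face of a patch element contributes a quarter of its area
    to each of its four corner nodes.
    """
    solid = np.zeros(mesh.grid_shape, dtype=bool)
    solid[tuple(mesh.elem_voxels.T)] = True
    padded = np.pad(solid, 1, constant_values=False)
    pv = np.atleast_2d(patch_voxels)
    weight = np.zeros(mesh.n_nodes)
    node_lut = {}  # (i,j,k) corner -> node id
    dims = (mesh.grid_shape[0] + 1, mesh.grid_shape[1] + 1, mesh.grid_shape[2] + 1)
    lin_ids = np.ravel_multi_index(tuple(mesh.node_ijk.T), dims)
    node_lut = dict(zip(lin_ids.tolist(), range(mesh.n_nodes)))
    face_area = mesh.spacing**2
    face_corner_offsets = {
        (0, -1): [(0, 0, 0), (0, 1, 0), (0, 0, 1), (0, 1, 1)],
        (0, +1): [(1, 0, 0), (1, 1, 0), (1, 0, 1), (1, 1, 1)],
        (1, -1): [(0, 0, 0), (1, 0, 0), (0, 0, 1), (1, 0, 1)],
        (1, +1): [(0, 1, 0), (1, 1, 0), (0, 1, 1), (1, 1, 1)],
        (2, -1): [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)],
        (2, +1): [(0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)],
    }
    for (axis, side), offsets in face_corner_offsets.items():
        shift = np.zeros(3, dtype=int)
        shift[axis] = side
        nb = pv + shift
        exposed = ~padded[nb[:, 0] + 1, nb[:, 1] + 1, nb[:, 2] + 1]
        for off in offsets:
            corners = pv[exposed] + np.asarray(off)
            lin = np.ravel_multi_index(tuple(corners.T), dims)
            for l in lin:
                weight[node_lut[int(l)]] += face_area / 4.0
    w = weight[nodes]
    return w


def build_load_case(
    grid: VoxelGrid,
    annotation: MandibleAnnotation,
    mesh: FEMesh,
    muscles: list[MuscleSpec],
    constants: PhysioConstants | None = None,
    distribution: str = "equal",
) -> LoadCase:
    """Construct the nodal force table for a set of muscles.

    For each muscle the unit pull direction is normalize(origin - attachment
    patch centroid) and the total force is split across the patch's surface
    nodes — equally by default, or in proportion to exposed face area with
    ``distribution="area"``.
    """
    constants = constants or PhysioConstants()
    forces = np.zeros((mesh.n_nodes, 3))
    totals: dict[str, tuple[float, np.ndarray]] = {}
    for m in muscles:
        if m.patch_name not in annotation.muscle_patches:
            raise LoadingError(f"{m.name}: patch {m.patch_name!r} not in annotation")
        patch = np.atleast_2d(annotation.muscle_patches[m.patch_name])
        if len(patch) == 0:
            raise LoadingError(f"{m.name}: attachment patch is empty")
        nodes = mesh.patch_nodes(patch, surface_only=True)
        if len(nodes) == 0:
            raise LoadingError(f"{m.name}: patch has no surface nodes")
        centroid = grid.voxel_centers(patch).mean(axis=0)
        vec = m.origin_point - centroid
        norm = np.linalg.norm(vec)
        if norm < 1e-9:
            raise LoadingError(f"{m.name}: origin coincides with attachment centroid")
        direction = vec / norm
        F = m.force(constants)
        if distribution == "equal":
            w = np.full(len(nodes), 1.0 / len(nodes))
        elif distribution == "area":
            areas = _patch_face_areas_per_node(mesh, patch, nodes)
            if areas.sum() <= 0:
                raise LoadingError(f"{m.name}: patch exposes no surface area")
            w = areas / areas.sum()
        else:
            raise LoadingError(f"unknown distribution {distribution!r}")
        forces[nodes] += F * w[:, None] * direction[None, :]
        totals[m.name] = (F, direction)
    return LoadCase(forces=forces, totals=totals)


def build_constraints(
    grid: VoxelGrid,
    annotation: MandibleAnnotation,
    mesh: FEMesh,
    bite_mode: str = "point",
) -> ConstraintSet:
    """TMJ surface nodes fixed in x, y, z; incisor-tip surface nodes
    constrained along the occlusal-plane normal (the bite direction).

    ``bite_mode`` "point" (default) constrains the single surface node at
    the occlusal (chisel) edge of the tip — a point bite contact that
    transmits force but no couple, so the bite reaction has a well-defined
    line of action; "patch" constrains every surface node of the tip patch
    (which on a stiff tooth also clamps its rotation).
    """
    for side in ("left", "right"):
        if side not in annotation.tmj_patches or len(annotation.tmj_patches[side]) == 0:
            raise LoadingError(f"missing TMJ patch {side!r}")
    if annotation.incisor_tip_patch is None or len(annotation.incisor_tip_patch) == 0:
        raise LoadingError("missing incisor tip patch")
    tmj_nodes = np.unique(
        np.concatenate(
            [mesh.patch_nodes(annotation.tmj_patches[s]) for s in ("left", "right")]
        )
    )
    tip_nodes = mesh.patch_nodes(annotation.incisor_tip_patch)
    tip_nodes = np.setdiff1d(tip_nodes, tmj_nodes)
    if bite_mode == "point":
        c = mesh.node_coords[tip_nodes]
        order = np.lexsort((c[:, 0], -c[:, 2]))  # highest, then most anterior
        tip_nodes = tip_nodes[order[:1]]
    elif bite_mode != "patch":
        raise LoadingError(f"unknown bite_mode {bite_mode!r}")
    normal = annotation.occlusal_frame[2]
    return ConstraintSet(fixed_nodes=tmj_nodes, bite_nodes=tip_nodes, bite_direction=normal)
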