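"""Parametric synthetic voxel mandibles and solver benchmark geometries.

The generator emulates, at desk scale, what microCT segmentation of a
diprotodont (rodent-like) mandible provides: a two-material voxel grid in
which an elongated, continually growing incisor follows a circular arc
through an arched corpus, its internal "root" reaching to or past the end
of the molar row, with a posterior ramus bearing coronoid, condylar and
angular processes.  Alongside the grid it returns a
:class:`MandibleAnnotation` naming every geometric feature the downstream
analysis needs: the labial margin of the incisor (along which root length
is measured), the alveolar margin, the molar-row extent, TMJ and incisor
tip patches, muscle attachment patches with cranial origin landmarks, the
occlusal frame (whose normal is the bite direction) and the ventral-margin
path used for landmark placement.

World frame: x anteroposterior (anterior low), y mediolateral (symmetric
about 0), z dorsoventral (dorsal up); units mm.  The occlusal plane of the
post-incisor dentition is horizontal, so the bite direction is +z.

Benchmark geometries (beam, arch, cantilever) share the same grid type and
carry simple support/load annotations for solver verification and the
arch-versus-beam bending experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .voxel_model import Label, VoxelGrid, largest_component


class GeometryError(ValueError):
    """Invalid or degenerate generator parameters."""


class ResolutionError(GeometryError):
    """Voxel spacing too coarse to resolve the incisor tube."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class MandibleParams:
    """Parameters of the synthetic mandible (all lengths mm, angles degrees).

    The incisor is a tapered tube along a circular arc in the sagittal
    plane.  ``tip_angle_deg`` locates the erupted tip on the arc circle
    (angles measured counter-clockwise from +x about the arc centre);
    ``erupted_arc_deg`` and ``root_arc_deg`` split the tube into the
    erupted segment and the internal root, so the root fraction of the
    whole tube is root/(root+erupted).  Defaults give a rat-scale jaw
    (~30 mm long) whose internal root ends just past the molar row and
    whose ventral profile has a rise-to-span ratio of ~0.12.
    """

    spacing: float = 0.25
    # incisor arc
    arc_radius: float = 22.0
    arc_center_x: float = 13.2
    arc_center_z: float = 24.7
    tip_angle_deg: float = 232.0
    erupted_arc_deg: float = 13.0
    root_arc_deg: float = 56.0
    r_tip: float = 1.7
    r_root: float = 0.8
    # corpus
    corpus_thickness: float = 0.9
    symphysis_thickness: float = 1.7
    corpus_halfwidth: float = 2.7
    occlusal_z: float = 7.0
    molar_start_x: float = 10.0
    molar_end_x: float = 22.5
    corpus_end_x: float = 23.8
    # ramus
    ramus_x0: float = 23.0
    ramus_x1: float = 29.5
    ramus_halfwidth: float = 1.3
    coronoid_z: float = 12.8
    notch_z: float = 9.5
    condyle_z: float = 11.2
    condyle_halfwidth: float = 2.4
    angular_z: float = 0.8
    # stochastic surface jitter (probability of removing a surface bone voxel)
    jitter: float = 0.0
    seed: int = 0

    @property
    def alveolar_angle_deg(self) -> float:
        return self.tip_angle_deg + self.erupted_arc_deg

    @property
    def end_angle_deg(self) -> float:
        return self.tip_angle_deg + self.erupted_arc_deg + self.root_arc_deg

    @property
    def root_extent(self) -> float:
        """Arc-length fraction of the incisor tube lying internal."""
        return self.root_arc_deg / (self.erupted_arc_deg + self.root_arc_deg)

    def validate(self) -> None:
        if not self.spacing > 0:
            raise GeometryError("spacing must be > 0")
        for name in ("arc_radius", "corpus_thickness", "corpus_halfwidth"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0")
        if self.r_tip < 0 or self.r_root < 0:
            raise GeometryError("incisor radii must be >= 0")
        if not (0 < self.root_arc_deg and 0 <= self.erupted_arc_deg):
            raise GeometryError("arc extents must be positive")
        if not (0.0 <= self.jitter <= 1.0):
            raise GeometryError("jitter must be in [0, 1]")
        rmin = min(self.r_tip, self.r_root)
        if rmin > 0 and 2 * rmin < 2 * self.spacing:
            raise ResolutionError(
                f"incisor tube ({2 * rmin:.3g} mm across) is under 2 voxels at "
                f"spacing {self.spacing} mm"
            )

    def tube_radius_at(self, angle_deg: np.ndarray) -> np.ndarray:
        """Tapered tube radius, linear in arc angle from tip to root end."""
        t = (np.asarray(angle_deg) - self.tip_angle_deg) / (
            self.end_angle_deg - self.tip_angle_deg
        )
        return self.r_tip + (self.r_root - self.r_tip) * np.clip(t, 0.0, 1.0)

    def shell_at(self, angle_deg: np.ndarray) -> np.ndarray:
        """Cortical wall thickness around the root: robust at the symphysis
        (alveolar region, roughly the anterior third of the corpus), tapering
        to the thin posterior corpus wall."""
        t = (np.asarray(angle_deg) - self.alveolar_angle_deg) / (
            0.3 * self.root_arc_deg
        )
        t = np.clip(t, 0.0, 1.0)
        return self.symphysis_thickness + (self.corpus_thickness - self.symphysis_thickness) * t


#: Archetype presets approximating relative internal root lengths: a
#: squirrel-like jaw with the root somewhat past the molar row, a rat-like
#: default, and a beaver-like jaw with a markedly longer root.
PRESETS: dict[str, dict] = {
    "rat": {},
    "squirrel": {"root_arc_deg": 58.0},
    "beaver": {"root_arc_deg": 62.0, "r_tip": 1.8, "r_root": 0.9},
}


def preset_params(name: str, **overrides) -> MandibleParams:
    if name not in PRESETS:
        raise GeometryError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return MandibleParams(**kwargs)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class MandibleAnnotation:
    """Named geometric features of a (synthetic or imported) mandible model.

    Point and polyline fields are world coordinates in mm; patches are
    ``(k, 3)`` integer voxel-index arrays lying on the model surface.
    """

    labial_margin: np.ndarray  # (m, 3) polyline, tip -> deepest root point
    alveolar_margin_point: np.ndarray  # (3,)
    molar_posterior_point: np.ndarray  # (3,)
    incisor_tip_patch: np.ndarray  # (k, 3) voxel indices
    tmj_patches: dict[str, np.ndarray]  # "left"/"right"
    muscle_patches: dict[str, np.ndarray]
    muscle_origins: dict[str, np.ndarray]
    occlusal_frame: np.ndarray  # (3, 3) rows: anteroposterior, transverse, normal
    ventral_path: np.ndarray  # (m, 3) anterior -> posterior
    root_arc_length: float  # bookkeeping: labial root length by construction

    def bite_direction(self) -> np.ndarray:
        return self.occlusal_frame[2]

    def to_json(self, path: str | Path) -> Path:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v

        payload = {k: conv(v) for k, v in self.__dict__.items()}
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "MandibleAnnotation":
        raw = json.loads(Path(path).read_text())
        int_fields = {"incisor_tip_patch"}

        def arr(name, v):
            dtype = int if name in int_fields or name.endswith("patches") else float
            return np.asarray(v, dtype=dtype)

        kwargs = {}
        for k, v in raw.items():
            if isinstance(v, dict):
                dtype = int if k.endswith("patches") else float
                kwargs[k] = {kk: np.asarray(vv, dtype=dtype) for kk, vv in v.items()}
            elif isinstance(v, list):
                kwargs[k] = arr(k, v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# mandible generation
# ---------------------------------------------------------------------------

def _interp_profile(x: np.ndarray, knots: list[tuple[float, float]]) -> np.ndarray:
    kx = np.array([k[0] for k in knots])
    kz = np.array([k[1] for k in knots])
    return np.interp(x, kx, kz)


def generate_mandible(params: MandibleParams | None = None) -> tuple[VoxelGrid, MandibleAnnotation]:
    """Build the synthetic two-material mandible grid and its annotation.

    Deterministic for fixed (params, seed); the returned grid is a single
    connected component.
    """
    p = params or MandibleParams()
    p.validate()
    h = p.spacing
    xc, zc, R = p.arc_center_x, p.arc_center_z, p.arc_radius
    b_tip, b_alv, b_end = (
        np.deg2rad(p.tip_angle_deg),
        np.deg2rad(p.alveolar_angle_deg),
        np.deg2rad(p.end_angle_deg),
    )
    shell = max(p.corpus_thickness, p.symphysis_thickness)

    # --- grid bounds -------------------------------------------------------
    bs = np.linspace(b_tip, b_end, 200)
    rs = p.tube_radius_at(np.rad2deg(bs)) + shell
    env_x = xc + (R + rs) * np.cos(bs)
    env_x2 = xc + (R - rs) * np.cos(bs)
    env_z = zc + (R + rs) * np.sin(bs)
    env_z2 = zc + (R - rs) * np.sin(bs)
    pad = 2 * h
    xmin = min(env_x.min(), env_x2.min()) - pad
    xmax = max(p.ramus_x1, env_x.max(), env_x2.max()) + pad
    ymax = max(p.corpus_halfwidth, p.condyle_halfwidth, p.r_tip + shell) + pad
    zmin = min(env_z.min(), env_z2.min(), p.angular_z - 0.5) - pad
    zmax = max(p.coronoid_z, env_z.max(), env_z2.max(), p.occlusal_z) + pad
    origin = np.array([xmin, -ymax, zmin])
    n = np.ceil((np.array([xmax, ymax, zmax]) - origin) / h).astype(int)
    nx, ny, nz = (int(v) for v in n)

    x = origin[0] + h * (np.arange(nx) + 0.5)
    y = origin[1] + h * (np.arange(ny) + 0.5)
    z = origin[2] + h * (np.arange(nz) + 0.5)
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    # --- sagittal arc geometry --------------------------------------------
    dx, dz = X - xc, Z - zc
    rho = np.sqrt(dx**2 + dz**2)  # (nx, 1, nz)
    beta = np.arctan2(dz, dx)
    beta = np.where(beta < 0, beta + 2 * np.pi, beta)  # [0, 2pi); arc well inside
    in_arc = (beta >= b_tip) & (beta <= b_end)
    r_at = p.tube_radius_at(np.rad2deg(beta))
    d_ring = np.abs(rho - R)
    d3 = np.sqrt(d_ring**2 + Y**2)  # distance to arc (within angular range)

    tip_pt = np.array([xc + R * np.cos(b_tip), 0.0, zc + R * np.sin(b_tip)])
    end_pt = np.array([xc + R * np.cos(b_end), 0.0, zc + R * np.sin(b_end)])
    d_tip = np.sqrt((X - tip_pt[0]) ** 2 + Y**2 + (Z - tip_pt[2]) ** 2)
    d_end = np.sqrt((X - end_pt[0]) ** 2 + Y**2 + (Z - end_pt[2]) ** 2)

    incisor = np.zeros((nx, ny, nz), dtype=bool)
    if max(p.r_tip, p.r_root) > 0:
        incisor = (in_arc & (d3 <= r_at)) | (d_tip <= p.r_tip) | (d_end <= p.r_root)

    # --- bone: shell around the root + corpus body + ramus -----------------
    shell_b = p.shell_at(np.rad2deg(beta))
    bone_shell = (in_arc & (beta >= b_alv) & (d3 <= r_at + shell_b)) | (
        d_end <= p.r_root + p.corpus_thickness
    )

    alv_labial = np.array(
        [
            xc + (R + p.tube_radius_at(p.alveolar_angle_deg)) * np.cos(b_alv),
            0.0,
            zc + (R + p.tube_radius_at(p.alveolar_angle_deg)) * np.sin(b_alv),
        ]
    )
    x_alv = alv_labial[0]
    # lower branch of the arc circle (defined where |x - xc| <= R), and the
    # tube radius/shell thickness along it
    under = np.clip(R**2 - (x - xc) ** 2, 0.0, None)
    z_arc_low = zc - np.sqrt(under)
    beta_low = np.arctan2(z_arc_low - zc, x - xc)
    beta_low = np.where(beta_low < 0, beta_low + 2 * np.pi, beta_low)
    r_low = p.tube_radius_at(np.rad2deg(beta_low))
    # dorsal profile: alveolar rim, then the low diastema waist hugging the
    # incisor, rising to the molar platform at the occlusal plane
    plat = _interp_profile(
        x,
        [
            (x_alv, alv_labial[2] + 1.0),
            (x_alv + 2.0, 4.3),
            (p.molar_start_x - 1.5, 4.3),
            (p.molar_start_x, p.occlusal_z),
            (p.corpus_end_x, p.occlusal_z),
        ],
    )
    z_dorsal = np.maximum(plat, z_arc_low + r_low + 0.6)
    # the corpus is a full-width arched block housing the tube: its ventral
    # margin follows the incisor arc offset by tube radius + cortical shell
    z_corpus_bottom = z_arc_low - (r_low + p.shell_at(np.rad2deg(beta_low)))
    corpus = (
        (X >= x_alv)
        & (X <= p.corpus_end_x)
        & (np.abs(Y) <= p.corpus_halfwidth)
        & (Z >= z_corpus_bottom[:, None, None])
        & (Z <= z_dorsal[:, None, None])
    )
    # symphyseal prow ("chin"): the corpus continues a few mm anterior of the
    # alveolar margin below the erupted incisor, separated from the tooth's
    # exposed labial face by an air gap so the alveolar rim stays where the
    # labial margin meets bone
    chin_gap = 0.7
    chin_top = z_arc_low - r_low - chin_gap
    chin_floor = float(np.interp(x_alv, x, z_corpus_bottom))
    under_tooth = Z <= chin_top[:, None, None]
    # lateral trough walls cradle the erupted incisor without touching it
    beside_tooth = (np.abs(Y) >= (r_low + 0.5)[:, None, None]) & (
        Z <= z_arc_low[:, None, None]
    )
    chin = (
        (X >= x_alv - 3.0)
        & (X < x_alv)
        & (np.abs(Y) <= p.corpus_halfwidth)
        & (Z >= chin_floor)
        & (under_tooth | beside_tooth)
    )
    corpus = corpus | chin

    top_knots = [
        (p.ramus_x0, 8.0),
        (p.ramus_x0 + 1.0, p.coronoid_z),
        (p.ramus_x0 + 1.8, p.coronoid_z),
        (p.ramus_x0 + 3.0, p.notch_z),
        (p.ramus_x0 + 4.2, p.condyle_z),
        (p.ramus_x1 - 0.7, p.condyle_z),
        (p.ramus_x1, p.condyle_z - 1.0),
    ]
    bot_knots = [
        (p.ramus_x0, 2.8),
        (p.ramus_x0 + 2.5, 2.0),
        (p.ramus_x0 + 3.5, p.angular_z),
        (p.ramus_x1 - 0.5, p.angular_z),
        (p.ramus_x1, p.angular_z + 0.7),
    ]
    z_top = _interp_profile(x, top_knots)
    z_bot = _interp_profile(x, bot_knots)
    cond_x0 = p.ramus_x0 + 4.0
    halfwidth = np.where(
        (x >= cond_x0)[:, None, None] & (Z >= p.notch_z),
        p.condyle_halfwidth,
        p.ramus_halfwidth,
    )
    ramus = (
        (X >= p.ramus_x0)
        & (X <= p.ramus_x1)
        & (np.abs(Y) <= halfwidth)
        & (Z >= z_bot[:, None, None])
        & (Z <= z_top[:, None, None])
    )

    bone = (bone_shell | corpus | ramus) & ~incisor

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[bone] = Label.BONE
    labels[incisor] = Label.INCISOR
    grid = VoxelGrid(labels, h, origin)

    if p.jitter > 0:
        from .voxel_model import surface_voxel_mask

        rng = np.random.default_rng(p.seed)
        surf = surface_voxel_mask(grid) & (grid.labels == Label.BONE)
        drop = surf & (rng.random(grid.shape) < p.jitter)
        grid.labels[drop] = Label.VOID

    grid, dropped = largest_component(grid, connectivity=6)
    if dropped > 0.01 * grid.n_solid:
        raise GeometryError(f"geometry disconnected: dropped {dropped} voxels")

    annotation = _annotate(grid, p)
    _check_annotation(grid, annotation)
    return grid, annotation


def _annotate(grid: VoxelGrid, p: MandibleParams) -> MandibleAnnotation:
    h = p.spacing
    xc, zc, R = p.arc_center_x, p.arc_center_z, p.arc_radius
    b_tip, b_alv, b_end = (
        np.deg2rad(p.tip_angle_deg),
        np.deg2rad(p.alveolar_angle_deg),
        np.deg2rad(p.end_angle_deg),
    )

    # labial margin polyline: outer (convex) margin of the tube, with the
    # alveolar margin as an exact vertex
    bs = np.concatenate(
        [
            np.linspace(b_tip, b_alv, 40, endpoint=False),
            np.linspace(b_alv, b_end, 360),
        ]
    )
    r_out = R + p.tube_radius_at(np.rad2deg(bs))
    labial = np.column_stack(
        [xc + r_out * np.cos(bs), np.zeros_like(bs), zc + r_out * np.sin(bs)]
    )
    alv_idx = 40  # first vertex of the second segment
    seg = np.linalg.norm(np.diff(labial, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    root_len = float(cum[-1] - cum[alv_idx])
    alveolar_point = labial[alv_idx].copy()

    molar_posterior = np.array([p.molar_end_x, 0.0, p.occlusal_z])

    # voxel-center coordinate axes
    nxg, nyg, nzg = grid.shape
    x = grid.origin[0] + h * (np.arange(nxg) + 0.5)
    z = grid.origin[2] + h * (np.arange(nzg) + 0.5)
    jmid = int(np.argmin(np.abs(grid.origin[1] + h * (np.arange(nyg) + 0.5))))
    ymid = grid.origin[1] + h * (jmid + 0.5)

    # ventral path: lowest bone voxel in the midline column at each x station
    # between the alveolar margin and the posterior end of the molar row
    cols = np.where((x >= alveolar_point[0]) & (x <= molar_posterior[0]))[0]
    pts = []
    bone_mid = grid.labels[:, jmid, :] == Label.BONE
    for i in cols:
        ks = np.where(bone_mid[i])[0]
        if len(ks):
            pts.append([x[i], ymid, z[ks.min()]])
    ventral_path = np.asarray(pts)
    if len(ventral_path) < 2:
        raise GeometryError("ventral path could not be traced")

    # incisor tip patch: the occlusal (chisel) edge of the erupted tip — the
    # dorsal sliver of the distal end cap.  Keeping the patch compact also
    # keeps the bite constraint point-like, so it cannot transmit a spurious
    # couple through the statically indeterminate per-node reactions.
    iv = np.argwhere(grid.labels == Label.INCISOR)
    if len(iv) == 0:  # degenerate zero-radius tube: no tooth, no tip patch
        tip_patch = np.zeros((0, 3), dtype=int)
    else:
        ctr = grid.voxel_centers(iv)
        beta_v = np.arctan2(ctr[:, 2] - zc, ctr[:, 0] - xc)
        beta_v = np.where(beta_v < 0, beta_v + 2 * np.pi, beta_v)
        cap = beta_v <= b_tip + 1.5 * h / R
        if not cap.any():
            raise GeometryError("incisor tip patch is empty")
        cap_ctr = ctr[cap]
        apex = cap_ctr[np.argmax(cap_ctr[:, 2])]
        edge = cap & (np.linalg.norm(ctr - apex, axis=1) <= 0.75 * h)
        tip_patch = iv[edge]

    # TMJ patches: top surface layer of the condylar head, split left/right
    from .voxel_model import surface_voxel_mask

    surf_mask = surface_voxel_mask(grid)
    sv = np.argwhere(grid.solid_mask() & surf_mask)
    svc = grid.voxel_centers(sv)
    cond = (
        (svc[:, 0] >= p.ramus_x0 + 4.2)
        & (svc[:, 0] <= p.ramus_x1 - 0.7)
        & (svc[:, 2] >= p.condyle_z - 1.5 * h)
    )
    tmj = sv[cond]
    tmjc = svc[cond]
    tmj_patches = {"left": tmj[tmjc[:, 1] < 0], "right": tmj[tmjc[:, 1] >= 0]}
    if min(len(v) for v in tmj_patches.values()) == 0:
        raise GeometryError("TMJ patch is empty on one side")

    # muscle patches: spherical surface caps at plausible ramus sites,
    # claimed in a fixed order so the patches are disjoint by construction
    surf = np.argwhere(surf_mask & (grid.labels == Label.BONE))
    surfc = grid.voxel_centers(surf)
    sites = {
        "temporalis": (np.array([p.ramus_x0 + 1.3, 0.0, p.coronoid_z - 0.2]), 1.5),
        "zygomatico_mandibularis": (np.array([p.ramus_x0 + 2.0, 0.0, p.notch_z - 0.3]), 1.2),
        "deep_masseter": (np.array([p.ramus_x0 + 3.3, 0.0, 6.2]), 1.4),
        "superficial_masseter": (np.array([p.ramus_x0 + 2.8, 0.0, p.angular_z + 0.5]), 1.5),
        "medial_pterygoid": (np.array([p.ramus_x1 - 0.9, 0.0, p.angular_z + 0.7]), 1.4),
    }
    claimed = np.zeros(len(surf), dtype=bool)
    tmj_set = set(map(tuple, np.concatenate(list(tmj_patches.values()))))
    in_tmj = np.fromiter((tuple(v) in tmj_set for v in surf), dtype=bool, count=len(surf))
    muscle_patches = {}
    for name, (site, radius) in sites.items():
        m = (np.linalg.norm(surfc - site, axis=1) <= radius) & ~claimed & ~in_tmj
        if not m.any():
            raise GeometryError(f"muscle patch {name!r} is empty")
        muscle_patches[name] = surf[m]
        claimed |= m

    muscle_origins = {
        "superficial_masseter": np.array([8.0, 0.0, 12.0]),
        "deep_masseter": np.array([14.0, 0.0, 14.0]),
        "zygomatico_mandibularis": np.array([18.0, 0.0, 14.0]),
        "temporalis": np.array([20.0, 0.0, 20.0]),
        "medial_pterygoid": np.array([22.0, 0.0, 12.0]),
    }

    frame = np.eye(3)  # rows: anteroposterior (+x), transverse (+y), normal (+z)

    return MandibleAnnotation(
        labial_margin=labial,
        alveolar_margin_point=alveolar_point,
        molar_posterior_point=molar_posterior,
        incisor_tip_patch=tip_patch,
        tmj_patches=tmj_patches,
        muscle_patches=muscle_patches,
        muscle_origins=muscle_origins,
        occlusal_frame=frame,
        ventral_path=ventral_path,
        root_arc_length=root_len,
    )


def _check_annotation(grid: VoxelGrid, ann: MandibleAnnotation) -> None:
    """Assert annotation-grid coherence for every generated model."""
    has_incisor = bool((grid.labels == Label.INCISOR).any())
    all_patches = [("incisor_tip", ann.incisor_tip_patch)] if has_incisor else []
    all_patches += [(f"tmj_{k}", v) for k, v in ann.tmj_patches.items()]
    all_patches += list(ann.muscle_patches.items())
    seen: set[tuple[int, int, int]] = set()
    for name, patch in all_patches:
        if len(patch) == 0:
            raise GeometryError(f"patch {name!r} is empty")
        if (grid.labels[tuple(np.atleast_2d(patch).T)] == Label.VOID).any():
            raise GeometryError(f"patch {name!r} contains VOID voxels")
        tset = set(map(tuple, np.atleast_2d(patch)))
        if seen & tset and not name.startswith("tmj"):
            raise GeometryError(f"patch {name!r} overlaps another patch")
        seen |= tset
    if not np.linalg.norm(np.diff(ann.labial_margin, axis=0), axis=1).sum() > 0:
        raise GeometryError("labial margin has zero length")
    nrm = np.linalg.norm(ann.occlusal_frame[2])
    if not np.isclose(nrm, 1.0):
        raise GeometryError("occlusal normal is not a unit vector")


def default_muscle_table() -> pd.DataFrame:
    """Generic rodent-scale muscle table (masses g, fibre lengths mm).

    Invented rat-scale magnitudes giving ~45 N of total muscle force;
    origin landmarks sit dorsal/anterior of the ramus on a virtual cranium.
    """
    origins = {
        "superficial_masseter": (8.0, 0.0, 12.0),
        "deep_masseter": (14.0, 0.0, 14.0),
        "zygomatico_mandibularis": (18.0, 0.0, 14.0),
        "temporalis": (20.0, 0.0, 20.0),
        "medial_pterygoid": (22.0, 0.0, 12.0),
    }
    rows = [
        ("superficial_masseter", 0.35, 7.0),
        ("deep_masseter", 0.25, 6.0),
        ("zygomatico_mandibularis", 0.12, 5.0),
        ("temporalis", 0.18, 8.0),
        ("medial_pterygoid", 0.12, 6.0),
    ]
    return pd.DataFrame(
        [
            {
                "name": name,
                "patch_name": name,
                "mass_g": mass,
                "fiber_length_mm": fl,
                "origin_x_mm": origins[name][0],
                "origin_y_mm": origins[name][1],
                "origin_z_mm": origins[name][2],
            }
            for name, mass, fl in rows
        ]
    )


def analytic_incisor_volume(params: MandibleParams) -> float:
    """Analytic volume (mm^3) of the tapered incisor tube plus end caps."""
    p = params
    bs = np.linspace(np.deg2rad(p.tip_angle_deg), np.deg2rad(p.end_angle_deg), 2000)
    r = p.tube_radius_at(np.rad2deg(bs))
    tube = np.trapezoid(np.pi * r**2 * p.arc_radius, bs)
    caps = 2.0 / 3.0 * np.pi * (p.r_tip**3 + p.r_root**3)
    return float(tube + caps)


# ---------------------------------------------------------------------------
# benchmark geometries
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkAnnotation:
    """Support and load patches for beam/arch/cantilever benchmarks.

    ``support_faces``/``load_face`` give the (axis, side) of the geometric
    face each patch acts on, so constraints and loads can be applied to the
    face node plane rather than every corner node of the voxel layer.
    """

    support_patches: dict[str, np.ndarray]  # name -> (k, 3) voxel indices
    load_patch: np.ndarray  # (k, 3)
    load_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    midspan_x: float = 0.0
    support_faces: dict[str, tuple[int, int]] = field(default_factory=dict)
    load_face: tuple[int, int] = (2, 1)


def _box_counts(length: float, depth: float, width: float, spacing: float) -> tuple[int, int, int]:
    if min(length, depth, width, spacing) <= 0:
        raise GeometryError("all benchmark dimensions must be > 0")
    return (
        int(round(length / spacing)),
        int(round(width / spacing)),
        int(round(depth / spacing)),
    )


def generate_beam(
    length: float, depth: float, width: float, spacing: float
) -> tuple[VoxelGrid, BenchmarkAnnotation]:
    """Rectangular BONE beam: x along the span, z the depth, y the width.

    Support patches are the bottom voxel rows at each end; the load patch is
    the top row(s) at midspan (symmetric about the midspan plane).
    """
    nx, ny, nz = _box_counts(length, depth, width, spacing)
    labels = np.full((nx, ny, nz), int(Label.BONE), dtype=np.uint8)
    grid = VoxelGrid(labels, spacing)
    supports = {
        "left": np.array([[0, j, 0] for j in range(ny)]),
        "right": np.array([[nx - 1, j, 0] for j in range(ny)]),
    }
    mid = [nx // 2 - 1, nx // 2] if nx % 2 == 0 else [nx // 2]
    load = np.array([[i, j, nz - 1] for i in mid for j in range(ny)])
    return grid, BenchmarkAnnotation(
        support_patches=supports,
        load_patch=load,
        midspan_x=spacing * nx / 2.0,
        support_faces={"left": (2, -1), "right": (2, -1)},
        load_face=(2, 1),
    )


def generate_cantilever(
    length: float, depth: float, width: float, spacing: float
) -> tuple[VoxelGrid, BenchmarkAnnotation]:
    """Cantilever: full fixed end face at x = 0, tip patch = opposite face."""
    nx, ny, nz = _box_counts(length, depth, width, spacing)
    labels = np.full((nx, ny, nz), int(Label.BONE), dtype=np.uint8)
    grid = VoxelGrid(labels, spacing)
    fixed = np.array([[0, j, k] for j in range(ny) for k in range(nz)])
    tip = np.array([[nx - 1, j, k] for j in range(ny) for k in range(nz)])
    return grid, BenchmarkAnnotation(
        support_patches={"fixed": fixed},
        load_patch=tip,
        midspan_x=spacing * nx / 2.0,
        support_faces={"fixed": (0, -1)},
        load_face=(0, 1),
    )


def generate_arch(
    span: float, rise: float, depth: float, width: float, spacing: float
) -> tuple[VoxelGrid, BenchmarkAnnotation]:
    """Circular-arc bar of constant cross-section between springings at z=0.

    The arc midline passes through (0, 0) and (span, 0) with crown height
    ``rise``; the bar occupies the ring band of thickness ``depth`` around
    it, cut flat at the bar underside z = -depth/2 (so the flat limit
    ``rise -> 0`` recovers a straight beam of the same cross-section).
    Supports are the bottom voxel layers at the two springing points; the
    load patch is the outer crown surface.
    """
    if min(span, depth, width, spacing) <= 0 or rise < 0:
        raise GeometryError("all arch dimensions must be > 0 (rise >= 0)")
    if rise >= span / 2:
        raise GeometryError(f"rise ({rise}) must be < span/2 ({span / 2})")
    h = spacing
    rise_eff = max(rise, 1e-9)
    Rc = (rise_eff**2 + (span / 2.0) ** 2) / (2.0 * rise_eff)
    cx, cz = span / 2.0, rise_eff - Rc
    pad = h
    origin = np.array([-pad, -width / 2.0, -depth / 2.0])
    nx = int(np.ceil((span + 2 * pad) / h))
    ny = int(round(width / h))
    nz = int(np.ceil((rise_eff + depth + pad) / h))
    x = origin[0] + h * (np.arange(nx) + 0.5)
    z = origin[2] + h * (np.arange(nz) + 0.5)
    X, Z = x[:, None], z[None, :]
    ring = np.abs(np.sqrt((X - cx) ** 2 + (Z - cz) ** 2) - Rc) <= depth / 2.0
    sag = ring & (X >= 0.0) & (X <= span)
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[:, :, :] = np.where(sag[:, None, :], int(Label.BONE), int(Label.VOID))
    grid = VoxelGrid(labels, h, origin)
    grid, _ = largest_component(grid, connectivity=6)

    solid = np.argwhere(grid.solid_mask())
    ctr = grid.voxel_centers(solid)
    bottom = ctr[:, 2] <= origin[2] + h  # first voxel layer above the flat cut
    supports = {
        "left": solid[bottom & (ctr[:, 0] < span / 2.0)],
        "right": solid[bottom & (ctr[:, 0] >= span / 2.0)],
    }
    top = (np.abs(ctr[:, 0] - span / 2.0) <= 0.8 * h + 1e-12) & (
        ctr[:, 2] >= rise_eff + depth / 2.0 - 1.3 * h
    )
    load = solid[top]
    if len(load) == 0 or min(len(v) for v in supports.values()) == 0:
        raise GeometryError("arch support/load patches are empty; refine spacing")
    return grid, BenchmarkAnnotation(
        support_patches=supports,
        load_patch=load,
        midspan_x=span / 2.0,
        support_faces={"left": (2, -1), "right": (2, -1)},
        load_face=(2, 1),
    )


def arch_midline_length(span: float, rise: float) -> float:
    """Arc length of the arch midline (for materially equivalent beams)."""
    rise_eff = max(rise, 1e-9)
    Rc = (rise_eff**2 + (span / 2.0) ** 2) / (2.0 * rise_eff)
    return float(2.0 * Rc * np.arcsin(min(1.0, span / (2.0 * Rc))))


def generate_matched_pair(
    span: float, rise: float, depth: float, width: float, spacing: float
) -> tuple[
    tuple[VoxelGrid, BenchmarkAnnotation], tuple[VoxelGrid, BenchmarkAnnotation]
]:
    """Materially equivalent (beam, arch) pair: identical cross-section and
    element counts within 2%.

    The beam length is chosen so its element count matches the voxelised
    arch (the arch midline length, corrected to the nearest voxel layer).
    """
    arch = generate_arch(span, rise, depth, width, spacing)
    n_arch = arch[0].n_solid
    ny = int(round(width / spacing))
    nz = int(round(depth / spacing))
    nxb = max(1, int(round(n_arch / (ny * nz))))
    beam = generate_beam(nxb * spacing, depth, width, spacing)
    n_beam = beam[0].n_solid
    if abs(n_arch - n_beam) / n_beam > 0.02:
        raise GeometryError(
            f"matched pair differs by more than 2%: arch {n_arch}, beam {n_beam}"
        )
    return beam, arch
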