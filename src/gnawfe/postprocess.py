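"""Measurement layer: ventral-margin stress profiles, cross-sections,
variant comparisons and the arch-versus-beam bending experiment.

Quantitative comparison across the five variant models follows the
landmark protocol: n (default 20) landmarks at equal arc-length intervals
along the ventral mandibular margin between the alveolar margin and the
posteriormost point of the molar row, at which the von Mises stress of the
nearest surface element is recorded.  Variant effects are expressed as the
percent change relative to the unaltered model at the same landmark.

Principal strains 1 and 3 are examined on a dorso-ventral cross-section
taken perpendicular to the occlusal plane's anteroposterior axis,
immediately (one voxel by default) posterior to the molar row.

The arch-versus-beam experiment quantifies how much an arched bar of
identical cross-section and material lowers the internal bending moment at
its crown, relative to a straight beam's midspan, under central three-point
loading with both supports restrained vertically and horizontally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import variant_builder
from .hexfem import FEMesh, FESolution, build_mesh, reactions_and_bite_force, solve
from .loading import (
    ConstraintSet,
    LoadCase,
    PhysioConstants,
    build_constraints,
    build_load_case,
    read_muscle_table,
)
from .synthetic_mandible import (
    BenchmarkAnnotation,
    MandibleAnnotation,
    MandibleParams,
    default_muscle_table,
    generate_mandible,
    generate_matched_pair,
)
from .voxel_model import Label, MaterialTable, VoxelGrid, write_vtk


class PostprocessError(ValueError):
    pass


class SamplingError(PostprocessError):
    pass


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkProfile:
    """Landmark points along the ventral margin plus per-variant von Mises
    values (MPa)."""

    points: np.ndarray  # (n, 3) world mm
    von_mises_values: dict[int, np.ndarray] = field(default_factory=dict)  # model_index -> (n,)

    @property
    def n(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "landmark": np.arange(1, self.n + 1),
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
            }
        )
        for idx in sorted(self.von_mises_values):
            df[f"model_{idx}_MPa"] = self.von_mises_values[idx]
        return df


def _resample_polyline(path: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, path.shape[1]))
    for d in range(path.shape[1]):
        out[:, d] = np.interp(targets, cum, path[:, d])
    return out


def place_landmarks(
    annotation: MandibleAnnotation, n: int = 20, anchor_tol: float | None = None
) -> LandmarkProfile:
    """n points at equal arc-length intervals along the ventral path between
    the alveolar margin and the posteriormost molar point (inclusive).

    The ventral path must span exactly that segment: its endpoints must lie
    at the two anchors' anteroposterior stations (within ``anchor_tol``,
    default 2 mm) or an :class:`AnnotationError` is raised.
    """
    if n < 2:
        raise PostprocessError("need at least 2 landmarks")
    path = np.asarray(annotation.ventral_path, dtype=float)
    if len(path) < 2:
        raise variant_builder.AnnotationError("ventral path has fewer than 2 points")
    tol = 2.0 if anchor_tol is None else anchor_tol
    ap = annotation.occlusal_frame[0]
    s0 = float(path[0] @ ap)
    s1 = float(path[-1] @ ap)
    a0 = float(np.asarray(annotation.alveolar_margin_point) @ ap)
    a1 = float(np.asarray(annotation.molar_posterior_point) @ ap)
    if abs(s0 - a0) > tol or abs(s1 - a1) > tol:
        raise variant_builder.AnnotationError(
            "ventral path endpoints do not lie at the alveolar-margin / "
            f"posterior-molar stations (offsets {abs(s0 - a0):.2f}, {abs(s1 - a1):.2f} mm)"
        )
    return LandmarkProfile(points=_resample_polyline(path, n))


def sample_von_mises(
    solution: FESolution, points: np.ndarray, max_dist_voxels: float = 2.0
) -> np.ndarray:
    """Von Mises stress (MPa) of the surface element whose centroid is
    nearest each point (ties resolved to the lowest element index)."""
    mesh = solution.mesh
    surf = np.where(mesh.surface_element_mask())[0]
    centroids = mesh.element_centroids()[surf]
    tree = cKDTree(centroids)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist, idx = tree.query(pts)
    if np.any(dist > max_dist_voxels * mesh.spacing):
        worst = float(dist.max())
        raise SamplingError(
            f"point {worst:.3g} mm from the nearest surface element "
            f"(limit {max_dist_voxels} voxels)"
        )
    return solution.von_mises[surf[idx]]


def sample_mean_von_mises(
    solution: FESolution, points: np.ndarray, radius: float
) -> np.ndarray:
    """Mean von Mises over surface elements within ``radius`` mm of each
    point (robustness alternative to nearest-element sampling)."""
    mesh = solution.mesh
    surf = np.where(mesh.surface_element_mask())[0]
    centroids = mesh.element_centroids()[surf]
    tree = cKDTree(centroids)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        hits = tree.query_ball_point(p, radius)
        if not hits:
            raise SamplingError(f"no surface elements within {radius} mm of point {i}")
        out[i] = float(solution.von_mises[surf[hits]].mean())
    return out


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------

@dataclass
class CrossSection:
    """Dorso-ventral slice of element-centroid principal strains.

    ``e1_map``/``e3_map`` are 2-D (transverse x dorsoventral) arrays over
    the section plane, NaN outside the model; ``incisor_footprint`` marks
    elements labeled INCISOR in the sliced model.
    """

    plane_point: np.ndarray
    plane_normal: np.ndarray
    element_ids: np.ndarray
    e1_map: np.ndarray
    e3_map: np.ndarray
    incisor_footprint: np.ndarray  # bool, same shape as the maps

    def values(self, which: str = "e1") -> np.ndarray:
        m = self.e1_map if which == "e1" else self.e3_map
        return m[np.isfinite(m)]


def section_element_ids(mesh: FEMesh, point: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Elements whose centroid lies within half a voxel of the plane.

    The slab is half-open (-h/2 <= d < h/2) so a plane lying exactly on a
    voxel-layer boundary selects a single element layer, never two.
    """
    c = mesh.element_centroids()
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = (c - np.asarray(point, dtype=float)) @ normal
    half = mesh.spacing / 2.0
    return np.where((d >= -half) & (d < half))[0]


def extract_cross_section(
    solution: FESolution,
    annotation: MandibleAnnotation,
    offset_voxels: float = 1.0,
) -> CrossSection:
    """Slice immediately posterior to the molar row, perpendicular to the
    occlusal anteroposterior axis, mapping principal strains 1 and 3."""
    mesh = solution.mesh
    ap = np.asarray(annotation.occlusal_frame[0], dtype=float)
    point = np.asarray(annotation.molar_posterior_point, dtype=float) + (
        offset_voxels * mesh.spacing
    ) * ap
    ids = section_element_ids(mesh, point, ap)
    if len(ids) == 0:
        raise PostprocessError("cross-section plane misses the model")
    # 2-D maps indexed by the in-plane voxel coordinates (transverse, dorsoventral)
    vox = mesh.elem_voxels[ids]
    j, k = vox[:, 1], vox[:, 2]
    j0, k0 = j.min(), k.min()
    shape = (j.max() - j0 + 1, k.max() - k0 + 1)
    e1 = np.full(shape, np.nan)
    e3 = np.full(shape, np.nan)
    foot = np.zeros(shape, dtype=bool)
    e1[j - j0, k - k0] = solution.principal_strains[ids, 0]
    e3[j - j0, k - k0] = solution.principal_strains[ids, 2]
    foot[j - j0, k - k0] = mesh.elem_labels[ids] == Label.INCISOR
    return CrossSection(
        plane_point=point,
        plane_normal=ap,
        element_ids=ids,
        e1_map=e1,
        e3_map=e3,
        incisor_footprint=foot,
    )


# ---------------------------------------------------------------------------
# variant comparison
# ---------------------------------------------------------------------------

@dataclass
class VariantComparison:
    """Per-landmark percent change of each variant against model 1."""

    percent_change: dict[int, np.ndarray]  # model_index -> (n,), NaN where undefined
    max_relative_increase: dict[int, float]  # % per variant
    threshold_indices: dict[int, int]  # landmark index (0-based) over the cut

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "percent_change": {k: list(v) for k, v in self.percent_change.items()},
            "max_relative_increase": self.max_relative_increase,
            "threshold_indices": self.threshold_indices,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, default=float))
        return path


def compare_variants(
    profile: LandmarkProfile,
    cut_points: dict[int, np.ndarray] | None = None,
    baseline_index: int = 1,
) -> VariantComparison:
    """Percent change per landmark vs the unaltered model.

    change = 100 (sigma_variant - sigma_model1) / sigma_model1; landmarks
    where the baseline is zero are flagged NaN and excluded from the max.
    ``cut_points`` (variant -> world cut position) yields each variant's
    threshold landmark: the landmark nearest the cut along the
    anteroposterior axis.
    """
    if baseline_index not in profile.von_mises_values:
        raise PostprocessError(f"profile lacks baseline model {baseline_index}")
    base = profile.von_mises_values[baseline_index]
    pct: dict[int, np.ndarray] = {}
    mri: dict[int, float] = {}
    for idx, vals in profile.von_mises_values.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            change = 100.0 * (vals - base) / base
        change = np.where(base == 0.0, np.nan, change)
        pct[idx] = change
        finite = change[np.isfinite(change)]
        mri[idx] = float(finite.max()) if len(finite) else float("nan")
    thresholds: dict[int, int] = {}
    if cut_points:
        xs = profile.points[:, 0]
        for idx, cp in cut_points.items():
            thresholds[idx] = int(np.argmin(np.abs(xs - float(np.asarray(cp)[0]))))
    return VariantComparison(
        percent_change=pct, max_relative_increase=mri, threshold_indices=thresholds
    )


# ---------------------------------------------------------------------------
# section bending moment (arch vs beam)
# ---------------------------------------------------------------------------

def section_bending_moment(
    solution: FESolution,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    neutral_reference: np.ndarray | None = None,
) -> float:
    """Internal bending moment (N mm) carried by a cross-section.

    Integrates the axial stress sigma_nn over elements within half a voxel
    of the plane, with lever arm about a horizontal transverse axis through
    ``neutral_reference`` (default: the section's area centroid).  Sign
    convention: sagging (top fibres in compression) is positive for a
    section normal along +x with z up.
    """
    mesh = solution.mesh
    normal = np.asarray(plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ids = section_element_ids(mesh, plane_point, normal)
    if len(ids) == 0:
        raise PostprocessError("section plane misses the model")
    c = mesh.element_centroids()[ids]
    ref = c.mean(axis=0) if neutral_reference is None else np.asarray(neutral_reference, float)
    s = solution.element_stress[ids]  # Voigt xx, yy, zz, xy, yz, zx
    nxx, nyy, nzz = normal**2
    nxy, nyz, nzx = (
        2 * normal[0] * normal[1],
        2 * normal[1] * normal[2],
        2 * normal[2] * normal[0],
    )
    sigma_nn = (
        s[:, 0] * nxx + s[:, 1] * nyy + s[:, 2] * nzz
        + s[:, 3] * nxy + s[:, 4] * nyz + s[:, 5] * nzx
    )
    area = mesh.spacing**2
    lever = c[:, 2] - ref[2]
    return float(-np.sum(sigma_nn * area * lever))


def arch_beam_experiment(
    span: float,
    rise: float,
    depth: float,
    width: float,
    spacing: float,
    load: float = 10.0,
    materials: MaterialTable | None = None,
    tol: float = 1e-8,
) -> dict:
    """Three-point bending of a materially equivalent beam/arch pair.

    Both structures carry the same central load; both supports are
    restrained vertically and horizontally (all three axes) at their bottom
    faces.  Returns the crown/midspan internal moments and the percent
    moment reduction 100 (|M_beam| - |M_arch|) / |M_beam|.
    """
    materials = materials or MaterialTable.default()
    (beam_grid, beam_ann), (arch_grid, arch_ann) = generate_matched_pair(
        span, rise, depth, width, spacing
    )

    def _solve_bench(grid: VoxelGrid, ann: BenchmarkAnnotation) -> tuple[FESolution, float]:
        mesh = build_mesh(grid)
        fixed = np.unique(
            np.concatenate(
                [
                    mesh.patch_face_nodes(p, *ann.support_faces[name])
                    for name, p in ann.support_patches.items()
                ]
            )
        )
        constraints = ConstraintSet(fixed_nodes=fixed)
        load_nodes = mesh.patch_face_nodes(ann.load_patch, *ann.load_face)
        forces = np.zeros((mesh.n_nodes, 3))
        forces[load_nodes] = load / len(load_nodes) * ann.load_direction
        sol = solve(mesh, materials, LoadCase(forces=forces), constraints, tol=tol)
        moment = section_bending_moment(
            sol,
            plane_point=np.array([ann.midspan_x, 0.0, 0.0]),
            plane_normal=np.array([1.0, 0.0, 0.0]),
        )
        return sol, moment

    beam_sol, m_beam = _solve_bench(beam_grid, beam_ann)
    arch_sol, m_arch = _solve_bench(arch_grid, arch_ann)
    reduction = 100.0 * (abs(m_beam) - abs(m_arch)) / abs(m_beam)
    return {
        "span_mm": span,
        "rise_mm": rise,
        "rise_to_span": rise / span,
        "n_elements_beam": beam_grid.n_solid,
        "n_elements_arch": arch_grid.n_solid,
        "moment_beam_Nmm": m_beam,
        "moment_arch_Nmm": m_arch,
        "moment_reduction_pct": reduction,
    }


def corpus_section_dims(grid: VoxelGrid, annotation: MandibleAnnotation) -> dict:
    """Dorsoventral depth and mediolateral width (mm) of the corpus
    cross-section at the mid ventral-path station — the natural bar
    cross-section for the arch-versus-beam comparison."""
    path = np.asarray(annotation.ventral_path, dtype=float)
    xmid = path[len(path) // 2, 0]
    h = grid.spacing
    c = grid.voxel_centers(np.argwhere(grid.solid_mask()))
    slab = np.abs(c[:, 0] - xmid) <= h / 2.0
    if not slab.any():
        raise PostprocessError("mid-corpus section is empty")
    depth = float(c[slab, 2].max() - c[slab, 2].min() + h)
    width = float(c[slab, 1].max() - c[slab, 1].min() + h)
    return {"depth_mm": depth, "width_mm": width, "station_x_mm": float(xmid)}


def ventral_profile_arch(annotation: MandibleAnnotation) -> dict:
    """Span, rise and rise-to-span ratio of the mandible's ventral profile
    (maximum sagitta of the ventral path below its end-to-end chord)."""
    path = np.asarray(annotation.ventral_path, dtype=float)
    a, b = path[0], path[-1]
    chord = b - a
    span = float(np.linalg.norm(chord))
    t = (path - a) @ chord / span**2
    closest = a + np.clip(t, 0, 1)[:, None] * chord
    sag = np.linalg.norm(path - closest, axis=1)
    rise = float(sag.max())
    return {"span_mm": span, "rise_mm": rise, "rise_to_span": rise / span}


# ---------------------------------------------------------------------------
# end-to-end experiment driver
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Configuration of the full five-variant biting experiment."""

    params: MandibleParams = field(default_factory=MandibleParams)
    muscle_table: pd.DataFrame | str | Path | None = None  # default synthetic table
    constants: PhysioConstants = field(default_factory=PhysioConstants)
    materials: MaterialTable = field(default_factory=MaterialTable.default)
    n_landmarks: int = 20
    tol: float = 1e-8
    section_offset_voxels: float = 1.0
    distribution: str = "equal"
    write_fields: bool = True
    make_plots: bool = True


@dataclass
class ExperimentResult:
    grid: VoxelGrid
    annotation: MandibleAnnotation
    profile: LandmarkProfile
    comparison: VariantComparison
    sections: dict[int, CrossSection]
    bite_forces: dict[int, float]
    probe_von_mises: dict[str, dict[int, float]]
    solutions: dict[int, FESolution]
    manifest: list[dict]


def probe_points(annotation: MandibleAnnotation) -> dict[str, np.ndarray]:
    """Far-field probe points (coronoid process, condylar region): the patch
    voxel nearest each patch's own centroid, guaranteed on the surface."""
    out = {}
    for name, patch in (
        ("coronoid", annotation.muscle_patches["temporalis"]),
        ("condyle", np.concatenate(list(annotation.tmj_patches.values()))),
    ):
        patch = np.atleast_2d(patch)
        ctr = patch.mean(axis=0)
        out[name] = patch[np.argmin(np.linalg.norm(patch - ctr, axis=1))]
    return out


def run_experiment(
    config: ExperimentConfig | None = None, outdir: str | Path | None = None
) -> ExperimentResult:
    """Generate the mandible, build and solve the five-variant suite, and
    extract landmark profiles, comparisons and cross-sections.

    When ``outdir`` is given, writes per-variant VTK fields, the landmark
    CSV, comparison JSON, suite manifest, run log and (optionally) plots.
    """
    cfg = config or ExperimentConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    grid, annotation = generate_mandible(cfg.params)
    if cfg.muscle_table is None:
        muscles = read_muscle_table(default_muscle_table())
    else:
        muscles = read_muscle_table(cfg.muscle_table)

    suite = variant_builder.build_model_suite(grid, annotation)
    manifest = variant_builder.suite_manifest(grid, annotation)
    profile = place_landmarks(annotation, n=cfg.n_landmarks)
    probes = probe_points(annotation)

    sections: dict[int, CrossSection] = {}
    bite_forces: dict[int, float] = {}
    probe_vm: dict[str, dict[int, float]] = {name: {} for name in probes}
    solutions: dict[int, FESolution] = {}

    for variant_grid, spec in suite:
        mesh = build_mesh(variant_grid)
        loads = build_load_case(
            variant_grid, annotation, mesh, muscles, cfg.constants, cfg.distribution
        )
        constraints = build_constraints(variant_grid, annotation, mesh)
        sol = solve(mesh, cfg.materials, loads, constraints, tol=cfg.tol)
        solutions[spec.model_index] = sol
        profile.von_mises_values[spec.model_index] = sample_von_mises(sol, profile.points)
        _, bite_forces[spec.model_index] = reactions_and_bite_force(sol, constraints)
        sections[spec.model_index] = extract_cross_section(
            sol, annotation, cfg.section_offset_voxels
        )
        for name, pv in probes.items():
            pt = variant_grid.voxel_centers(pv)[0]
            probe_vm[name][spec.model_index] = float(sample_von_mises(sol, pt[None, :])[0])
        if outdir is not None and cfg.write_fields:
            write_vtk(
                variant_grid,
                outdir / f"model_{spec.model_index}.vtk",
                fields={
                    "von_mises": sol.field_on_grid(sol.von_mises, fill=0.0),
                    "principal_strains": sol.field_on_grid(sol.principal_strains, fill=0.0),
                },
            )

    cut_points = {
        rec["model_index"]: np.asarray(rec["cut_point_mm"])
        for rec in manifest
        if "cut_point_mm" in rec
    }
    comparison = compare_variants(profile, cut_points=cut_points)

    if outdir is not None:
        profile.to_frame().to_csv(outdir / "landmark_profiles.csv", index=False)
        comparison.to_json(outdir / "comparison.json")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log = {
            "params": {k: (v if not isinstance(v, np.ndarray) else v.tolist()) for k, v in vars(cfg.params).items()},
            "seed": cfg.params.seed,
            "tol": cfg.tol,
            "n_landmarks": cfg.n_landmarks,
            "distribution": cfg.distribution,
            "bite_forces_N": bite_forces,
            "probe_von_mises_MPa": probe_vm,
            "solver_reports": {k: s.solver_report for k, s in solutions.items()},
        }
        (outdir / "run_log.json").write_text(json.dumps(log, default=float, indent=1))
        if cfg.make_plots:
            _write_plots(outdir, profile, comparison, sections)

    return ExperimentResult(
        grid=grid,
        annotation=annotation,
        profile=profile,
        comparison=comparison,
        sections=sections,
        bite_forces=bite_forces,
        probe_von_mises=probe_vm,
        solutions=solutions,
        manifest=manifest,
    )


def _write_plots(
    outdir: Path,
    profile: LandmarkProfile,
    comparison: VariantComparison,
    sections: dict[int, CrossSection],
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    lm = np.arange(1, profile.n + 1)
    for idx in sorted(profile.von_mises_values):
        ax.plot(lm, profile.von_mises_values[idx], marker="o", ms=3, label=f"model {idx}")
    for idx, t in comparison.threshold_indices.items():
        ax.axvline(t + 1, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("ventral landmark (anterior to posterior)")
    ax.set_ylabel("von Mises stress (MPa)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "landmark_profiles.png", dpi=150)
    plt.close(fig)

    for which, cmap in (("e1", "magma"), ("e3", "viridis_r")):
        fig, axes = plt.subplots(1, len(sections), figsize=(3 * len(sections), 3))
        axes = np.atleast_1d(axes)
        for ax, (idx, sec) in zip(axes, sorted(sections.items())):
            m = sec.e1_map if which == "e1" else sec.e3_map
            ax.imshow(m.T, origin="lower", cmap=cmap)
            if sec.incisor_footprint.any():
                ax.contour(sec.incisor_footprint.T, levels=[0.5], colors="k", linestyles="--")
            ax.set_title(f"model {idx}", fontsize=9)
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(outdir / f"cross_section_{which}.png", dpi=150)
        plt.close(fig)
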