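# Methods

## The model

`gnawfe` simulates incisal biting in a diprotodont (rodent-like) mandible
with voxel-based finite elements, and asks what the long internal incisor
"root" contributes mechanically. The workflow mirrors the standard
comparative-biomechanics protocol for this question:

1. a two-material voxel model of a hemifused mandible — cortical bone plus
   a continually growing incisor whose unerupted portion runs through the
   corpus to the end of the molar row or beyond;
2. five model variants: the intact jaw (model 1); the internal root
   shortened to 50% or 25% of its length with the removed dental tissue
   replaced by cortical bone (models 2, 3) or left as an empty, air-filled
   crypt (models 4, 5). Root length is measured anteroposteriorly along the
   outer (labial) margin of the incisor from the alveolar margin to the
   deepest point of the root;
3. muscle loads from physiological cross-sectional area (PCSA): for each
   masticatory muscle, PCSA = (mass / 1.0564 g cm⁻³) / fibre length and
   force = PCSA × 0.3 N mm⁻², pulling from the centroid of the mandibular
   attachment patch toward a cranial origin landmark;
4. constraints: both temporomandibular joints fixed in x, y, z; the incisor
   tip constrained along the bite direction, the normal to the occlusal
   plane of the post-incisor dentition. The bite force emerges as the
   reaction at the tip constraint;
5. linear isotropic elasticity solved on the voxel mesh (one eight-noded
   hexahedral element per solid voxel; E = 17 GPa, ν = 0.3 for bone,
   E = 55 GPa, ν = 0.32 for the incisor);
6. outputs: von Mises stress at 20 landmarks spaced equally along the
   ventral margin between the alveolar margin and the posteriormost molar
   point; per-landmark percent change of each variant against model 1;
   principal strains ε1/ε3 on a dorso-ventral cross-section immediately
   posterior to the molar row; and an arch-versus-beam three-point-bending
   comparison quantifying how much the jaw's arched profile lowers the
   internal bending moment.

Assumptions shared with the experimental design this emulates: the model is
solid (no cancellous bone, pulp or enamel/dentine distinction), there is no
periodontal ligament — the tooth is fused to bone wherever voxels meet —
and the analysis is linear and static. Conclusions therefore rest on
*relative* comparisons between variants of the same jaw, not on absolute
stress magnitudes.

## The synthetic mandible

The generator (`synthetic_mandible`) produces, at desk scale, the geometric
structure that microCT segmentation of a real specimen would supply. The
incisor is a tapered tube (default radius 1.7 mm at the erupted tip to
0.8 mm at the growing apex — hypselodont roots thin strongly toward the
apex) following a circular arc (radius 22 mm) in the sagittal plane; the
split of the tube into erupted segment and internal root is parametric,
with the root ending just past the molar row by default. The corpus is a
full-width arched block housing the tube: its ventral margin follows the
arc offset by tube radius plus cortical wall, giving the characteristic
arched profile (measured rise-to-span ≈ 0.09). The cortical wall is robust
at the symphysis (1.7 mm, tapering to 0.9 mm over the anterior third of the
root), the dorsal profile dips into a diastema waist hugging the incisor
before rising to the molar platform at the occlusal plane, and a symphyseal
prow with lateral trough walls cradles the erupted tooth. The posterior
ramus carries coronoid, condylar and angular processes, with a transversely
widened condylar head whose top surface forms the left/right TMJ patches.

Muscle attachment patches (superficial and deep masseter,
zygomatico-mandibularis, temporalis, medial pterygoid) are spherical
surface caps at plausible ramus sites, claimed in a fixed order so they are
disjoint; the default muscle table is an invented rodent-scale set (masses
0.12–0.35 g, fibres 5–8 mm, ≈ 45 N total force, bite force ≈ 6 N). The
bite contact is a *point*: the single surface node at the occlusal (chisel)
edge of the erupted tip. A broader z-constrained tip patch on a 55 GPa
tooth acts as a rotational clamp — it absorbs a large part of the bite
moment as a statically indeterminate couple, which both distorts the
anterior moment distribution and makes anterior stresses wander between
variants. A point contact transmits force but no couple, so the internal
moment along the corpus is set by statics alone (`bite_mode="patch"`
remains available).

What the generator does *not* emulate: real cortical-thickness maps,
cancellous architecture, the curvature of the occlusal surface, asymmetry,
species-specific muscle geometry, or the fine anatomy of the symphysis.
Passing tests on this geometry show that the pipeline reproduces the
*mechanical logic* of the root-shortening experiment — they are not
evidence about any particular species.

## Numerical choices

* **Mesh/solver.** Direct voxel conversion to axis-aligned cube elements;
  assembled sparse CSR stiffness; Jacobi-preconditioned conjugate gradients
  to a relative residual of 1e-8 (sparse LU available for small systems and
  exactness checks). Dirichlet constraints are imposed by row/column
  elimination and are satisfied exactly; an oblique bite direction is
  handled by rotating the bite nodes' degrees of freedom so the constrained
  direction becomes a coordinate axis.
* **Element.** The default element is the hex8 with three Wilson
  incompatible bending modes, statically condensed (2×2×2 Gauss
  quadrature). On cube meshes the Jacobian is constant, so the element
  passes the patch test exactly while removing the parasitic shear
  stiffness of the plain trilinear element, which we measured at 13% tip-
  deflection error on a 40×4×4 cantilever (0.9% with incompatible modes).
  The plain fully integrated element remains available
  (`formulation="plain"`).
* **Recovery.** Strains and stresses are recovered at element centroids
  only, where the bubble-mode gradients vanish; principal strains are
  eigenvalues of the centroid strain tensor, sorted descending.
* **Sampling.** Landmark values take the von Mises stress of the surface
  element whose centroid is nearest the landmark (ties to the lowest
  element index); a mean-over-radius alternative exists. Cross-sections
  select elements whose centroid lies within half a voxel of the plane,
  half-open so a plane on a voxel boundary never selects two layers.
* **Section moments.** Internal bending moment = −Σ σ_nn · h² · (z − z̄)
  over the section's elements, about the transverse axis through the
  section's area centroid; sagging positive for a +x normal with z up.
* **Degenerate inputs.** A zero-radius incisor yields a valid all-bone
  model with no tip patch; spacing too coarse to resolve the tube (< 2
  voxels across) raises a resolution error; constraint sets that leave
  rigid-body modes are rejected before assembly with the free modes named.

## Study conditions and problem sizes

The default study runs the five-variant experiment on the default mandible
at 0.25 mm spacing (≈ 55 000 elements, ≈ 230 000 degrees of freedom,
≈ 2 400 CG iterations per solve); the unit-test fixtures use 0.5 mm. The
arch-versus-beam experiment voxelises a materially equivalent beam/arch
pair at 0.25 mm (≈ 42 000 elements each) with the rise-to-span ratio taken
from the mandible's ventral profile and the bar cross-section from its
mid-corpus section, both supports fixed in all three axes at their bottom
faces, and equal central loads; it reports the percent reduction in the
crown/midspan internal moment, measured at 22.0% under these conditions.

## Design choices that were genuinely open

* Cut surface for root shortening: an incisor voxel's arc-length
  coordinate is that of its nearest labial-margin vertex, so the cut is
  approximately perpendicular to the local tooth axis. The crypt removes
  only tooth voxels; the alveolar wall is never touched.
* The air-filled crypt is represented as VOID (no elements), the
  conventional voxel-FE treatment of air.
* Muscle force is split equally across the attachment patch's surface
  nodes (area-weighted division is available as a robustness option).
* Far-field landmarks in the localization check exclude the threshold
  landmark and its immediate anterior neighbour: the stress jump at a cut
  physically spreads over about one corpus depth, which at 20-landmark
  spacing is one to two landmarks.

## Known limitations

* The threshold-spike magnitude scales with the local internal moment,
  which under a point incisal bite grows posteriorly along the corpus. The
  50%-cut variants therefore hand off a somewhat larger tooth-carried
  moment at their (more posterior) cut face than the 25% variants do at
  theirs. In this synthetic geometry the measured consequence is that
  model 4's peak relative increase (+48.9%) slightly exceeds model 5's
  (+45.7%), and model 5's peak falls just short of +50%; in the real
  specimens this balance evidently favours the quarter-root crypt model.
  The corresponding checks in the acceptance suite are left failing with
  this explanation rather than adjusting geometry to chase them.
* Percent changes at landmarks with very low baseline stress are ratios of
  small numbers; the far-field stability results should be read together
  with the absolute changes (two orders of magnitude below the
  removed-region changes).
* The arch-versus-beam moment reduction is sensitive to the bar
  cross-section (stockier sections develop proportionally less arch
  thrust); the corpus-section definition used here is stated above and in
  the code.
* Muscle patch placement is schematic; sensitivity to patch position has
  not been quantified and should not be assumed negligible.
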