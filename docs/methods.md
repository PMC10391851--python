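# Methods

## Scope and claims

`cervifem` is a desk-scale static linear-elasticity simulator for comparing
three anterior cervical constructs (ACDF, ACCF, modified ACDF with partial
vertebral osteotomy) across WHO bone-quality groups and axial preloads. The
geometry is an idealized parametric stand-in for a subject-specific CT
segmentation. Consequently the package does **not reproduce** absolute
stress or displacement magnitudes, or the statistic/p-values, of any
CT-derived model — those depend on individual anatomy, surface smoothing,
and meshing. What it does claim, and what the test suite verifies, is
**qualitative** structure: the ordering of constructs by superior-surface
displacement (ACDF < Mod ACDF < ACCF), the monotone effect of bone loss,
exact proportionality to load in the linear model, and the localization of
stress concentrations (osteotomy-notch corners; posterior half of the C6
surface after corpectomy).

## Geometry

Axis-aligned voxel grid, default 1 mm voxels; x mediolateral, y
anteroposterior (anterior positive), z cranio-caudal (cranial positive).
Each vertebral body is 24 × 16 × 12 mm: one-voxel bony endplates top and
bottom, a one-voxel cortical shell, cancellous core. Discs are 5 mm: one-voxel
cartilaginous endplates above and below, an annulus ring, and a central
nucleus occupying ≈ 40 % of the cross-section. These are typical subaxial
dimensions and are fully configurable (`SegmentSpec`). Posterior elements
(laminae, facets) are omitted: the load path studied is axial through the
body/implant column, and the monitored observable is the body surface.

Surgical edits are boolean relabelings:

* **ACDF** (2-level C4–C5 stack): the C4/5 disc and both cartilaginous
  endplates become air; a 5 × 14 × 16 mm PEEK cage is centred mediolaterally,
  1 mm from the anterior body edge; a 1 × 20 × 16 mm titanium plate sits
  flush on the anterior face with two 4 × 14 mm screws per vertebra reaching
  cancellous bone. No bone is resected.
* **ACCF** (3-level C4–C6 stack): both discs removed; a full-depth,
  full-height central channel through C5; a hollow titanium cylinder
  (OD 10 / ID 8 mm → 1 mm wall) spans from the C6 superior endplate to the C4
  inferior endplate, 1 mm from the anterior edge; three-level plate + screws
  into C4 and C6.
* **Mod ACDF**: the ACDF edit plus a rectangular notch, 8 mm (ML) × 9 mm
  (AP, measured forward from the posterior margin), cut from the C5 superior
  surface to half the body height. Only bone is removed; a zero-size notch
  reproduces ACDF exactly.

Rasterization choices worth noting:

* Mediolateral implant/resection widths are rasterized to **even** voxel
  counts so every construct is mirror-symmetric about the mid-sagittal plane
  (asserted voxel-wise in tests). The 15 mm corpectomy channel therefore
  becomes 14 mm (within the one-voxel rasterization tolerance). The narrower
  choice is deliberate a second way: with fully resected discs the lateral
  C5 remnant columns are load-connected only through the anterior plate, and
  a 14 mm channel leaves a 1 mm overlap between the 16 mm plate and each
  column, keeping the remnant tied into the construct.
* The titanium mesh's catalog length (50 mm) exceeds the C4–C6 defect
  (22 mm at default geometry) and is truncated to the defect. For the same
  reason the printed three-level plate height (22 mm) cannot reach C4 and C6
  screw anchorage across a 46 mm stack; the plate is extended to span
  mid-C6 to mid-C4 (34 mm). The two-level 20 mm plate is used as printed.
* Screw axes sit ±6 mm from the midline: symmetric, within the plate
  footprint, and clear of the 8 mm osteotomy notch.
* The notch depth is not a printed quantity; the default is half the body
  height and it is configurable (`SurgicalPlan.notch_depth`).

All interfaces — bone/implant included — are **tied** (shared nodes). This
collapses frictionless articulating contact and bonded fusion interfaces
into one linear model; it is the principal fidelity gap, and it biases the
model stiff (no relative sliding, no gap opening).

## Materials

Isotropic linear elasticity per role (MPa): cortical 12000/0.30, cancellous
450/0.25, bony endplate = cortical, cartilaginous endplate 25/0.40, annulus
4.2/0.45, nucleus 1/0.50, titanium (mesh/plate/screw) 110000/0.36, PEEK cage
3600/0.30. The nucleus' ν = 0.5 is singular for a displacement formulation
and is clamped to 0.499 with a warning; the nucleus only exists in the
intact model, so no production grid cell contains it. An articular-cartilage
role exists for completeness but carries no default constants (reported
values for this tissue vary by an order of magnitude) and the default
geometry never uses it.

Bone quality scales only the bone roles: cortical/endplate ×0.67 for both
OPA and OPS, cancellous ×0.67 (OPA) and ×0.33 (OPS), rounded half-up to
whole MPa (8040, 302, 149). The tabulated values are stored as the source of
truth and the arithmetic rule is cross-checked against them in tests.
Degradation is defined relative to the **normal** group; the alternative
reading (relative to OPS) is inconsistent with the stored table.

## Discretization and solver

Trilinear 8-node hexahedra, one per voxel, full 2×2×2 Gauss quadrature; no
reduced integration or hourglass control is needed at unit aspect ratio.
Because all elements are congruent cubes, one 24×24 stiffness per material
suffices, and centroid strain equals the Gauss average, so stress recovery is
a single matrix product per element. Verification (all in the suite):

* patch test — affine boundary displacement reproduced interior-exact
  (< 1e−10);
* uniaxial bar δ = FL/EA and σ = −F/A to < 0.5 % (machine precision in
  practice: the affine solution is exact for this element);
* two-material stacked bar = springs in series;
* element eigenstructure: symmetric, six rigid-body zero modes;
* mesh refinement leaves the affine bar solution unchanged (< 0.1 %).

Dirichlet constraints (inferior surface of the monitored vertebra fully
fixed) are applied by row/column elimination, so reactions are exact; the
reduced SPD system is factorized once per surgery × bone-quality family with
sparse LU and reused across the three loads (the matrix is identical;
linearity is separately asserted to 1e−10). The free-dof residual must be
≤ 1e−10 relative and the reaction sum balances the applied load to ≤ 1e−8
relative in every cell. The axial load is lumped over the superior C4
surface by tributary area (1:2:4 corner:edge:interior on the regular grid)
and normalized to the exact total.

Default problem sizes: ~10 700 elements / 37 500 dof (two-level constructs),
~12 900 elements / 46 600 dof (ACCF). The full 27-cell grid runs in roughly
three minutes on one CPU.

## Monitored points and summaries

The observable is the superior surface of the caudal monitored vertebra (C5;
C6 for ACCF): its topmost remaining bone layer. Per cell two channels of
"16 points of maximum variation" are selected deterministically — the 16
surface elements with the largest Von Mises stress, and separately the 16
with the largest displacement magnitude — with ties broken by lexicographic
(z, y, x) centroid order, coordinates logged. Cell summaries are mean ± SD
(n−1) over the matching channel, displacements in µm. The figure-point
layout of any particular external model is *not* claimed to be recovered;
the selection here is algorithmic so that it is exactly reproducible.

## Statistics

Comparisons mirror the factorial design (across loads within surgery ×
quality; across qualities within surgery × load; across surgeries within
quality × load). Groups are screened per-sample with Shapiro–Wilk at
α = 0.05: one-way ANOVA if all pass, else Kruskal–Wallis (tie-corrected H).
For small pooled samples (n ≤ 13) the Kruskal–Wallis p-value is exact, by
enumeration of all distinct assignments of the pooled observations to the
groups; it is validated against an exhaustive raw-permutation oracle to
three decimals. Pairwise post-hoc tests (t or two-group rank) are
Bonferroni-adjusted, labelled as such in the output. A Monte-Carlo
calibration (1000 seeded null replicates, 3 × 16 standard normals) keeps the
omnibus type-I error at 0.05 ± 0.02.

The 16 monitored points are spatial samples of one deterministic field, not
independent replicates; every report carries this pseudo-replication caveat,
and the package draws no inferential conclusions from these tests — they are
descriptive summaries of spatial variation.

## Known limitations

* Tied interfaces: no contact separation or sliding; graft/bone interface
  micromotion (a real subsidence driver) is not represented.
* Rectangular body cross-sections, no posterior column, no ligaments; only
  axial compression is modelled — no flexion/extension/rotation, no
  destructive load search, no dynamics.
* Voxel resolution limits geometric fidelity of cylinders (mesh, screws) to
  ± one voxel; all printed implant dimensions rasterize within one voxel.
* Absolute magnitudes are geometry-bound and are not validated against any
  external subject-specific model; only the qualitative trend suite is.
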