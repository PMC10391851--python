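"""Idealized voxel geometry of a C4-C6 cervical segment and its surgical edits.

The vertebral bodies are layered rectangular blocks (cortical shell around a
cancellous core, bony endplates top and bottom) stacked with intervertebral
discs (annulus ring with a central nucleus, cartilaginous endplates above and
below). Posterior elements are omitted: the load path studied is axial through
the body/implant column.

Three constructs are applied as boolean edits of the label grid:

* ACDF      - C4/5 discectomy, PEEK interbody cage, two-level anterior plate
              with four screws;
* ACCF      - C4/5 + C5/6 discectomy, central C5 corpectomy channel, hollow
              titanium mesh cylinder, three-level anterior plate with screws
              into C4 and C6;
* Mod ACDF  - ACDF plus a rectangular partial osteotomy of the superior,
              posterior C5 body (default 8 mm mediolateral x 9 mm
              anteroposterior, to mid-body depth).

Coordinate convention: x = mediolateral (left positive), y = anteroposterior
(anterior positive), z = cranio-caudal (cranial positive). Voxel indices are
0-based; the label grid is indexed ``labels[i, j, k]`` = (x, y, z). All
interfaces are tied (adjacent voxels share element faces and therefore nodes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .materials import BONE_ROLES, Role

__all__ = [
    "SegmentSpec",
    "SurgicalPlan",
    "LabeledVoxelModel",
    "HexMesh",
    "DisconnectedModelError",
    "build_intact_segment",
    "apply_acdf",
    "apply_accf",
    "apply_mod_acdf",
    "build_for_surgery",
    "voxel_to_hexmesh",
]

_DISC_ROLES = (Role.CARTILAGINOUS_ENDPLATE, Role.ANNULUS, Role.NUCLEUS)

# integer codes used in the label grid
ROLE_CODES: dict[Role, int] = {r: i for i, r in enumerate(Role)}
CODE_ROLES: dict[int, Role] = {i: r for r, i in ROLE_CODES.items()}
AIR = ROLE_CODES[Role.AIR]
BONE_CODE_SET = frozenset(ROLE_CODES[r] for r in BONE_ROLES)


class DisconnectedModelError(ValueError):
    """The non-air region splits into several face-connected components."""

    def __init__(self, sizes: Sequence[int]):
        self.component_sizes = tuple(sorted(sizes, reverse=True))
        super().__init__(
            "voxel model is not face-connected; component sizes "
            f"{self.component_sizes} (a floating fragment would make the "
            "stiffness matrix singular)"
        )


@dataclass(frozen=True)
class SegmentSpec:
    """Dimensions (mm) of the idealized subaxial cervical segment."""

    vertebra_width_ml: float = 24.0
    vertebra_depth_ap: float = 16.0
    vertebra_height: float = 12.0
    disc_height: float = 5.0
    cortical_shell_layers: int = 1
    bony_endplate_layers: int = 1
    cartilaginous_endplate_layers: int = 1
    nucleus_area_fraction: float = 0.40
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        for name in ("vertebra_width_ml", "vertebra_depth_ap", "vertebra_height",
                     "disc_height", "voxel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.nucleus_area_fraction < 1:
            raise ValueError("nucleus_area_fraction must lie in (0, 1)")
        if min(self.width_vox, self.depth_vox, self.height_vox, self.disc_vox) < 3:
            raise ValueError("degenerate dimensions: every tissue must span >= 3 voxels")
        shell = self.cortical_shell_layers + self.bony_endplate_layers
        if shell >= self.height_vox // 2:
            raise ValueError("cortical shell + endplate layers must be < half the "
                             "vertebra height in voxels")
        if 2 * self.cartilaginous_endplate_layers >= self.disc_vox:
            raise ValueError("cartilaginous endplates leave no room for the disc core")

    # voxel counts (nearest-voxel rasterization)
    @property
    def width_vox(self) -> int:
        return round(self.vertebra_width_ml / self.voxel_size)

    @property
    def depth_vox(self) -> int:
        return round(self.vertebra_depth_ap / self.voxel_size)

    @property
    def height_vox(self) -> int:
        return round(self.vertebra_height / self.voxel_size)

    @property
    def disc_vox(self) -> int:
        return round(self.disc_height / self.voxel_size)


@dataclass(frozen=True)
class SurgicalPlan:
    """Implant and resection dimensions (mm)."""

    surgery: str = "INTACT"  # INTACT | ACDF | ACCF | MOD_ACDF
    cage_dims: tuple[float, float, float] = (5.0, 14.0, 16.0)  # height, AP, ML
    mesh_diameter: float = 10.0
    mesh_inner_diameter: float = 8.0
    mesh_length: float = 50.0  # catalog length; truncated to the actual defect
    corpectomy_width: float = 15.0
    osteotomy_notch: tuple[float, float] = (8.0, 9.0)  # ML, AP from posterior margin
    notch_depth: float | None = None  # cranio-caudal; None -> half body height
    plate_dims_two_level: tuple[float, float, float] = (1.0, 20.0, 16.0)  # t, h, ML
    plate_dims_three_level: tuple[float, float, float] = (1.0, 22.0, 16.0)
    anterior_clearance: float = 1.0  # implant offset from the anterior edge
    screw_diameter: float = 4.0
    screw_length: float = 14.0
    screw_lateral_offset: float = 6.0  # screw axis offset from midline

    def __post_init__(self) -> None:
        if self.mesh_inner_diameter >= self.mesh_diameter:
            raise ValueError("mesh inner diameter must be smaller than outer")


@dataclass
class LabeledVoxelModel:
    """Regular 3-D grid of material role codes: the CT stand-in.

    ``labels[i, j, k]`` with i = x (ML), j = y (AP), k = z (cranio-caudal).
    ``level_spans`` maps level names (e.g. ``"C5"``, ``"C4/5"``) to half-open
    voxel ranges along z.
    """

    labels: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spec: SegmentSpec | None = None
    level_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    surgery: str = "INTACT"
    provenance: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def copy(self) -> "LabeledVoxelModel":
        return replace(
            self,
            labels=self.labels.copy(),
            level_spans=dict(self.level_spans),
            provenance=list(self.provenance),
            meta=dict(self.meta),
        )

    @property
    def monitored_vertebra(self) -> str:
        return "C6" if self.surgery == "ACCF" else "C5"

    def count(self, *roles: Role) -> int:
        codes = [ROLE_CODES[r] for r in roles]
        return int(np.isin(self.labels, codes).sum())

    def bone_voxel_count(self, level: str | None = None) -> int:
        sel = self.labels
        if level is not None:
            k0, k1 = self.level_spans[level]
            sel = sel[:, :, k0:k1]
        return int(np.isin(sel, list(BONE_CODE_SET)).sum())

    def is_mirror_symmetric(self) -> bool:
        """Voxel-wise mirror symmetry about the mid-sagittal (x) plane."""
        return bool(np.array_equal(self.labels, self.labels[::-1, :, :]))

    def bounding_box(self, role: Role) -> tuple[tuple[float, float], ...] | None:
        """Axis-aligned bounding box (mm) of all voxels with the given role."""
        idx = np.argwhere(self.labels == ROLE_CODES[role])
        if idx.size == 0:
            return None
        h = self.voxel_size
        lo = idx.min(axis=0) * h
        hi = (idx.max(axis=0) + 1) * h
        return tuple((float(a), float(b)) for a, b in zip(lo, hi))


@dataclass
class HexMesh:
    """8-node hexahedral mesh with per-element material labels and named sets.

    Element-local node ordering: counter-clockwise around the bottom face
    (viewed from +z), then the corresponding top-face nodes:
    ``(i,j,k) (i+1,j,k) (i+1,j+1,k) (i,j+1,k) (i,j,k+1) ... (i,j+1,k+1)``
    (the VTK hexahedron convention).
    """

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (E, 8) node indices
    element_labels: np.ndarray  # (E,) role codes
    element_voxels: np.ndarray  # (E, 3) originating voxel (i, j, k)
    voxel_size: float
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)  # (F, 4) node quads

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)


# ---------------------------------------------------------------------------
# intact segment
# ---------------------------------------------------------------------------

def _even_width_vox(width_mm: float, h: float) -> int:
    """Rasterize a mediolateral width to an even voxel count (mirror symmetry)."""
    return max(2, 2 * int(width_mm / (2 * h)))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _fill_vertebra(labels: np.ndarray, spec: SegmentSpec, k0: int, k1: int) -> None:
    w, d = spec.width_vox, spec.depth_vox
    ep = spec.bony_endplate_layers
    sh = spec.cortical_shell_layers
    labels[:w, :d, k0:k0 + ep] = ROLE_CODES[Role.BONY_ENDPLATE]
    labels[:w, :d, k1 - ep:k1] = ROLE_CODES[Role.BONY_ENDPLATE]
    mid = slice(k0 + ep, k1 - ep)
    labels[:w, :d, mid] = ROLE_CODES[Role.CORTICAL]
    labels[sh:w - sh, sh:d - sh, mid] = ROLE_CODES[Role.CANCELLOUS]


def _fill_disc(labels: np.ndarray, spec: SegmentSpec, k0: int, k1: int) -> None:
    w, d = spec.width_vox, spec.depth_vox
    ce = spec.cartilaginous_endplate_layers
    labels[:w, :d, k0:k1] = ROLE_CODES[Role.ANNULUS]
    # central nucleus occupying ~nucleus_area_fraction of the cross-section
    f = spec.nucleus_area_fraction
    nxv = _even_width_vox(math.sqrt(f) * spec.vertebra_width_ml, spec.voxel_size)
    nyv = max(2, _round_half_up(math.sqrt(f) * d))
    i0 = (w - nxv) // 2
    j0 = (d - nyv) // 2
    labels[i0:i0 + nxv, j0:j0 + nyv, k0 + ce:k1 - ce] = ROLE_CODES[Role.NUCLEUS]
    labels[:w, :d, k0:k0 + ce] = ROLE_CODES[Role.CARTILAGINOUS_ENDPLATE]
    labels[:w, :d, k1 - ce:k1] = ROLE_CODES[Role.CARTILAGINOUS_ENDPLATE]


def build_intact_segment(spec: SegmentSpec, levels: int = 2) -> LabeledVoxelModel:
    """Stack an intact two- or three-level segment (C4-C5 or C4-C6).

    Levels are stacked caudal-to-cranial from z = 0; one extra anterior voxel
    layer (y beyond the body footprint) is reserved for the plate.
    """
    if levels not in (2, 3):
        raise ValueError("levels must be 2 or 3")
    names = (["C5", "C4/5", "C4"] if levels == 2
             else ["C6", "C5/6", "C5", "C4/5", "C4"])
    plate_layers = max(1, round(1.0 / spec.voxel_size))
    nx = spec.width_vox
    ny = spec.depth_vox + plate_layers
    heights = [spec.disc_vox if "/" in n else spec.height_vox for n in names]
    nz = sum(heights)
    labels = np.zeros((nx, ny, nz), dtype=np.int8)
    spans: dict[str, tuple[int, int]] = {}
    k = 0
    for name, hk in zip(names, heights):
        spans[name] = (k, k + hk)
        if "/" in name:
            _fill_disc(labels, spec, k, k + hk)
        else:
            _fill_vertebra(labels, spec, k, k + hk)
        k += hk
    return LabeledVoxelModel(
        labels=labels,
        voxel_size=spec.voxel_size,
        spec=spec,
        level_spans=spans,
        surgery="INTACT",
        provenance=[f"intact {levels}-level segment ({' '.join(names)})"],
        meta={"levels": levels, "plate_layers": plate_layers},
    )


# ---------------------------------------------------------------------------
# surgical edits
# ---------------------------------------------------------------------------

def _remove_disc(model: LabeledVoxelModel, disc: str) -> None:
    k0, k1 = model.level_spans[disc]
    region = model.labels[:, :, k0:k1]
    mask = np.isin(region, [ROLE_CODES[r] for r in _DISC_ROLES])
    region[mask] = AIR
    model.provenance.append(f"resected disc {disc} (incl. cartilaginous endplates)")


def _place_plate_and_screws(
    model: LabeledVoxelModel,
    plan: SurgicalPlan,
    top_vertebra: str,
    bottom_vertebra: str,
    plate_dims: tuple[float, float, float],
) -> None:
    """Anterior plate flush on the body face, plus two screws per anchor vertebra.

    The plate is centred on the construct. If the printed plate height cannot
    span the anchor vertebrae (three-level case), it is extended to reach from
    mid-bottom to mid-top vertebra so the end screws anchor in cancellous bone.
    """
    spec = model.spec
    h = model.voxel_size
    w, d = spec.width_vox, spec.depth_vox
    plate_layers = model.meta["plate_layers"]
    nz = model.labels.shape[2]

    tz0, tz1 = model.level_spans[top_vertebra]
    bz0, bz1 = model.level_spans[bottom_vertebra]
    mid_top = (tz0 + tz1) / 2
    mid_bot = (bz0 + bz1) / 2
    required = mid_top - mid_bot
    plate_len = max(round(plate_dims[1] / h), _round_half_up(required))
    center = (mid_top + mid_bot) / 2
    z0p = _round_half_up(center - plate_len / 2)
    z1p = min(nz, z0p + plate_len)
    pw = _even_width_vox(plate_dims[2], h)
    i0 = (w - pw) // 2
    model.labels[i0:i0 + pw, d:d + plate_layers, z0p:z1p] = ROLE_CODES[Role.TITANIUM]
    model.provenance.append(
        f"anterior plate {plate_layers * h:g} x {plate_len * h:g} x {pw * h:g} mm "
        f"spanning {bottom_vertebra}-{top_vertebra}"
    )

    ep = spec.bony_endplate_layers
    r_vox = plan.screw_diameter / (2 * h)
    screw_len = round(plan.screw_length / h)
    j0s, j1s = d - screw_len, d + plate_layers
    for vert, (vz0, vz1), near_caudal in (
        (top_vertebra, (tz0, tz1), True),
        (bottom_vertebra, (bz0, bz1), False),
    ):
        # screw axis centred in the cancellous zone nearest the plate end
        margin = ep + int(math.ceil(r_vox)) + 1
        zc = (vz0 + margin) if near_caudal else (vz1 - margin)
        for sign in (-1, 1):
            xc = w / 2 + sign * plan.screw_lateral_offset / h
            ii, kk = np.meshgrid(np.arange(w), np.arange(nz), indexing="ij")
            inside = ((ii + 0.5 - xc) ** 2 + (kk + 0.5 - zc) ** 2) <= r_vox ** 2
            inside &= (kk >= vz0) & (kk < vz1) & (kk >= z0p) & (kk < z1p)
            for i, k in np.argwhere(inside):
                model.labels[i, j0s:j1s, k] = ROLE_CODES[Role.TITANIUM]
        model.provenance.append(
            f"2 screws (d {plan.screw_diameter:g} mm, l {plan.screw_length:g} mm) "
            f"into {vert} cancellous bone"
        )


def _place_cage(model: LabeledVoxelModel, plan: SurgicalPlan, disc: str) -> None:
    spec = model.spec
    h = model.voxel_size
    k0, k1 = model.level_spans[disc]
    ch, cap, cml = plan.cage_dims
    ch_v, cap_v = round(ch / h), round(cap / h)
    cml_v = _even_width_vox(cml, h)
    gap = k1 - k0
    if ch_v > gap or cml_v > spec.width_vox or cap_v > spec.depth_vox:
        raise ValueError("cage does not fit the created interspace")
    kz0 = k0 + (gap - ch_v) // 2
    j1 = spec.depth_vox - round(plan.anterior_clearance / h)
    j0 = j1 - cap_v
    i0 = (spec.width_vox - cml_v) // 2
    model.labels[i0:i0 + cml_v, j0:j1, kz0:kz0 + ch_v] = ROLE_CODES[Role.PEEK]
    model.meta["cage_box"] = ((i0 * h, (i0 + cml_v) * h),
                              (j0 * h, j1 * h),
                              (kz0 * h, (kz0 + ch_v) * h))
    model.provenance.append(
        f"PEEK cage {ch:g} x {cap:g} x {cml:g} mm in {disc} space, "
        f"{plan.anterior_clearance:g} mm from the anterior edge"
    )


def apply_acdf(model: LabeledVoxelModel, plan: SurgicalPlan | None = None) -> LabeledVoxelModel:
    """C4/5 discectomy + cage + two-level anterior plate on a 2-level model."""
    plan = plan or SurgicalPlan(surgery="ACDF")
    if model.surgery != "INTACT" or model.meta.get("levels") != 2:
        raise ValueError("ACDF requires a 2-level intact model")
    out = model.copy()
    _remove_disc(out, "C4/5")
    _place_cage(out, plan, "C4/5")
    _place_plate_and_screws(out, plan, "C4", "C5", plan.plate_dims_two_level)
    out.surgery = "ACDF"
    return out


def apply_accf(model: LabeledVoxelModel, plan: SurgicalPlan | None = None) -> LabeledVoxelModel:
    """Double discectomy + central C5 corpectomy + titanium mesh + 3-level plate."""
    plan = plan or SurgicalPlan(surgery="ACCF")
    if model.surgery != "INTACT" or model.meta.get("levels") != 3:
        raise ValueError("ACCF requires a 3-level intact model")
    spec = model.spec
    h = model.voxel_size
    if plan.corpectomy_width > spec.vertebra_width_ml:
        raise ValueError("corpectomy channel wider than the vertebral body")
    out = model.copy()
    _remove_disc(out, "C4/5")
    _remove_disc(out, "C5/6")
    # central full-depth, full-height channel through C5
    w, d = spec.width_vox, spec.depth_vox
    cw = _even_width_vox(plan.corpectomy_width, h)
    i0 = (w - cw) // 2
    k0, k1 = out.level_spans["C5"]
    out.labels[i0:i0 + cw, :d, k0:k1] = AIR
    out.meta["channel_box"] = ((i0 * h, (i0 + cw) * h), (0.0, d * h), (k0 * h, k1 * h))
    out.provenance.append(f"C5 corpectomy channel, ML width {cw * h:g} mm, full depth")
    # hollow titanium mesh cylinder spanning the defect (C6 top to C4 bottom);
    # the printed catalog length is truncated to the actual defect height
    z_lo = out.level_spans["C6"][1]
    z_hi = out.level_spans["C4"][0]
    r_out = plan.mesh_diameter / 2
    r_in = plan.mesh_inner_diameter / 2
    cx = w * h / 2
    cy = d * h - plan.anterior_clearance - r_out
    ii, jj = np.meshgrid(np.arange(w), np.arange(d), indexing="ij")
    d2 = ((ii + 0.5) * h - cx) ** 2 + ((jj + 0.5) * h - cy) ** 2
    ring = (d2 >= r_in ** 2) & (d2 <= r_out ** 2)
    for i, j in np.argwhere(ring):
        out.labels[i, j, z_lo:z_hi] = ROLE_CODES[Role.TITANIUM]
    out.meta["mesh_axis"] = (cx, cy)
    out.provenance.append(
        f"titanium mesh cylinder OD {plan.mesh_diameter:g} / ID "
        f"{plan.mesh_inner_diameter:g} mm, truncated to the "
        f"{(z_hi - z_lo) * h:g} mm defect"
    )
    _place_plate_and_screws(out, plan, "C4", "C6", plan.plate_dims_three_level)
    out.surgery = "ACCF"
    return out


def apply_mod_acdf(model: LabeledVoxelModel, plan: SurgicalPlan | None = None) -> LabeledVoxelModel:
    """ACDF plus a rectangular partial osteotomy of the superior posterior C5 body.

    The notch is centred on the mid-sagittal plane at the posterior margin,
    ``osteotomy_notch = (ML, AP)`` mm in footprint, cut downward from the C5
    superior surface to ``notch_depth`` (default: half the body height). Only
    bone is removed.
    """
    plan = plan or SurgicalPlan(surgery="MOD_ACDF")
    out = apply_acdf(model, plan)
    spec = model.spec
    h = model.voxel_size
    w, d = spec.width_vox, spec.depth_vox
    nml, nap = plan.osteotomy_notch
    if nml > spec.vertebra_width_ml or nap > spec.vertebra_depth_ap:
        raise ValueError("osteotomy notch exceeds the C5 body footprint")
    k0, k1 = out.level_spans["C5"]
    depth = plan.notch_depth if plan.notch_depth is not None else spec.vertebra_height / 2
    if nml > 0 and nap > 0 and depth > 0:
        nml_v = _even_width_vox(nml, h)
        nap_v = round(nap / h)
        nd_v = min(round(depth / h), k1 - k0)
        i0 = (w - nml_v) // 2
        region = out.labels[i0:i0 + nml_v, 0:nap_v, k1 - nd_v:k1]
        region[np.isin(region, list(BONE_CODE_SET))] = AIR
        out.meta["notch_box"] = ((i0 * h, (i0 + nml_v) * h),
                                 (0.0, nap_v * h),
                                 ((k1 - nd_v) * h, k1 * h))
        out.provenance.append(
            f"partial osteotomy of C5: {nml_v * h:g} x {nap_v * h:g} mm notch at the "
            f"posterior margin, depth {nd_v * h:g} mm"
        )
    out.surgery = "MOD_ACDF"
    return out


def build_for_surgery(
    surgery: str,
    spec: SegmentSpec | None = None,
    plan: SurgicalPlan | None = None,
) -> LabeledVoxelModel:
    """Intact segment of the right level count with the requested construct applied."""
    spec = spec or SegmentSpec()
    surgery = surgery.upper().replace("-", "_").replace(" ", "_")
    levels = 3 if surgery == "ACCF" else 2
    intact = build_intact_segment(spec, levels=levels)
    if surgery == "INTACT":
        return intact
    if surgery == "ACDF":
        return apply_acdf(intact, plan)
    if surgery == "ACCF":
        return apply_accf(intact, plan)
    if surgery == "MOD_ACDF":
        return apply_mod_acdf(intact, plan)
    raise ValueError(f"unknown surgery {surgery!r}")


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def voxel_to_hexmesh(model: LabeledVoxelModel) -> HexMesh:
    """One hex element per non-air voxel, shared nodes on shared faces.

    Node and element numbering follow a fixed lexicographic (z, y, x)
    traversal, so identical models yield bit-identical meshes. Raises
    :class:`DisconnectedModelError` if the non-air region is not
    face-connected.
    """
    occ = model.labels != AIR
    if not occ.any():
        raise ValueError("model contains no material voxels")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    comp, ncomp = ndimage.label(occ, structure=structure)
    if ncomp > 1:
        sizes = ndimage.sum_labels(occ, comp, index=np.arange(1, ncomp + 1))
        raise DisconnectedModelError([int(s) for s in sizes])

    nx, ny, nz = occ.shape
    h = model.voxel_size
    occ_t = occ.transpose(2, 1, 0)  # [k, j, i]
    used = np.zeros((nz + 1, ny + 1, nx + 1), dtype=bool)
    for dk in (0, 1):
        for dj in (0, 1):
            for di in (0, 1):
                used[dk:nz + dk, dj:ny + dj, di:nx + di] |= occ_t
    ids = np.full(used.shape, -1, dtype=np.int64)
    ids[used] = np.arange(int(used.sum()))
    kji = np.argwhere(used)  # C order == lexicographic (z, y, x)
    nodes = np.empty((kji.shape[0], 3), dtype=float)
    nodes[:, 0] = model.origin[0] + kji[:, 2] * h
    nodes[:, 1] = model.origin[1] + kji[:, 1] * h
    nodes[:, 2] = model.origin[2] + kji[:, 0] * h

    ev = np.argwhere(occ_t)  # (k, j, i), lexicographic (z, y, x)
    k, j, i = ev[:, 0], ev[:, 1], ev[:, 2]
    elements = np.stack(
        [
            ids[k, j, i], ids[k, j, i + 1], ids[k, j + 1, i + 1], ids[k, j + 1, i],
            ids[k + 1, j, i], ids[k + 1, j, i + 1], ids[k + 1, j + 1, i + 1],
            ids[k + 1, j + 1, i],
        ],
        axis=1,
    )
    element_labels = model.labels.transpose(2, 1, 0)[occ_t].astype(np.int8)
    element_voxels = ev[:, ::-1].copy()  # (i, j, k)

    node_sets = {
        "inferior_fixed_nodes": ids[0][used[0]],
        "superior_C4_nodes": ids[nz][used[nz]],
    }
    top = k == nz - 1
    superior_faces = np.stack(
        [ids[nz, j[top], i[top]], ids[nz, j[top], i[top] + 1],
         ids[nz, j[top] + 1, i[top] + 1], ids[nz, j[top] + 1, i[top]]],
        axis=1,
    )
    element_sets: dict[str, np.ndarray] = {}
    vert = model.monitored_vertebra
    if vert in model.level_spans:
        mk = model.level_spans[vert][1] - 1
        bone = np.isin(element_labels, list(BONE_CODE_SET))
        element_sets["monitored_surface_elements"] = np.flatnonzero((k == mk) & bone)

    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        element_labels=element_labels,
        element_voxels=element_voxels,
        voxel_size=h,
        node_sets=node_sets,
        element_sets=element_sets,
        face_sets={"superior_C4_faces": superior_faces},
    )
    for name, s in node_sets.items():
        if s.size == 0:
            raise ValueError(f"named node set {name!r} is empty")
    return mesh
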