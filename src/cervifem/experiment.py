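"""Full factorial experiment: surgery x bone quality x axial load.

Runs the 3 x 3 x 3 grid {ACDF, ACCF, Mod ACDF} x {NBM, OPA, OPS} x
{100, 150, 200 N}, extracts the 16 monitored points of maximum variation on
the superior surface of the caudal (monitored) vertebra for each cell, and
summarizes each cell as mean +/- SD of Von Mises stress (MPa) and displacement
(micrometres).

Two monitored-point channels are recorded per cell: the 16 surface elements
with the largest Von Mises stress and, separately, the 16 with the largest
displacement magnitude. Ties are broken by lexicographic (z, y, x) centroid
order so the selection is fully deterministic.

The pipeline is deterministic end to end; within one surgery x quality cell
the stiffness factorization is shared across the three loads (identical
matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fem
from .geometry import (
    HexMesh,
    LabeledVoxelModel,
    SegmentSpec,
    SurgicalPlan,
    build_for_surgery,
    voxel_to_hexmesh,
)
from .materials import (
    BONE_QUALITIES,
    BoneQuality,
    MaterialTable,
    base_material_table,
    degrade_for_bone_quality,
)

__all__ = [
    "SURGERIES",
    "DEFAULT_LOADS",
    "CaseSpec",
    "CaseResult",
    "GridSummary",
    "select_monitored_points",
    "run_case",
    "run_grid",
    "displacement_ordering_table",
    "bone_loss_monotonicity_table",
    "load_scaling_errors",
    "peak_distance_to_notch_corner",
    "accf_peak_is_posterior",
]

SURGERIES = ("ACDF", "MOD_ACDF", "ACCF")
DEFAULT_LOADS = (100.0, 150.0, 200.0)
MONITORED_POINT_COUNT = 16


@dataclass(frozen=True)
class CaseSpec:
    """One cell of the factorial design."""

    surgery: str
    bone_quality: str
    load: float  # N, applied axially (downward) on the superior C4 surface
    segment_spec: SegmentSpec = field(default_factory=SegmentSpec)
    surgical_plan: SurgicalPlan | None = None
    allow_custom_load: bool = False

    def __post_init__(self) -> None:
        if self.surgery.upper().replace("-", "_") not in SURGERIES + ("INTACT",):
            raise ValueError(f"unknown surgery {self.surgery!r}")
        if self.bone_quality not in BONE_QUALITIES:
            raise ValueError(f"unknown bone quality {self.bone_quality!r}")
        if not self.allow_custom_load and self.load not in DEFAULT_LOADS:
            raise ValueError(
                f"load {self.load} N is outside the standard set {DEFAULT_LOADS}; "
                "pass allow_custom_load=True for free-form loads"
            )

    @property
    def monitored_vertebra(self) -> str:
        return "C6" if self.surgery.upper() == "ACCF" else "C5"

    @property
    def quality(self) -> BoneQuality:
        return BONE_QUALITIES[self.bone_quality]


@dataclass
class CaseResult:
    """Solved cell: monitored-point tables plus summary statistics."""

    case: CaseSpec
    stress_points: pd.DataFrame  # point_id, x, y, z (mm), von_mises (MPa)
    displacement_points: pd.DataFrame  # point_id, x, y, z (mm), displacement (um)
    stress_mean: float
    stress_sd: float
    displacement_mean: float
    displacement_sd: float
    peak_stress_location: tuple[float, float, float]
    peak_displacement_location: tuple[float, float, float]
    reaction_balance_rel: float = float("nan")
    model: LabeledVoxelModel | None = None
    mesh: HexMesh | None = None
    solution: fem.FieldSolution | None = None


def select_monitored_points(
    values: np.ndarray,
    centroids: np.ndarray,
    element_ids: np.ndarray,
    k: int = MONITORED_POINT_COUNT,
    value_name: str = "value",
) -> pd.DataFrame:
    """The k elements with the largest field value, deterministic tie-break.

    Ties are resolved by lexicographic (z, y, x) centroid order; coordinates
    are logged in the returned table for reproducibility.
    """
    if values.shape[0] < k:
        raise ValueError(
            f"only {values.shape[0]} monitored-surface elements (< {k}); "
            "use a finer voxel_size"
        )
    order = np.lexsort((centroids[:, 0], centroids[:, 1], centroids[:, 2], -values))
    top = order[:k]
    return pd.DataFrame(
        {
            "point_id": np.arange(1, k + 1),
            "element_id": element_ids[top],
            "x": centroids[top, 0],
            "y": centroids[top, 1],
            "z": centroids[top, 2],
            value_name: values[top],
        }
    )


@dataclass
class _CellCache:
    model: LabeledVoxelModel
    mesh: HexMesh
    table: MaterialTable
    factorization: fem.StiffnessFactorization
    system: fem.LinearSystem


def _prepare_cell(surgery: str, quality_label: str, spec: SegmentSpec,
                  plan: SurgicalPlan | None) -> _CellCache:
    model = build_for_surgery(surgery, spec, plan)
    mesh = voxel_to_hexmesh(model)
    table = degrade_for_bone_quality(base_material_table(), BONE_QUALITIES[quality_label])
    system = fem.assemble(mesh, table)
    system = fem.fix_nodes(system, mesh.node_sets["inferior_fixed_nodes"])
    fac = fem.StiffnessFactorization(system)
    return _CellCache(model=model, mesh=mesh, table=table, factorization=fac,
                      system=system)


def run_case(case: CaseSpec, _cache: _CellCache | None = None,
             store_fields: bool = False) -> CaseResult:
    """Geometry -> materials -> assemble -> load -> solve -> recover -> select."""
    cache = _cache or _prepare_cell(case.surgery, case.bone_quality,
                                    case.segment_spec, case.surgical_plan)
    mesh, model = cache.mesh, cache.model
    system = fem.apply_axial_load(
        cache.system, mesh.face_sets["superior_C4_faces"], case.load, mesh
    )
    sol = fem.solve(system, factorization=cache.factorization)
    sol = fem.recover_stress(mesh, sol, cache.table)

    monitored = mesh.element_sets["monitored_surface_elements"]
    centroids = mesh.element_centroids()[monitored]
    vm = sol.element_von_mises[monitored]
    disp_nodes = np.linalg.norm(sol.displacements, axis=1)
    elem_disp_mm = disp_nodes[mesh.elements].mean(axis=1)
    disp_um = elem_disp_mm[monitored] * 1000.0  # mm -> micrometres

    stress_pts = select_monitored_points(vm, centroids, monitored, value_name="von_mises")
    disp_pts = select_monitored_points(disp_um, centroids, monitored,
                                       value_name="displacement")
    peak_s = stress_pts.iloc[0]
    peak_d = disp_pts.iloc[0]
    # reactions must balance the applied load: sum R_z = +load (load acts in -z)
    rz = float(sol.reaction_total()[2])
    balance = abs(rz - case.load) / case.load if case.load else 0.0
    return CaseResult(
        case=case,
        stress_points=stress_pts,
        displacement_points=disp_pts,
        stress_mean=float(stress_pts["von_mises"].mean()),
        stress_sd=float(stress_pts["von_mises"].std(ddof=1)),
        displacement_mean=float(disp_pts["displacement"].mean()),
        displacement_sd=float(disp_pts["displacement"].std(ddof=1)),
        peak_stress_location=(float(peak_s.x), float(peak_s.y), float(peak_s.z)),
        peak_displacement_location=(float(peak_d.x), float(peak_d.y), float(peak_d.z)),
        reaction_balance_rel=balance,
        model=model,
        mesh=mesh if store_fields else None,
        solution=sol if store_fields else None,
    )


@dataclass
class GridSummary:
    """All grid cells: one summary row and two 16-point samples per cell."""

    table: pd.DataFrame
    cases: dict[tuple[str, str, float], CaseResult]
    errors: dict[tuple[str, str, float], str] = field(default_factory=dict)

    def samples(self, channel: str) -> dict[tuple[str, str, float], np.ndarray]:
        """Per-cell 16-point samples; channel is 'stress' or 'displacement'."""
        col = {"stress": ("stress_points", "von_mises"),
               "displacement": ("displacement_points", "displacement")}[channel]
        return {key: getattr(r, col[0])[col[1]].to_numpy()
                for key, r in self.cases.items()}

    def cell(self, surgery: str, bone: str, load: float) -> CaseResult:
        return self.cases[(surgery, bone, load)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_grid(
    segment_spec: SegmentSpec | None = None,
    plan: SurgicalPlan | None = None,
    surgeries: tuple[str, ...] = SURGERIES,
    qualities: tuple[str, ...] = ("NBM", "OPA", "OPS"),
    loads: tuple[float, ...] = DEFAULT_LOADS,
    store_fields: bool = False,
) -> GridSummary:
    """Run every cell of the factorial design; per-cell failures are collected.

    The stiffness factorization is computed once per surgery x quality family
    and reused across the loads of that family (identical matrix).
    """
    spec = segment_spec or SegmentSpec()
    rows = []
    cases: dict[tuple[str, str, float], CaseResult] = {}
    errors: dict[tuple[str, str, float], str] = {}
    for surgery in surgeries:
        for quality in qualities:
            try:
                cache = _prepare_cell(surgery, quality, spec, plan)
            except Exception as exc:  # noqa: BLE001 - grid must keep going
                for load in loads:
                    errors[(surgery, quality, load)] = f"prepare: {exc}"
                continue
            for load in loads:
                key = (surgery, quality, load)
                try:
                    res = run_case(
                        CaseSpec(surgery=surgery, bone_quality=quality, load=load,
                                 segment_spec=spec, surgical_plan=plan,
                                 allow_custom_load=load not in DEFAULT_LOADS),
                        _cache=cache,
                        store_fields=store_fields,
                    )
                except Exception as exc:  # noqa: BLE001
                    errors[key] = f"solve: {exc}"
                    continue
                cases[key] = res
                px, py, pz = res.peak_stress_location
                dx, dy, dz = res.peak_displacement_location
                rows.append(
                    {
                        "surgery": surgery,
                        "bone_quality": quality,
                        "load_N": load,
                        "stress_mean_MPa": res.stress_mean,
                        "stress_sd_MPa": res.stress_sd,
                        "displacement_mean_um": res.displacement_mean,
                        "displacement_sd_um": res.displacement_sd,
                        "peak_stress_x": px, "peak_stress_y": py, "peak_stress_z": pz,
                        "peak_disp_x": dx, "peak_disp_y": dy, "peak_disp_z": dz,
                        "reaction_balance_rel": res.reaction_balance_rel,
                    }
                )
    return GridSummary(table=pd.DataFrame(rows), cases=cases, errors=errors)


# --- trend analysis ---------------------------------------------------------

def displacement_ordering_table(grid: GridSummary) -> pd.DataFrame:
    """Per (bone quality, load): is mean displacement ACDF < Mod ACDF < ACCF?"""
    t = grid.table.pivot_table(index=["bone_quality", "load_N"], columns="surgery",
                               values="displacement_mean_um")
    out = t.reset_index()
    out["ordering_ok"] = (t["ACDF"] < t["MOD_ACDF"]).to_numpy() & (
        t["MOD_ACDF"] < t["ACCF"]
    ).to_numpy()
    return out


def bone_loss_monotonicity_table(grid: GridSummary) -> pd.DataFrame:
    """Per (surgery, load): displacement non-decreasing NBM -> OPA -> OPS."""
    t = grid.table.pivot_table(index=["surgery", "load_N"], columns="bone_quality",
                               values="displacement_mean_um")
    out = t.reset_index()
    out["monotone_ok"] = (t["NBM"] <= t["OPA"]).to_numpy() & (
        t["OPA"] <= t["OPS"]
    ).to_numpy()
    return out


def load_scaling_errors(grid: GridSummary,
                        loads: tuple[float, ...] = DEFAULT_LOADS) -> pd.DataFrame:
    """Relative deviation of each cell's displacement from exact load linearity."""
    base = loads[0]
    rows = []
    for (surgery, quality, load), res in grid.cases.items():
        if load == base:
            continue
        ref = grid.cases.get((surgery, quality, base))
        if ref is None:
            continue
        expect = ref.displacement_mean * load / base
        rows.append(
            {
                "surgery": surgery,
                "bone_quality": quality,
                "load_N": load,
                "scale": load / base,
                "rel_error": abs(res.displacement_mean - expect) / expect,
            }
        )
    return pd.DataFrame(rows)


def peak_distance_to_notch_corner(res: CaseResult) -> float:
    """In-plane Chebyshev distance (mm) from the peak-stress element centroid
    to the nearest posterior corner of the Mod ACDF osteotomy notch."""
    if res.model is None or "notch_box" not in res.model.meta:
        raise ValueError("case has no osteotomy notch")
    box = res.model.meta["notch_box"]
    (x0, x1), (y0, y1), _ = box
    px, py, _ = res.peak_stress_location
    corners = [(x0, y0), (x1, y0), (x0, y1), (x1, y1)]
    return min(max(abs(px - cx), abs(py - cy)) for cx, cy in corners)


def accf_peak_is_posterior(res: CaseResult) -> bool:
    """Is the ACCF peak-stress element on the posterior half of the C6 surface?

    Posterior = small y (anterior positive convention).
    """
    depth = res.case.segment_spec.vertebra_depth_ap
    return res.peak_stress_location[1] < depth / 2
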