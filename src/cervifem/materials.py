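"""Material library for the cervical-segment models.

Houses the isotropic elastic constants for every tissue and implant used by the
geometry module, the WHO bone-quality grouping (normal bone mass, osteopenia,
osteoporosis, by T-score), and the bone-loss degradation arithmetic that maps
the normal-bone moduli to the osteopenic/osteoporotic ones.

Units are fixed package-wide: lengths in mm, forces in N, moduli and stresses
in MPa. Displacements downstream are reported in micrometres.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

__all__ = [
    "Role",
    "BONE_ROLES",
    "MaterialSpec",
    "BoneQuality",
    "MaterialTable",
    "NBM",
    "OPA",
    "OPS",
    "BONE_QUALITIES",
    "base_material_table",
    "degrade_for_bone_quality",
    "degraded_modulus",
    "lame_parameters",
    "POISSON_CLAMP",
]

#: Upper clamp for Poisson's ratio. A ratio of exactly 0.5 (incompressible
#: nucleus pulposus) is singular for a displacement-based formulation; the
#: value is clamped just below and a warning emitted.
POISSON_CLAMP = 0.499


class Role(str, enum.Enum):
    """Tissue / implant role a material (and a voxel label) can take."""

    AIR = "air"
    CORTICAL = "cortical"
    CANCELLOUS = "cancellous"
    BONY_ENDPLATE = "bony_endplate"
    CARTILAGINOUS_ENDPLATE = "cartilaginous_endplate"
    ANNULUS = "annulus"
    NUCLEUS = "nucleus"
    ARTICULAR_CARTILAGE = "articular_cartilage"
    TITANIUM = "titanium"
    PEEK = "peek"


#: Roles whose moduli depend on bone quality.
BONE_ROLES = frozenset({Role.CORTICAL, Role.CANCELLOUS, Role.BONY_ENDPLATE})


@dataclass(frozen=True)
class MaterialSpec:
    """One isotropic material: a name, its role, E (MPa) and Poisson's ratio."""

    name: str
    role: Role
    young_modulus: float  # MPa
    poisson_ratio: float  # dimensionless, clamped into [0, POISSON_CLAMP]

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError(f"{self.name}: Young's modulus must be positive")
        nu = self.poisson_ratio
        if nu >= 0.5:
            warnings.warn(
                f"{self.name}: Poisson's ratio {nu} is singular for a "
                f"displacement-based solver; clamped to {POISSON_CLAMP}",
                stacklevel=2,
            )
            object.__setattr__(self, "poisson_ratio", POISSON_CLAMP)
        elif nu < 0:
            raise ValueError(f"{self.name}: Poisson's ratio must be >= 0")


@dataclass(frozen=True)
class BoneQuality:
    """A WHO bone-density group and its modulus multipliers on the NBM values."""

    label: str
    t_score_rule: str
    cortical_factor: float
    endplate_factor: float
    cancellous_factor: float

    def __post_init__(self) -> None:
        for f in (self.cortical_factor, self.endplate_factor, self.cancellous_factor):
            if not 0 < f <= 1:
                raise ValueError(f"{self.label}: factors must lie in (0, 1]")

    def factor_for(self, role: Role) -> float:
        if role in (Role.CORTICAL,):
            return self.cortical_factor
        if role is Role.BONY_ENDPLATE:
            return self.endplate_factor
        if role is Role.CANCELLOUS:
            return self.cancellous_factor
        return 1.0


NBM = BoneQuality("NBM", "T >= -1.0 SD", 1.0, 1.0, 1.0)
OPA = BoneQuality("OPA", "-2.5 SD < T < -1.0 SD", 0.67, 0.67, 0.67)
OPS = BoneQuality("OPS", "T <= -2.5 SD", 0.67, 0.67, 0.33)

BONE_QUALITIES: dict[str, BoneQuality] = {"NBM": NBM, "OPA": OPA, "OPS": OPS}


def degraded_modulus(nbm_modulus: float, factor: float) -> int:
    """Bone-loss degradation rule: scale the normal-bone modulus and round half-up.

    ``degraded_modulus(12000, 0.67) == 8040`` (osteopenic/osteoporotic cortical
    bone), ``degraded_modulus(450, 0.67) == 302`` and
    ``degraded_modulus(450, 0.33) == 149``. The published material table is
    authoritative for the table itself; this helper exists so the rule and the
    table can be checked against each other.
    """
    return int(math.floor(nbm_modulus * factor + 0.5))


@dataclass(frozen=True)
class MaterialTable:
    """Materials keyed by role, for one bone-quality condition."""

    bone_quality: BoneQuality
    entries: dict[Role, MaterialSpec] = field(default_factory=dict)

    def __getitem__(self, role: Role) -> MaterialSpec:
        try:
            return self.entries[role]
        except KeyError:
            raise KeyError(
                f"material table ({self.bone_quality.label}) has no entry for "
                f"role {role.value!r}"
            ) from None

    def __contains__(self, role: Role) -> bool:
        return role in self.entries

    def roles(self) -> Iterable[Role]:
        return self.entries.keys()

    def lame(self, role: Role) -> tuple[float, float]:
        return lame_parameters(self[role])

    # -- serialization ----------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "bone_quality": self.bone_quality.label,
            "entries": [
                {
                    "name": m.name,
                    "role": m.role.value,
                    "young_modulus_MPa": m.young_modulus,
                    "poisson_ratio": m.poisson_ratio,
                }
                for m in self.entries.values()
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MaterialTable":
        doc = yaml.safe_load(text)
        quality = BONE_QUALITIES[doc["bone_quality"]]
        entries = {}
        for e in doc["entries"]:
            m = MaterialSpec(
                name=e["name"],
                role=Role(e["role"]),
                young_modulus=e["young_modulus_MPa"],
                poisson_ratio=e["poisson_ratio"],
            )
            entries[m.role] = m
        return cls(bone_quality=quality, entries=entries)


def base_material_table() -> MaterialTable:
    """The normal-bone-mass (NBM) material table.

    The nucleus pulposus is tabulated with Poisson's ratio 0.50
    (incompressible); MaterialSpec clamps it to 0.499 with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # expected nucleus clamp
        nucleus = MaterialSpec("nucleus pulposus", Role.NUCLEUS, 1.0, 0.50)
    specs = [
        MaterialSpec("cortical bone", Role.CORTICAL, 12_000.0, 0.30),
        MaterialSpec("cancellous bone", Role.CANCELLOUS, 450.0, 0.25),
        MaterialSpec("bony endplate", Role.BONY_ENDPLATE, 12_000.0, 0.30),
        MaterialSpec("cartilaginous endplate", Role.CARTILAGINOUS_ENDPLATE, 25.0, 0.40),
        MaterialSpec("annulus fibrosus", Role.ANNULUS, 4.2, 0.45),
        nucleus,
        MaterialSpec("titanium mesh/plate/screw", Role.TITANIUM, 110_000.0, 0.36),
        MaterialSpec("PEEK cage", Role.PEEK, 3_600.0, 0.30),
    ]
    return MaterialTable(bone_quality=NBM, entries={m.role: m for m in specs})


#: Published quality-adjusted bone moduli (MPa). Authoritative; the
#: ``degraded_modulus`` rule is a cross-check against these.
_PUBLISHED_BONE_MODULI: dict[str, dict[Role, float]] = {
    "NBM": {Role.CORTICAL: 12_000.0, Role.BONY_ENDPLATE: 12_000.0, Role.CANCELLOUS: 450.0},
    "OPA": {Role.CORTICAL: 8_040.0, Role.BONY_ENDPLATE: 8_040.0, Role.CANCELLOUS: 302.0},
    "OPS": {Role.CORTICAL: 8_040.0, Role.BONY_ENDPLATE: 8_040.0, Role.CANCELLOUS: 149.0},
}


def published_bone_moduli(quality: BoneQuality) -> dict[Role, float]:
    """The tabulated bone moduli (MPa) for a bone-quality group."""
    try:
        return dict(_PUBLISHED_BONE_MODULI[quality.label])
    except KeyError:
        raise ValueError(f"unknown bone quality {quality.label!r}") from None


def degrade_for_bone_quality(table: MaterialTable, quality: BoneQuality) -> MaterialTable:
    """Return a new table with bone moduli replaced by the values for *quality*.

    Only the bone roles change; Poisson ratios and all soft-tissue/implant
    entries are untouched. The input table is never mutated and the operation
    is idempotent per quality.
    """
    moduli = published_bone_moduli(quality)
    entries = dict(table.entries)
    for role, e_new in moduli.items():
        if role in entries:
            entries[role] = replace(entries[role], young_modulus=e_new)
    return MaterialTable(bone_quality=quality, entries=entries)


def lame_parameters(m: MaterialSpec) -> tuple[float, float]:
    """Lame parameters (lambda, mu) in MPa from (E, nu).

    lambda = E*nu / ((1+nu)(1-2nu)),  mu = E / (2(1+nu)).
    """
    e, nu = m.young_modulus, m.poisson_ratio
    if not 0 <= nu < 0.5:
        raise ValueError(f"Poisson's ratio {nu} outside [0, 0.5)")
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    return lam, mu
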