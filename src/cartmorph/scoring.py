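"""Semiquantitative histology scoring and macroscopic India-ink grading.

Two ordinal instruments are implemented:

* the modified OARSI histopathology score — per joint compartment, a
  structure component (0-11, by erosion depth and surface extent), a
  chondrocyte-density component (0-4) and a cluster-formation component
  (0-3), summed to a compartment total (0-18) and over the four compartments
  to a joint histology total (0-72);
* the macroscopic India-ink grade — per compartment, 1 (intact surface,
  no ink retention) to 4 (cartilage loss with bone exposure), summed to a
  joint macroscopic total (4-16).

Within a compartment the structure score follows the most-severe-lesion
rule: each lesion is graded independently and the compartment takes the
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .presets import Compartment

__all__ = [
    "LesionDepth",
    "Lesion",
    "LesionDescriptor",
    "DensityPattern",
    "InkUptake",
    "OarsiScore",
    "JointScores",
    "ScoringError",
    "score_structure",
    "score_density",
    "score_clusters",
    "grade_macroscopic",
    "aggregate_joint",
    "STRUCTURE_RUBRIC",
]


class ScoringError(ValueError):
    pass


class LesionDepth(str, Enum):
    """Ordered lesion depth categories of the structure scale."""

    SURFACE_IRREGULARITY = "surface_irregularity"
    FISSURE = "fissure"
    EROSION_ONE_THIRD = "erosion_one_third"  # erosion of 1/3 hyaline depth
    EROSION_TWO_THIRDS = "erosion_two_thirds"  # erosion of 2/3 hyaline depth
    FULL_DEPTH = "full_depth"  # full-depth erosion of hyaline cartilage
    FULL_DEPTH_CALCIFIED = "full_depth_calcified"  # through calcified cartilage to subchondral bone


# Base structure score for each depth category at extent < 50%; one point is
# added when the lesion covers >= 50% of the surface (ties at exactly 50%
# grade as >= 50%).  Surface irregularities score 1 regardless of extent.
_DEPTH_BASE = {
    LesionDepth.SURFACE_IRREGULARITY: 1,
    LesionDepth.FISSURE: 2,
    LesionDepth.EROSION_ONE_THIRD: 4,
    LesionDepth.EROSION_TWO_THIRDS: 6,
    LesionDepth.FULL_DEPTH: 8,
    LesionDepth.FULL_DEPTH_CALCIFIED: 10,
}

#: The full 12-row structure rubric: score -> (depth category, extent class).
#: Extent class is None (not applicable), "lt50" or "ge50".
STRUCTURE_RUBRIC: dict[int, tuple[LesionDepth | None, str | None]] = {
    0: (None, None),
    1: (LesionDepth.SURFACE_IRREGULARITY, None),
    2: (LesionDepth.FISSURE, "lt50"),
    3: (LesionDepth.FISSURE, "ge50"),
    4: (LesionDepth.EROSION_ONE_THIRD, "lt50"),
    5: (LesionDepth.EROSION_ONE_THIRD, "ge50"),
    6: (LesionDepth.EROSION_TWO_THIRDS, "lt50"),
    7: (LesionDepth.EROSION_TWO_THIRDS, "ge50"),
    8: (LesionDepth.FULL_DEPTH, "lt50"),
    9: (LesionDepth.FULL_DEPTH, "ge50"),
    10: (LesionDepth.FULL_DEPTH_CALCIFIED, "lt50"),
    11: (LesionDepth.FULL_DEPTH_CALCIFIED, "ge50"),
}


@dataclass(frozen=True)
class Lesion:
    depth: LesionDepth
    extent_fraction: float  # fraction of the evaluated surface affected

    def __post_init__(self):
        if not 0.0 <= self.extent_fraction <= 1.0:
            raise ScoringError(f"extent_fraction {self.extent_fraction} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"depth": self.depth.value, "extent_fraction": self.extent_fraction}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Lesion":
        return cls(LesionDepth(d["depth"]), float(d["extent_fraction"]))


@dataclass
class LesionDescriptor:
    """The lesion inventory of one compartment."""

    lesions: tuple[Lesion, ...] = ()

    def __post_init__(self):
        self.lesions = tuple(self.lesions)

    @property
    def max_depth(self) -> LesionDepth | None:
        order = list(LesionDepth)
        depths = [order.index(l.depth) for l in self.lesions]
        return order[max(depths)] if depths else None

    @property
    def extent_fraction(self) -> float:
        return max((l.extent_fraction for l in self.lesions), default=0.0)


class DensityPattern(str, Enum):
    """Chondrocyte density categories, ordered by severity."""

    NO_DECREASE = "no_decrease"
    FOCAL_DECREASE = "focal_decrease"
    MULTIFOCAL_DECREASE = "multifocal_decrease"
    MULTIFOCAL_CONFLUENT_DECREASE = "multifocal_confluent_decrease"
    DIFFUSE_DECREASE = "diffuse_decrease"


_DENSITY_SCORE = {p: i for i, p in enumerate(DensityPattern)}


class InkUptake(str, Enum):
    """Macroscopic India-ink retention categories."""

    NONE = "none"  # intact surface, no ink retained
    MINIMAL_FOCAL = "minimal_focal"  # minimal fibrillation
    LARGE_FOCAL_PATCHES = "large_focal_patches"  # overt fibrillation
    BONE_EXPOSED = "bone_exposed"  # erosion down to bone


_MACRO_GRADE = {
    InkUptake.NONE: 1,
    InkUptake.MINIMAL_FOCAL: 2,
    InkUptake.LARGE_FOCAL_PATCHES: 3,
    InkUptake.BONE_EXPOSED: 4,
}


def _score_single_lesion(lesion: Lesion) -> int:
    base = _DEPTH_BASE.get(lesion.depth)
    if base is None:
        raise ScoringError(f"unknown lesion depth category: {lesion.depth!r}")
    if lesion.depth is LesionDepth.SURFACE_IRREGULARITY:
        return base
    return base + (1 if lesion.extent_fraction >= 0.5 else 0)


def score_structure(descriptor: LesionDescriptor | Sequence[Lesion]) -> int:
    """Structure component (0-11) under the most-severe-lesion rule."""
    lesions = descriptor.lesions if isinstance(descriptor, LesionDescriptor) else tuple(descriptor)
    if not lesions:
        return 0
    return max(_score_single_lesion(l) for l in lesions)


def score_density(pattern: DensityPattern | str) -> int:
    """Chondrocyte density component (0-4), a direct ordinal lookup."""
    try:
        pattern = DensityPattern(pattern)
    except ValueError:
        raise ScoringError(f"unknown chondrocyte density pattern: {pattern!r}") from None
    return _DENSITY_SCORE[pattern]


def score_clusters(count: int) -> int:
    """Cluster-formation component (0-3) from the chondrocyte cluster count."""
    if count < 0:
        raise ScoringError(f"cluster count must be >= 0, got {count}")
    if count == 0:
        return 0
    if count < 4:
        return 1
    if count < 8:
        return 2
    return 3


def grade_macroscopic(obs: InkUptake | str) -> int:
    """India-ink macroscopic grade 1-4."""
    try:
        obs = InkUptake(obs)
    except ValueError:
        raise ScoringError(f"unknown ink-uptake category: {obs!r}") from None
    return _MACRO_GRADE[obs]


@dataclass(frozen=True)
class OarsiScore:
    structure: int
    density: int
    clusters: int

    def __post_init__(self):
        if not (0 <= self.structure <= 11 and 0 <= self.density <= 4 and 0 <= self.clusters <= 3):
            raise ScoringError(f"OARSI components out of range: {self}")

    @property
    def compartment_total(self) -> int:
        return self.structure + self.density + self.clusters


@dataclass
class JointScores:
    oarsi: dict[Compartment, OarsiScore]
    macro_grades: dict[Compartment, int]

    @property
    def histology_total(self) -> int:
        return sum(s.compartment_total for s in self.oarsi.values())

    @property
    def macroscopic_total(self) -> int:
        return sum(self.macro_grades.values())


def score_compartment(descriptor: LesionDescriptor, pattern: DensityPattern | str,
                      cluster_count: int) -> OarsiScore:
    return OarsiScore(
        structure=score_structure(descriptor),
        density=score_density(pattern),
        clusters=score_clusters(cluster_count),
    )


def aggregate_joint(
    oarsi: Mapping[Compartment, OarsiScore],
    macro: Mapping[Compartment, InkUptake | int],
) -> JointScores:
    """Sum the four compartments into joint totals.

    ``macro`` values may be raw :class:`InkUptake` observations or already
    converted 1-4 grades.
    """
    for c in Compartment:
        if c not in oarsi:
            raise ScoringError(f"missing OARSI score for compartment {c.value}")
        if c not in macro:
            raise ScoringError(f"missing macroscopic observation for compartment {c.value}")
    grades = {}
    for c in Compartment:
        v = macro[c]
        if isinstance(v, (InkUptake, str)):
            grades[c] = grade_macroscopic(v)
        else:
            if not 1 <= int(v) <= 4:
                raise ScoringError(f"macroscopic grade {v} outside 1-4 for {c.value}")
            grades[c] = int(v)
    return JointScores(oarsi={c: oarsi[c] for c in Compartment}, macro_grades=grades)
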