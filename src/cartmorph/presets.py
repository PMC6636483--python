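"""Group presets and study configuration.

The synthetic study emulates a three-arm rabbit ACLT (anterior cruciate
ligament transection) osteoarthritis trial: a *Channa striatus* extract arm,
a glucosamine sulphate arm, and an untreated control arm, each of 11 animals,
with four scored joint compartments per knee (medial/lateral femoral condyle,
medial/lateral tibial plateau).

Each :class:`GroupPreset` carries the *generator truth* for its arm: the
between-animal distribution of medial-femoral cartilage thickness, the
fibrillation roughness of the articular surface (expressed through the
normalized-roughness ratio), the per-compartment distributions of the ordinal
histopathology components (structure, chondrocyte density, cluster
formation), the per-compartment India-ink macroscopic grade distributions,
and the serum biomarker levels (COMP, COX-2, PGE2).  Downstream measurement
and scoring stages are validated by recovering these truths from the
generated data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Group",
    "Compartment",
    "GroupPreset",
    "StudyConfig",
    "ConfigurationError",
    "default_config",
    "default_presets",
    "convert_human_dose",
    "RABBIT_BSA_FACTOR",
    "SERUM_ASSAY_RANGE_NG_ML",
]

#: Body-surface-area scaling factor from a 70 kg human to the rabbit.
RABBIT_BSA_FACTOR = 3.6

#: ELISA kit detection range for all serum analytes, ng/ml.
SERUM_ASSAY_RANGE_NG_ML = (1.56, 100.0)

PROB_TOL = 1e-9


class Group(str, Enum):
    CHANNA = "channa"
    GLUCOSAMINE = "glucosamine"
    CONTROL = "control"


class Compartment(str, Enum):
    """The four scored femoro-tibial joint compartments."""

    MF = "MF"  # medial femoral condyle (quantitative histology compartment)
    LF = "LF"  # lateral femoral condyle
    MT = "MT"  # medial tibial plateau
    LT = "LT"  # lateral tibial plateau


class ConfigurationError(ValueError):
    """Raised when a preset or study configuration is invalid."""


def _check_prob_vector(name: str, p: Sequence[float], length: int | None = None) -> None:
    arr = np.asarray(p, dtype=float)
    if length is not None and arr.size != length:
        raise ConfigurationError(f"{name}: expected {length} probabilities, got {arr.size}")
    if np.any(arr < 0):
        raise ConfigurationError(f"{name}: probabilities must be nonnegative")
    if abs(float(arr.sum()) - 1.0) > PROB_TOL:
        raise ConfigurationError(f"{name}: probabilities sum to {arr.sum()!r}, not 1")


@dataclass
class GroupPreset:
    """Generator truth for one treatment arm.

    Thickness and the normalized-roughness ratio are drawn per animal from
    lognormal distributions with the stated mean and between-animal SD, which
    keeps both quantities strictly positive without truncation bias.  The
    per-animal fibrillation RMS (in um) follows from the drawn ratio and
    thickness, ``rms = ratio * thickness / 1000``.

    The ordinal histopathology components are parameterised per compartment
    by a probability vector over the structure scale (12 categories), the
    chondrocyte-density scale (5 categories) and the cluster-formation scale
    (4 categories); lesion descriptors are realised from the drawn structure
    category, so the scoring rubric recovers the drawn category exactly and
    the expected compartment total equals the calibrated target.
    """

    group: Group
    dose_mg_per_kg: float | None
    # --- morphometry truth ---
    true_thickness_mean: float  # um, group mean of per-animal thickness
    true_thickness_sd_between_animals: float  # um
    normalized_roughness_mean: float  # dimensionless x1000
    normalized_roughness_sd: float  # dimensionless x1000
    area_truth_um2: float  # group-mean cartilage area over the area window
    area_window_um: float  # evaluation window length for area recovery
    lesion_rate: float  # expected carved erosion lesions per profile
    # --- ordinal histopathology truth, per compartment ---
    structure_dist: Mapping[Compartment, Sequence[float]]  # 12 probs each
    density_dist: Mapping[Compartment, Sequence[float]]  # 5 probs each
    cluster_dist: Mapping[Compartment, Sequence[float]]  # 4 probs each
    macro_grade_dist: Mapping[Compartment, Sequence[float]]  # 4 probs each
    # --- serum truth, ng/ml ---
    serum_means: Mapping[str, float]
    serum_sds: Mapping[str, float]

    @property
    def fibrillation_rms(self) -> float:
        """Group-mean true RMS deviation of the surface from its ideal, um."""
        return self.normalized_roughness_mean * self.true_thickness_mean / 1000.0

    def oarsi_compartment_means(self) -> dict[Compartment, float]:
        """Expected compartment totals implied by the component distributions."""
        out = {}
        for c in Compartment:
            e = 0.0
            for dist in (self.structure_dist[c], self.density_dist[c], self.cluster_dist[c]):
                p = np.asarray(dist, float)
                e += float(np.arange(p.size) @ p)
            out[c] = e
        return out

    def validate(self) -> None:
        if self.true_thickness_mean <= 0:
            raise ConfigurationError("true_thickness_mean must be > 0")
        if self.true_thickness_sd_between_animals < 0:
            raise ConfigurationError("true_thickness_sd_between_animals must be >= 0")
        if self.normalized_roughness_mean < 0:
            raise ConfigurationError("normalized_roughness_mean must be >= 0")
        if self.lesion_rate < 0:
            raise ConfigurationError("lesion_rate must be >= 0")
        for c in Compartment:
            _check_prob_vector(f"{self.group.value}.structure_dist[{c.value}]", self.structure_dist[c], 12)
            _check_prob_vector(f"{self.group.value}.density_dist[{c.value}]", self.density_dist[c], 5)
            _check_prob_vector(f"{self.group.value}.cluster_dist[{c.value}]", self.cluster_dist[c], 4)
            _check_prob_vector(f"{self.group.value}.macro_grade_dist[{c.value}]", self.macro_grade_dist[c], 4)
        for analyte, mean in self.serum_means.items():
            if mean <= 0:
                raise ConfigurationError(f"serum mean for {analyte} must be > 0")
            if self.serum_sds.get(analyte, 0.0) < 0:
                raise ConfigurationError(f"serum sd for {analyte} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group"] = self.group.value
        for key in ("structure_dist", "density_dist", "cluster_dist", "macro_grade_dist"):
            d[key] = {c.value: list(map(float, v)) for c, v in getattr(self, key).items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupPreset":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown preset keys: {sorted(unknown)}")
        d["group"] = Group(d["group"])
        for key in ("structure_dist", "density_dist", "cluster_dist", "macro_grade_dist"):
            d[key] = {Compartment(c): list(map(float, v)) for c, v in d[key].items()}
        return cls(**d)


@dataclass
class GeometrySettings:
    """Geometry of the synthetic histology cross-sections (all um)."""

    roi_length: float = 7000.0  # weight-bearing evaluation region
    flank_length: float = 1000.0  # normal cartilage on either side of the ROI
    point_spacing: float = 5.0  # digitization spacing along x
    condyle_radius: float = 15000.0  # apex radius of the condylar arc
    pixel_size: float = 2.0  # um/px for rendered raster sections
    n_roughness_waves: tuple[int, int] = (3, 8)  # sinusoid count range
    roughness_wavelength: tuple[float, float] = (250.0, 2000.0)  # um
    edge_taper: float = 150.0  # roughness taper width at ROI edges


@dataclass
class StatsSettings:
    alpha: float = 0.05
    adjust_method: str = "bonferroni"  # for the repeated Mann-Whitney tests


@dataclass
class StudyConfig:
    """Complete configuration for one simulated study."""

    presets: dict[Group, GroupPreset]
    n_per_group: int = 11
    block_size: int = 6
    geometry: GeometrySettings = field(default_factory=GeometrySettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    carve_lesions_in_profiles: bool = False
    master_seed: int = 0

    def validate(self) -> None:
        if set(self.presets) != set(Group):
            raise ConfigurationError(
                f"config must contain presets for all groups {[g.value for g in Group]}"
            )
        for preset in self.presets.values():
            preset.validate()
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.block_size % len(self.presets) != 0:
            raise ConfigurationError("block_size must be a multiple of the group count")
        if self.geometry.point_spacing > 5.0:
            raise ConfigurationError("point_spacing must be <= 5 um")

    @property
    def n_animals(self) -> int:
        return self.n_per_group * len(self.presets)

    def to_dict(self) -> dict:
        return {
            "presets": {g.value: p.to_dict() for g, p in self.presets.items()},
            "n_per_group": self.n_per_group,
            "block_size": self.block_size,
            "geometry": asdict(self.geometry),
            "stats": asdict(self.stats),
            "carve_lesions_in_profiles": self.carve_lesions_in_profiles,
            "master_seed": self.master_seed,
        }

    def fingerprint(self) -> str:
        """Stable hash of the configuration (seed excluded)."""
        d = self.to_dict()
        d.pop("master_seed")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        presets = {Group(g): GroupPreset.from_dict(p) for g, p in d.pop("presets").items()}
        geometry = d.pop("geometry", None)
        stats = d.pop("stats", None)
        if geometry is not None and not isinstance(geometry, GeometrySettings):
            geo = dict(geometry)
            unknown = set(geo) - set(GeometrySettings.__dataclass_fields__)
            if unknown:
                raise ConfigurationError(f"unknown geometry keys: {sorted(unknown)}")
            for key in ("n_roughness_waves", "roughness_wavelength"):
                if key in geo:
                    geo[key] = tuple(geo[key])
            geometry = GeometrySettings(**geo)
        if stats is not None and not isinstance(stats, StatsSettings):
            st = dict(stats)
            unknown = set(st) - set(StatsSettings.__dataclass_fields__)
            if unknown:
                raise ConfigurationError(f"unknown stats keys: {sorted(unknown)}")
            stats = StatsSettings(**st)
        kwargs = dict(d)
        if geometry is not None:
            kwargs["geometry"] = geometry
        if stats is not None:
            kwargs["stats"] = stats
        cfg = cls(presets=presets, **kwargs)
        cfg.validate()
        return cfg


def convert_human_dose(
    human_total_mg: float,
    human_mass_kg: float = 70.0,
    species_factor: float = RABBIT_BSA_FACTOR,
) -> float:
    """Convert a total human daily dose to a per-kg animal dose.

    Body-surface-area scaling: ``(human_total_mg / human_mass_kg) *
    species_factor``, rounded to one decimal (mg/kg/day).  With the rabbit
    factor 3.6, a 1000 mg/day dose for a 70 kg human becomes 51.4 mg/kg.
    """
    if human_total_mg <= 0 or human_mass_kg <= 0 or species_factor <= 0:
        raise ValueError("dose conversion inputs must all be > 0")
    return round(human_total_mg / human_mass_kg * species_factor, 1)


def _component_split(total_mean: float) -> tuple[float, float, float]:
    # Allocate a compartment-total target across structure (0-11),
    # density (0-4) and clusters (0-3) proportionally to scale width.
    return (total_mean * 11 / 18, total_mean * 4 / 18, total_mean * 3 / 18)


def _binomial_pmf(k_max: int, mean: float) -> list[float]:
    """Binomial(k_max, mean/k_max) pmf — a unimodal ordinal distribution
    with exactly the requested mean on support 0..k_max."""
    from scipy.stats import binom

    p = min(max(mean / k_max, 0.0), 1.0)
    return [float(binom.pmf(k, k_max, p)) for k in range(k_max + 1)]


def _ordinal_dists(compartment_totals: Mapping[Compartment, float]):
    structure, density, clusters = {}, {}, {}
    for c, total in compartment_totals.items():
        ms, md, mc = _component_split(total)
        structure[c] = _binomial_pmf(11, ms)
        density[c] = _binomial_pmf(4, md)
        clusters[c] = _binomial_pmf(3, mc)
    return structure, density, clusters


# ---------------------------------------------------------------------------
# Default presets — the study conditions.
#
# Morphometry truths (medial femoral condyle): group thickness means/SDs and
# normalized-roughness means/SDs; SDs are the between-animal values implied
# by SEM * sqrt(11).  Area truths use a group-specific evaluation window of
# length area_truth / thickness_mean so the expected windowed area equals the
# target (the full 7 mm ROI area is ~1.4e6 um2 for 200 um cartilage, an order
# of magnitude above the area targets; see docs/methods.md).
#
# OARSI compartment-total targets: control (MF 7.27, MT 5.82, LT 7.45) with
# LF as the residual 7.73 so the four compartments total 28.27; Channa
# (MF 4.36, MT 2.55, LT 3.82, LF residual 5.00, total 15.73); glucosamine
# MF 3.64 with the remaining 13.91 split evenly (total 17.55).
#
# Macroscopic grade distributions are calibrated so that each compartment's
# median matches the study's per-compartment grading and the induced median
# of the four-compartment sum is 4 (Channa), 9 (glucosamine), 10 (control).
# ---------------------------------------------------------------------------

_SQ11 = float(np.sqrt(11.0))

_MACRO = {
    Group.CHANNA: {
        Compartment.LF: (0.90, 0.08, 0.02, 0.00),
        Compartment.MF: (0.90, 0.08, 0.02, 0.00),
        Compartment.LT: (0.90, 0.08, 0.02, 0.00),
        Compartment.MT: (0.90, 0.08, 0.02, 0.00),
    },
    Group.GLUCOSAMINE: {
        Compartment.LF: (0.05, 0.35, 0.50, 0.10),
        Compartment.MF: (0.10, 0.60, 0.25, 0.05),
        Compartment.LT: (0.10, 0.60, 0.25, 0.05),
        Compartment.MT: (0.10, 0.55, 0.30, 0.05),
    },
    Group.CONTROL: {
        Compartment.LF: (0.05, 0.25, 0.55, 0.15),
        Compartment.MF: (0.05, 0.30, 0.50, 0.15),
        Compartment.LT: (0.10, 0.60, 0.25, 0.05),
        Compartment.MT: (0.10, 0.55, 0.30, 0.05),
    },
}

_OARSI_TOTALS = {
    Group.CHANNA: {
        Compartment.MF: 4.36,
        Compartment.LF: 5.00,
        Compartment.MT: 2.55,
        Compartment.LT: 3.82,
    },
    Group.GLUCOSAMINE: {
        Compartment.MF: 3.64,
        Compartment.LF: 4.64,
        Compartment.MT: 4.63,
        Compartment.LT: 4.64,
    },
    Group.CONTROL: {
        Compartment.MF: 7.27,
        Compartment.LF: 7.73,
        Compartment.MT: 5.82,
        Compartment.LT: 7.45,
    },
}

_MORPHOMETRY = {
    # group: (thickness mean, thickness SD, ratio mean, ratio SD, area truth)
    Group.CHANNA: (242.82, 12.79 * _SQ11, 22.18, 2.35 * _SQ11, 97722.27),
    Group.GLUCOSAMINE: (211.73, 10.60 * _SQ11, 33.82, 2.17 * _SQ11, 79368.91),
    Group.CONTROL: (155.73, 19.50 * _SQ11, 45.10, 4.17 * _SQ11, 57895.82),
}

_SERUM = {
    # COMP elevated in controls (cartilage degradation); COX-2 and PGE2 do
    # not separate the arms.
    Group.CHANNA: ({"COMP": 30.0, "COX2": 18.0, "PGE2": 30.0}, {"COMP": 8.0, "COX2": 5.0, "PGE2": 9.0}),
    Group.GLUCOSAMINE: ({"COMP": 32.0, "COX2": 18.0, "PGE2": 30.0}, {"COMP": 8.0, "COX2": 5.0, "PGE2": 9.0}),
    Group.CONTROL: ({"COMP": 42.0, "COX2": 18.0, "PGE2": 30.0}, {"COMP": 9.0, "COX2": 5.0, "PGE2": 9.0}),
}

_DOSES = {
    Group.CHANNA: convert_human_dose(1000.0),  # 51.4 mg/kg
    Group.GLUCOSAMINE: 77.5,  # recorded as administered; see docs/methods.md
    Group.CONTROL: None,
}

_LESION_RATES = {Group.CHANNA: 0.8, Group.GLUCOSAMINE: 1.2, Group.CONTROL: 2.0}


def default_presets() -> dict[Group, GroupPreset]:
    presets = {}
    for g in Group:
        t_mean, t_sd, r_mean, r_sd, area = _MORPHOMETRY[g]
        structure, density, clusters = _ordinal_dists(_OARSI_TOTALS[g])
        means, sds = _SERUM[g]
        presets[g] = GroupPreset(
            group=g,
            dose_mg_per_kg=_DOSES[g],
            true_thickness_mean=t_mean,
            true_thickness_sd_between_animals=t_sd,
            normalized_roughness_mean=r_mean,
            normalized_roughness_sd=r_sd,
            area_truth_um2=area,
            area_window_um=area / t_mean,
            lesion_rate=_LESION_RATES[g],
            structure_dist=structure,
            density_dist=density,
            cluster_dist=clusters,
            macro_grade_dist={c: list(v) for c, v in _MACRO[g].items()},
            serum_means=dict(means),
            serum_sds=dict(sds),
        )
    return presets


def default_config(master_seed: int = 0) -> StudyConfig:
    """The default three-arm, n=11-per-arm study configuration."""
    cfg = StudyConfig(presets=default_presets(), master_seed=master_seed)
    cfg.validate()
    return cfg
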