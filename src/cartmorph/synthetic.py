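"""Synthetic ACLT osteoarthritis study generator.

Produces complete three-arm studies (Channa extract, glucosamine, untreated
control; 11 rabbits per arm; four joint compartments per knee) whose true
underlying parameters are the configurable :class:`~cartmorph.presets.GroupPreset`
values, so every downstream stage — boundary-based morphometry, ordinal
scoring, group statistics — can be validated by parameter recovery.

Randomness is fully reproducible: a single master seed spawns one
independent substream per animal (plus one for group assignment), in
enrolment order; this spawn order is part of the serialization contract.
Group labels are assigned by block randomization in blocks of six (two per
arm per block), with a final balanced partial block when the cohort size is
not a multiple of the block size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .presets import (
    SERUM_ASSAY_RANGE_NG_ML,
    Compartment,
    ConfigurationError,
    Group,
    GroupPreset,
    StudyConfig,
    default_config,
)
from .profiles import CartilageProfile, build_profile
from .scoring import (
    STRUCTURE_RUBRIC,
    DensityPattern,
    InkUptake,
    Lesion,
    LesionDescriptor,
)

__all__ = [
    "CompartmentRecord",
    "AnimalRecord",
    "StudyDataset",
    "simulate_study",
    "synth_profile",
    "synth_serum",
    "render_section_image",
    "ResolutionError",
    "assign_groups",
]


class ResolutionError(ValueError):
    """Raised when the requested pixel size cannot resolve the tissue band."""

logger = logging.getLogger(__name__)

_INK_BY_GRADE = {1: InkUptake.NONE, 2: InkUptake.MINIMAL_FOCAL,
                 3: InkUptake.LARGE_FOCAL_PATCHES, 4: InkUptake.BONE_EXPOSED}
_DENSITY_BY_SCORE = list(DensityPattern)


@dataclass
class CompartmentRecord:
    """Everything generated for one joint compartment of one animal."""

    profile: CartilageProfile
    descriptor: LesionDescriptor
    density_pattern: DensityPattern
    cluster_count: int
    ink: InkUptake


@dataclass
class AnimalRecord:
    animal_id: str
    group: Group
    compartments: dict[Compartment, CompartmentRecord]
    serum: dict[str, float]  # analyte -> ng/ml

    def __post_init__(self):
        if set(self.compartments) != set(Compartment):
            raise ConfigurationError(
                f"{self.animal_id}: expected exactly the 4 compartments "
                f"{[c.value for c in Compartment]}"
            )


@dataclass
class StudyDataset:
    animals: list[AnimalRecord]
    config_fingerprint: str
    master_seed: int
    config: StudyConfig = field(repr=False, default=None)

    def by_group(self, group: Group) -> list[AnimalRecord]:
        return [a for a in self.animals if a.group == group]


def assign_groups(n_per_group: int, block_size: int, rng: np.random.Generator,
                  groups: tuple[Group, ...] = tuple(Group)) -> list[Group]:
    """Block randomization: each block holds equal numbers of every arm.

    The trailing partial block is itself balanced, so group sizes are
    conserved exactly for any seed.
    """
    k = len(groups)
    if block_size % k:
        raise ConfigurationError("block_size must be a multiple of the group count")
    n_total = n_per_group * k
    per_block = block_size // k
    labels: list[Group] = []
    remaining = {g: n_per_group for g in groups}
    while len(labels) < n_total:
        take = min(per_block, min(remaining.values()))
        block = [g for g in groups for _ in range(min(take, remaining[g]))]
        block = [block[i] for i in rng.permutation(len(block))]
        for g in block:
            remaining[g] -= 1
        labels.extend(block)
    return labels[:n_total]


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draw parameterised by its own mean and SD (positive support,
    exact mean — no truncation bias for positive biological quantities)."""
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def synth_serum(preset: GroupPreset, rng: np.random.Generator) -> dict[str, float]:
    """Per-animal serum analyte concentrations, ng/ml.

    Lognormal draws at the preset mean/SD, clipped to the assay detection
    range; clipping is logged as it mimics an out-of-range ELISA reading.
    """
    lo, hi = SERUM_ASSAY_RANGE_NG_ML
    out = {}
    for analyte, mean in preset.serum_means.items():
        v = float(_lognormal(rng, mean, preset.serum_sds.get(analyte, 0.0)))
        if v < lo or v > hi:
            logger.warning("serum %s = %.2f ng/ml outside assay range, clipped", analyte, v)
            v = min(max(v, lo), hi)
        out[analyte] = v
    return out


def _descriptor_from_structure_score(score: int, rng: np.random.Generator) -> LesionDescriptor:
    """Realize a lesion inventory whose rubric score equals ``score``.

    The drawn structure category is inverted through the 12-row rubric:
    even scores >= 2 get an extent below 50%, odd ones at or above 50%.
    With probability 0.4 a strictly less severe secondary lesion is added,
    which exercises the most-severe-lesion rule without changing the score.
    """
    def realize(s: int) -> Lesion:
        depth, extent_class = STRUCTURE_RUBRIC[s]
        if extent_class == "ge50":
            extent = float(rng.uniform(0.5, 0.95))
        elif extent_class == "lt50":
            extent = float(rng.uniform(0.05, 0.45))
        else:  # surface irregularity
            extent = float(rng.uniform(0.05, 0.30))
        return Lesion(depth, extent)

    if score == 0:
        return LesionDescriptor(())
    lesions = [realize(score)]
    if score >= 2 and rng.random() < 0.4:
        lesions.append(realize(int(rng.integers(1, score))))
    return LesionDescriptor(tuple(lesions))


def _cluster_count_from_score(score: int, rng: np.random.Generator) -> int:
    if score == 0:
        return 0
    if score == 1:
        return int(rng.integers(1, 4))
    if score == 2:
        return int(rng.integers(4, 8))
    return int(rng.integers(8, 13))


def synth_profile(
    preset: GroupPreset,
    rng: np.random.Generator,
    config: StudyConfig | None = None,
    thickness_um: float | None = None,
    rms_um: float | None = None,
    lesions: tuple[Lesion, ...] | None = None,
) -> CartilageProfile:
    """Generate one cross-section from a group preset.

    Thickness and fibrillation RMS default to fresh per-animal draws from
    the preset distributions; pass explicit values to reuse an animal's
    joint-level truth across compartments.  Lesions are carved only when a
    lesion inventory is supplied (or the study config requests carving).
    """
    config = config or default_config()
    if thickness_um is None:
        thickness_um = float(_lognormal(rng, preset.true_thickness_mean,
                                        preset.true_thickness_sd_between_animals))
    if rms_um is None:
        ratio = float(_lognormal(rng, preset.normalized_roughness_mean,
                                 preset.normalized_roughness_sd))
        rms_um = ratio * thickness_um / 1000.0
    return build_profile(thickness_um, rms_um, config.geometry, rng, lesions=lesions)


def render_section_image(
    profile: CartilageProfile,
    pixel_size: float = 2.0,
    rng: np.random.Generator | None = None,
    ruler_length_um: float = 1000.0,
) -> np.ndarray:
    """Render a grayscale raster of a section, emulating a microscope image.

    The cartilage band (surface down to tidemark) is filled with a bright
    tissue intensity plus Gaussian noise over a dark background, and a 1 mm
    black ruler bar is drawn below the tissue for scale calibration.  Raises
    :class:`ResolutionError` when the band would be under 3 px thick.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    rng = rng if rng is not None else np.random.default_rng(0)

    xs = profile.surface[:, 0]
    x_lo = max(xs[0], profile.tidemark[0, 0])
    x_hi = min(xs[-1], profile.tidemark[-1, 0])
    x_grid = np.arange(x_lo, x_hi, pixel_size)
    y_s = np.interp(x_grid, profile.surface[:, 0], profile.surface[:, 1])
    y_t = np.interp(x_grid, profile.tidemark[:, 0], profile.tidemark[:, 1])

    min_band_px = float(np.min(y_s - y_t)) / pixel_size
    if min_band_px < 3:
        raise ResolutionError(
            f"tissue band is {min_band_px:.1f} px thick at {pixel_size} um/px; "
            "need >= 3 px — use a finer pixel size"
        )

    ruler_gap_um = 120.0
    y_top = float(y_s.max()) + 40.0
    y_bottom = float(y_t.min()) - ruler_gap_um
    n_rows = int(np.ceil((y_top - y_bottom) / pixel_size)) + 1
    n_cols = x_grid.size

    img = np.clip(rng.normal(40.0, 5.0, size=(n_rows, n_cols)), 0, 255)

    rows_s = np.clip(np.round((y_top - y_s) / pixel_size).astype(int), 0, n_rows - 1)
    rows_t = np.clip(np.round((y_top - y_t) / pixel_size).astype(int), 0, n_rows - 1)
    for c in range(n_cols):
        tissue = np.clip(rng.normal(200.0, 10.0, size=rows_t[c] - rows_s[c] + 1), 150, 255)
        img[rows_s[c]: rows_t[c] + 1, c] = tissue

    # 1 mm ruler bar: pitch black, a few px thick, centred near the bottom
    bar_px = int(round(ruler_length_um / pixel_size))
    if bar_px >= n_cols:
        raise ResolutionError("image too narrow to hold the ruler bar")
    c0 = (n_cols - bar_px) // 2
    r0 = n_rows - max(3, int(20.0 / pixel_size))
    img[r0: r0 + max(2, int(8.0 / pixel_size)), c0: c0 + bar_px] = 0.0

    return img.astype(np.uint8)


def _draw_lesion_inventory(preset: GroupPreset, rng: np.random.Generator) -> tuple[Lesion, ...]:
    """Erosion lesions for geometric carving, at the preset's lesion rate."""
    from .scoring import LesionDepth

    n = int(rng.poisson(preset.lesion_rate))
    depths = (LesionDepth.EROSION_ONE_THIRD, LesionDepth.EROSION_TWO_THIRDS,
              LesionDepth.FULL_DEPTH)
    return tuple(
        Lesion(depths[int(rng.integers(0, len(depths)))], float(rng.uniform(0.05, 0.6)))
        for _ in range(n)
    )


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyDataset:
    """Simulate one complete study.

    Deterministic for a fixed ``(config, seed)``: the seed feeds a
    ``SeedSequence`` whose first spawn drives block randomization and whose
    subsequent spawns give each animal an independent substream, consumed in
    a fixed order (thickness/roughness draw, then per-compartment descriptor
    draws in MF, LF, MT, LT order, then serum).
    """
    config = config or default_config()
    config.validate()

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(1 + config.n_animals)
    assign_rng = np.random.default_rng(streams[0])
    labels = assign_groups(config.n_per_group, config.block_size, assign_rng)

    animals = []
    for i, group in enumerate(labels):
        rng = np.random.default_rng(streams[1 + i])
        preset = config.presets[group]

        thickness = float(_lognormal(rng, preset.true_thickness_mean,
                                     preset.true_thickness_sd_between_animals))
        ratio = float(_lognormal(rng, preset.normalized_roughness_mean,
                                 preset.normalized_roughness_sd))
        rms = ratio * thickness / 1000.0

        compartments = {}
        for comp in Compartment:
            s_score = int(rng.choice(12, p=np.asarray(preset.structure_dist[comp], float)))
            descriptor = _descriptor_from_structure_score(s_score, rng)
            d_score = int(rng.choice(5, p=np.asarray(preset.density_dist[comp], float)))
            c_score = int(rng.choice(4, p=np.asarray(preset.cluster_dist[comp], float)))
            grade = 1 + int(rng.choice(4, p=np.asarray(preset.macro_grade_dist[comp], float)))

            carve = None
            if config.carve_lesions_in_profiles:
                carve = _draw_lesion_inventory(preset, rng)
            profile = synth_profile(
                preset, rng, config=config,
                thickness_um=thickness, rms_um=rms, lesions=carve,
            )
            compartments[comp] = CompartmentRecord(
                profile=profile,
                descriptor=descriptor,
                density_pattern=_DENSITY_BY_SCORE[d_score],
                cluster_count=_cluster_count_from_score(c_score, rng),
                ink=_INK_BY_GRADE[grade],
            )

        animals.append(
            AnimalRecord(
                animal_id=f"R{i + 1:03d}",
                group=group,
                compartments=compartments,
                serum=synth_serum(preset, rng),
            )
        )

    return StudyDataset(
        animals=animals,
        config_fingerprint=config.fingerprint(),
        master_seed=seed,
        config=config,
    )
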