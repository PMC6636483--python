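"""File formats for the pipeline stages.

All tabular data are RFC-4180 CSV (UTF-8), geometry and statistics are JSON,
and configuration is YAML.  Column dictionary (units in parentheses):

``animals.csv`` — one row per animal x compartment:
    animal_id, group, compartment, lesions (JSON list of {depth,
    extent_fraction}), density_pattern, cluster_count, ink,
    serum_COMP / serum_COX2 / serum_PGE2 (ng/ml, repeated per row).

``profiles/<animal>_<compartment>.json`` — one section:
    animal_id, compartment, scale (um/px), roi, flanks, surface and
    tidemark as [[x, y], ...] (um), truth (generator bookkeeping).

``morphometry.csv`` — one row per measured section:
    animal_id, compartment, thickness_um (um), area_um2 (um^2), rms_um (um),
    normalized_roughness (dimensionless x1000), n_digitized.

``scores.csv`` — one row per animal x compartment plus one TOTAL row per
    animal: animal_id, group, compartment, structure, density, clusters,
    compartment_total, macro_grade.

``stats.json`` — endpoint name -> full statistics report.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .presets import Compartment, Group, StudyConfig
from .profiles import CartilageProfile
from .scoring import DensityPattern, InkUptake, Lesion, LesionDescriptor
from .synthetic import StudyDataset

__all__ = [
    "SchemaError",
    "load_config",
    "save_config",
    "write_study",
    "read_animals_csv",
    "write_profile_json",
    "read_profile_json",
    "write_morphometry_csv",
    "read_morphometry_csv",
    "write_scores_csv",
    "read_scores_csv",
    "write_stats_json",
    "read_stats_json",
]

ANIMALS_COLUMNS = [
    "animal_id", "group", "compartment", "lesions", "density_pattern",
    "cluster_count", "ink", "serum_COMP", "serum_COX2", "serum_PGE2",
]
MORPHOMETRY_COLUMNS = [
    "animal_id", "compartment", "thickness_um", "area_um2", "rms_um",
    "normalized_roughness", "n_digitized",
]
SCORES_COLUMNS = [
    "animal_id", "group", "compartment", "structure", "density", "clusters",
    "compartment_total", "macro_grade",
]


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def save_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> StudyConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: config must be a mapping")
    return StudyConfig.from_dict(data)


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------


def _write_csv(path: Path, columns: list[str], rows: Iterable[Mapping]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def _read_csv(path: str | Path, required: list[str]) -> list[dict]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header {required}")
        missing = set(required) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
        rows = list(reader)
    if not rows:
        raise SchemaError(f"{path}: no data rows")
    return rows


# ---------------------------------------------------------------------------
# Study dataset
# ---------------------------------------------------------------------------


def _animal_rows(dataset: StudyDataset) -> Iterable[dict]:
    for animal in dataset.animals:
        for comp in Compartment:
            rec = animal.compartments[comp]
            yield {
                "animal_id": animal.animal_id,
                "group": animal.group.value,
                "compartment": comp.value,
                "lesions": json.dumps([l.to_dict() for l in rec.descriptor.lesions]),
                "density_pattern": rec.density_pattern.value,
                "cluster_count": rec.cluster_count,
                "ink": rec.ink.value,
                "serum_COMP": f"{animal.serum['COMP']:.4f}",
                "serum_COX2": f"{animal.serum['COX2']:.4f}",
                "serum_PGE2": f"{animal.serum['PGE2']:.4f}",
            }


def write_profile_json(profile: CartilageProfile, path: str | Path,
                       animal_id: str = "", compartment: str = "") -> None:
    doc = {
        "animal_id": animal_id,
        "compartment": compartment,
        "scale": profile.scale,
        "roi": list(profile.roi),
        "flanks": [list(f) for f in profile.flanks],
        "surface": np.round(profile.surface, 4).tolist(),
        "tidemark": np.round(profile.tidemark, 4).tolist(),
        "truth": profile.truth,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_profile_json(path: str | Path) -> tuple[CartilageProfile, str, str]:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("surface", "tidemark", "roi", "flanks"):
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}")
    profile = CartilageProfile(
        surface=np.asarray(doc["surface"], dtype=float),
        tidemark=np.asarray(doc["tidemark"], dtype=float),
        roi=tuple(doc["roi"]),
        flanks=tuple(tuple(f) for f in doc["flanks"]),
        scale=float(doc.get("scale", 1.0)),
        truth=doc.get("truth", {}),
    )
    try:
        profile.validate(roi_width=profile.roi[1] - profile.roi[0])
    except ValueError as exc:
        raise SchemaError(f"{path}: invalid profile: {exc}") from exc
    return profile, doc.get("animal_id", ""), doc.get("compartment", "")


def write_study(dataset: StudyDataset, out_dir: str | Path,
                write_images: bool = False) -> None:
    """Write animals.csv, profiles/*.json, truth.json (and optional PNGs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(out / "animals.csv", ANIMALS_COLUMNS, _animal_rows(dataset))

    profile_dir = out / "profiles"
    profile_dir.mkdir(exist_ok=True)
    truth = {"config_fingerprint": dataset.config_fingerprint,
             "master_seed": dataset.master_seed, "animals": {}}
    for animal in dataset.animals:
        truth["animals"][animal.animal_id] = {
            "group": animal.group.value,
            "profile_truth": animal.compartments[Compartment.MF].profile.truth,
        }
        for comp, rec in animal.compartments.items():
            write_profile_json(
                rec.profile, profile_dir / f"{animal.animal_id}_{comp.value}.json",
                animal_id=animal.animal_id, compartment=comp.value,
            )
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    if write_images:
        from PIL import Image
        from .synthetic import render_section_image

        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for animal in dataset.animals:
            rec = animal.compartments[Compartment.MF]
            img = render_section_image(rec.profile, pixel_size=dataset.config.geometry.pixel_size)
            Image.fromarray(img).save(img_dir / f"{animal.animal_id}_MF.png")


def read_animals_csv(path: str | Path) -> list[dict]:
    """Rows of animals.csv with typed fields (lesion descriptors decoded)."""
    rows = _read_csv(path, ANIMALS_COLUMNS)
    out = []
    for i, row in enumerate(rows):
        try:
            lesions = tuple(Lesion.from_dict(d) for d in json.loads(row["lesions"]))
            out.append({
                "animal_id": row["animal_id"],
                "group": Group(row["group"]),
                "compartment": Compartment(row["compartment"]),
                "descriptor": LesionDescriptor(lesions),
                "density_pattern": DensityPattern(row["density_pattern"]),
                "cluster_count": int(row["cluster_count"]),
                "ink": InkUptake(row["ink"]),
                "serum": {a: float(row[f"serum_{a}"]) for a in ("COMP", "COX2", "PGE2")},
            })
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Morphometry / scores / stats
# ---------------------------------------------------------------------------


def write_morphometry_csv(rows: Iterable[Mapping], path: str | Path) -> None:
    formatted = (
        {
            "animal_id": r["animal_id"],
            "compartment": r["compartment"],
            "thickness_um": f"{r['thickness_um']:.4f}",
            "area_um2": f"{r['area_um2']:.2f}",
            "rms_um": f"{r['rms_um']:.5f}",
            "normalized_roughness": f"{r['normalized_roughness']:.5f}",
            "n_digitized": r["n_digitized"],
        }
        for r in rows
    )
    _write_csv(Path(path), MORPHOMETRY_COLUMNS, formatted)


def read_morphometry_csv(path: str | Path) -> list[dict]:
    rows = _read_csv(path, MORPHOMETRY_COLUMNS)
    out = []
    for i, row in enumerate(rows):
        try:
            out.append({
                "animal_id": row["animal_id"],
                "compartment": row["compartment"],
                "thickness_um": float(row["thickness_um"]),
                "area_um2": float(row["area_um2"]),
                "rms_um": float(row["rms_um"]),
                "normalized_roughness": float(row["normalized_roughness"]),
                "n_digitized": int(row["n_digitized"]),
            })
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_scores_csv(rows: Iterable[Mapping], path: str | Path) -> None:
    _write_csv(Path(path), SCORES_COLUMNS, rows)


def read_scores_csv(path: str | Path) -> list[dict]:
    rows = _read_csv(path, SCORES_COLUMNS)
    out = []
    for i, row in enumerate(rows):
        try:
            out.append({
                "animal_id": row["animal_id"],
                "group": row["group"],
                "compartment": row["compartment"],
                "structure": int(row["structure"]),
                "density": int(row["density"]),
                "clusters": int(row["clusters"]),
                "compartment_total": int(row["compartment_total"]),
                "macro_grade": int(row["macro_grade"]),
            })
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_stats_json(reports: Mapping[str, Mapping], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True, allow_nan=True)


def read_stats_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
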