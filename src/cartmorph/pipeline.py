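"""End-to-end orchestration: simulate -> measure -> score -> analyze -> report.

Each stage reads and writes the documented file formats (see
:mod:`cartmorph.io`), so stages can also be run individually from the CLI.
A :class:`RunManifest` records the configuration fingerprint, seed, package
version, stage timestamps and output hashes; rerunning with identical inputs
reproduces byte-identical ``stats.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import (
    read_animals_csv,
    read_morphometry_csv,
    read_profile_json,
    read_scores_csv,
    write_morphometry_csv,
    write_scores_csv,
    write_stats_json,
    write_study,
)
from .morphometry import measure_profile
from .presets import Compartment, StudyConfig, default_config
from .scoring import aggregate_joint, score_compartment
from .stats import EndpointVector, analyze_endpoint
from .synthetic import simulate_study

__all__ = ["RunManifest", "PipelineError", "run_pipeline",
           "measure_stage", "score_stage", "analyze_stage", "report_stage"]

logger = logging.getLogger(__name__)

#: Endpoint name -> (source, scale); the analyze stage builds one vector each.
ENDPOINTS = {
    "thickness_um": ("morphometry", "continuous"),
    "area_um2": ("morphometry", "continuous"),
    "rms_um": ("morphometry", "continuous"),
    "normalized_roughness": ("morphometry", "continuous"),
    "histology_total": ("scores", "continuous"),
    "macroscopic_total": ("scores", "ordinal"),
    "serum_COMP": ("serum", "continuous"),
    "serum_COX2": ("serum", "continuous"),
    "serum_PGE2": ("serum", "continuous"),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config_fingerprint: str
    seed: int
    version: str
    stages: dict[str, float] = field(default_factory=dict)  # stage -> unix time
    output_hashes: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, *paths: Path) -> None:
        self.stages[stage] = time.time()
        for p in paths:
            if p.is_file():
                self.output_hashes[str(p.name)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def to_dict(self) -> dict:
        return {
            "config_fingerprint": self.config_fingerprint,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "output_hashes": self.output_hashes,
        }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def measure_stage(profiles_dir: str | Path, out_csv: str | Path,
                  compartments: tuple[str, ...] = ("MF",)) -> int:
    """Measure every stored profile of the selected compartments.

    The quantitative assessment targets the medial femoral condyle (the
    compartment with the most advanced degenerative change), so only MF is
    measured by default.
    """
    profiles_dir = Path(profiles_dir)
    paths = sorted(profiles_dir.glob("*.json"))
    if not paths:
        raise PipelineError(f"no profile JSON files found in {profiles_dir}")
    rows = []
    for path in paths:
        profile, animal_id, compartment = read_profile_json(path)
        if compartment not in compartments:
            continue
        result = measure_profile(profile)
        rows.append({"animal_id": animal_id, "compartment": compartment,
                     **result.to_dict()})
    if not rows:
        raise PipelineError(f"no profiles for compartments {compartments} in {profiles_dir}")
    write_morphometry_csv(rows, out_csv)
    return len(rows)


def score_stage(animals_csv: str | Path, out_csv: str | Path) -> int:
    """Apply the OARSI rubric and India-ink grading to every compartment,
    then append one TOTAL row per animal with the joint sums."""
    rows = read_animals_csv(animals_csv)
    per_animal: dict[str, dict] = defaultdict(dict)
    groups: dict[str, str] = {}
    for row in rows:
        oarsi = score_compartment(row["descriptor"], row["density_pattern"],
                                  row["cluster_count"])
        per_animal[row["animal_id"]][row["compartment"]] = (oarsi, row["ink"])
        groups[row["animal_id"]] = row["group"].value

    out_rows = []
    for animal_id, comps in per_animal.items():
        joint = aggregate_joint({c: s for c, (s, _) in comps.items()},
                                {c: ink for c, (_, ink) in comps.items()})
        for comp in Compartment:
            oarsi = joint.oarsi[comp]
            out_rows.append({
                "animal_id": animal_id, "group": groups[animal_id],
                "compartment": comp.value,
                "structure": oarsi.structure, "density": oarsi.density,
                "clusters": oarsi.clusters,
                "compartment_total": oarsi.compartment_total,
                "macro_grade": joint.macro_grades[comp],
            })
        out_rows.append({
            "animal_id": animal_id, "group": groups[animal_id],
            "compartment": "TOTAL",
            "structure": sum(s.structure for s in joint.oarsi.values()),
            "density": sum(s.density for s in joint.oarsi.values()),
            "clusters": sum(s.clusters for s in joint.oarsi.values()),
            "compartment_total": joint.histology_total,
            "macro_grade": joint.macroscopic_total,
        })
    write_scores_csv(out_rows, out_csv)
    return len(out_rows)


def build_endpoints(
    morphometry_rows: list[dict],
    score_rows: list[dict],
    animal_rows: list[dict],
) -> dict[str, EndpointVector]:
    """Assemble per-endpoint group vectors from the stage outputs."""
    group_of = {r["animal_id"]: r["group"].value for r in animal_rows}

    vectors: dict[str, dict[str, list[float]]] = {
        name: defaultdict(list) for name in ENDPOINTS
    }
    for r in morphometry_rows:
        g = group_of[r["animal_id"]]
        for name in ("thickness_um", "area_um2", "rms_um", "normalized_roughness"):
            vectors[name][g].append(r[name])
    for r in score_rows:
        if r["compartment"] != "TOTAL":
            continue
        g = group_of[r["animal_id"]]
        vectors["histology_total"][g].append(float(r["compartment_total"]))
        vectors["macroscopic_total"][g].append(float(r["macro_grade"]))
    seen = set()
    for r in animal_rows:
        if r["animal_id"] in seen:
            continue
        seen.add(r["animal_id"])
        g = group_of[r["animal_id"]]
        for analyte, v in r["serum"].items():
            vectors[f"serum_{analyte}"][g].append(v)

    out = {}
    for name, (source, scale) in ENDPOINTS.items():
        groups = {g: np.asarray(v) for g, v in vectors[name].items() if v}
        if len(groups) >= 2:
            out[name] = EndpointVector(name=name, groups=groups, scale=scale)
    return out


def analyze_stage(
    morphometry_csv: str | Path,
    scores_csv: str | Path,
    animals_csv: str | Path,
    out_json: str | Path,
    alpha: float = 0.05,
    adjust_method: str = "bonferroni",
) -> dict:
    endpoints = build_endpoints(
        read_morphometry_csv(morphometry_csv),
        read_scores_csv(scores_csv),
        read_animals_csv(animals_csv),
    )
    reports = {
        name: analyze_endpoint(ep, alpha=alpha, adjust_method=adjust_method).to_dict()
        for name, ep in sorted(endpoints.items())
    }
    write_stats_json(reports, out_json)
    return reports


def _fmt_summary(summary: dict) -> str:
    if "mean" in summary:
        return f"{summary['mean']:.2f} ± {summary['sem']:.2f}"
    return f"{summary['median']:.2f} ({summary['iqr']:.2f})"


def report_stage(stats_json: str | Path, out_md: str | Path,
                 plots_png: str | Path | None = None,
                 endpoint_data: dict[str, EndpointVector] | None = None) -> None:
    """Render stats.json as a markdown report with per-group summary tables
    (mean ± SEM for continuous endpoints, median (IQR) for ordinal ones)."""
    with open(stats_json, encoding="utf-8") as fh:
        reports = json.load(fh)

    lines = ["# Study report", ""]
    for name, rep in reports.items():
        lines.append(f"## {name}")
        lines.append("")
        lines.append(f"Plan: {rep['plan']} — {rep['omnibus']['test']} "
                     f"statistic {rep['omnibus']['statistic']:.3f}, "
                     f"p = {rep['omnibus']['p']:.4g}")
        lines.append("")
        lines.append("| group | n | summary |")
        lines.append("|---|---|---|")
        for g, s in rep["summaries"].items():
            lines.append(f"| {g} | {s['n']} | {_fmt_summary(s)} |")
        lines.append("")
        lines.append("| pair | estimate | adjusted p | significant |")
        lines.append("|---|---|---|---|")
        for c in rep["pairwise"]:
            p_adj = "—" if c["p_adjusted"] is None else f"{c['p_adjusted']:.4g}"
            est = c["estimate"]
            if c["critical_difference"] is not None:
                est_s = f"{est:.3f} (CD {c['critical_difference']:.3f})"
            else:
                est_s = f"{est:.3f}"
            lines.append(f"| {c['group_a']} vs {c['group_b']} | {est_s} | "
                         f"{p_adj} | {'yes' if c['significant'] else 'no'} |")
        lines.append("")
    Path(out_md).write_text("\n".join(lines), encoding="utf-8")

    if plots_png is not None and endpoint_data:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = sorted(endpoint_data)
        ncols = 3
        nrows = int(np.ceil(len(names) / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows))
        for ax, name in zip(np.ravel(axes), names):
            ep = endpoint_data[name]
            ax.boxplot(list(ep.groups.values()), tick_labels=list(ep.groups))
            ax.set_title(name, fontsize=9)
        for ax in np.ravel(axes)[len(names):]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(plots_png, dpi=110)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: StudyConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = "study_run",
    write_images: bool = False,
) -> RunManifest:
    """Execute all stages in order under ``out_dir``.

    Layout: ``study/`` (animals.csv, profiles/, truth.json),
    ``morphometry.csv``, ``scores.csv``, ``report/stats.json``,
    ``report/report.md``, ``report/boxplots.png``, ``manifest.json``.
    """
    config = config or default_config(master_seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_fingerprint=config.fingerprint(), seed=seed,
                           version=__version__)

    stage = "simulate"
    try:
        dataset = simulate_study(config, seed=seed)
        study_dir = out / "study"
        write_study(dataset, study_dir, write_images=write_images)
        manifest.record(stage, study_dir / "animals.csv", study_dir / "truth.json")

        stage = "measure"
        measure_stage(study_dir / "profiles", out / "morphometry.csv")
        manifest.record(stage, out / "morphometry.csv")

        stage = "score"
        score_stage(study_dir / "animals.csv", out / "scores.csv")
        manifest.record(stage, out / "scores.csv")

        stage = "analyze"
        report_dir = out / "report"
        report_dir.mkdir(exist_ok=True)
        analyze_stage(out / "morphometry.csv", out / "scores.csv",
                      study_dir / "animals.csv", report_dir / "stats.json",
                      alpha=config.stats.alpha,
                      adjust_method=config.stats.adjust_method)
        manifest.record(stage, report_dir / "stats.json")

        stage = "report"
        endpoints = build_endpoints(
            read_morphometry_csv(out / "morphometry.csv"),
            read_scores_csv(out / "scores.csv"),
            read_animals_csv(study_dir / "animals.csv"),
        )
        report_stage(report_dir / "stats.json", report_dir / "report.md",
                     plots_png=report_dir / "boxplots.png",
                     endpoint_data=endpoints)
        manifest.record(stage, report_dir / "report.md")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return manifest
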