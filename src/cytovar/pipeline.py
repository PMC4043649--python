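"""Study orchestration: simulate -> preprocess -> gate -> quantify -> summarize.

The in-memory drivers (`run_wt_cohort`, `run_duplicate_study`,
`run_volume_pair_study`, `run_timecourse_study`) execute whole study
designs deterministically from a seed.  The file-based path writes each
acquisition as FCS 3.1 plus a ground-truth sidecar CSV and a JSON manifest,
and `run_pipeline` replays a manifest from disk into tidy result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import EventTable
from .fcs import read_fcs, write_fcs
from .gating import GateSet, classify_events, identify_beads, template_midpoint_gates
from .panel import SUBSET_LABELS
from .preprocess import SpilloverMatrix, compensate, qc_check
from .quantify import SampleResult, quantify_sample, results_to_tidy_csv
from .synth import (
    GeneratorConfig,
    StudyDesign,
    sample_cohort_params,
    simulate_duplicates,
    simulate_sample,
    simulate_timecourse,
)
from .synth.config import _config_to_dict


def process_sample(
    events: EventTable,
    spillover: SpilloverMatrix | np.ndarray,
    gateset: GateSet,
    min_leukocytes: int = 30_000,
    min_beads: int = 3_000,
) -> SampleResult:
    """Full per-acquisition pipeline: compensate, gate beads, classify, quantify."""
    comp = compensate(events, spillover)
    bead_mask = identify_beads(comp, gateset)
    qc = qc_check(comp, bead_mask, min_leukocytes, min_beads)
    labels = classify_events(comp, gateset, bead_mask)
    return quantify_sample(comp, labels, qc)


def _study_pipeline(
    acquisitions: list[EventTable],
    config: GeneratorConfig,
    gateset: GateSet | None,
    qc_exclude: bool,
    min_leukocytes: int,
    min_beads: int,
) -> list[SampleResult]:
    gates = gateset or template_midpoint_gates(config)
    spill = SpilloverMatrix(config.spillover)
    results = [
        process_sample(ev, spill, gates, min_leukocytes, min_beads)
        for ev in acquisitions
    ]
    if qc_exclude:
        results = [r for r in results if r.qc.passed]
    return results


def run_wt_cohort(
    config: GeneratorConfig,
    n_animals: int,
    rng: np.random.Generator,
    gateset: GateSet | None = None,
    qc_exclude: bool = True,
    min_leukocytes: int = 30_000,
    min_beads: int = 3_000,
) -> list[SampleResult]:
    """Cross-sectional wild-type cohort at the configured volume.

    Acquisitions are processed one at a time so peak memory stays at a
    single listmode table regardless of cohort size.
    """
    gates = gateset or template_midpoint_gates(config)
    spill = SpilloverMatrix(config.spillover)
    animals = sample_cohort_params(config, n_animals, rng)
    results = []
    for animal in animals:
        events = simulate_sample(animal, config.volume_ul, config, rng)
        results.append(
            process_sample(events, spill, gates, min_leukocytes, min_beads)
        )
    if qc_exclude:
        results = [r for r in results if r.qc.passed]
    return results


def run_duplicate_study(
    config: GeneratorConfig,
    n_animals: int,
    rng: np.random.Generator,
    gateset: GateSet | None = None,
) -> list[tuple[SampleResult, SampleResult]]:
    """n animals measured twice each with independent technical noise."""
    gates = gateset or template_midpoint_gates(config)
    spill = SpilloverMatrix(config.spillover)
    animals = sample_cohort_params(config, n_animals, rng, id_prefix="dup")
    out = []
    for animal in animals:
        (a, b), = simulate_duplicates(animal, 1, config, rng)
        out.append((process_sample(a, spill, gates), process_sample(b, spill, gates)))
    return out


def run_volume_pair_study(
    config: GeneratorConfig,
    n_animals: int,
    rng: np.random.Generator,
    volumes: tuple[float, float] = (50.0, 20.0),
    gateset: GateSet | None = None,
) -> tuple[list[SampleResult], list[SampleResult]]:
    """Same animals acquired at two sample volumes (assay-standardized vs reduced)."""
    gates = gateset or template_midpoint_gates(config)
    spill = SpilloverMatrix(config.spillover)
    animals = sample_cohort_params(config, n_animals, rng, id_prefix="vol")
    first, second = [], []
    for animal in animals:
        ev_a = simulate_sample(animal, volumes[0], config, rng)
        ev_b = simulate_sample(animal, volumes[1], config, rng)
        first.append(process_sample(ev_a, spill, gates))
        second.append(process_sample(ev_b, spill, gates))
    return first, second


def run_timecourse_study(
    design: StudyDesign,
    config: GeneratorConfig,
    rng: np.random.Generator,
    gateset: GateSet | None = None,
    qc_exclude: bool = False,
) -> list[SampleResult]:
    """Longitudinal or cross-sectional study through the full pipeline.

    QC exclusion defaults off here: serial low-volume draws legitimately
    acquire fewer events than the terminal-bleed threshold.
    """
    acquisitions = simulate_timecourse(design, config, rng)
    return _study_pipeline(acquisitions, config, gateset, qc_exclude, 0, 1)


# --- file-based study replay --------------------------------------------------


def config_hash(config: GeneratorConfig) -> str:
    payload = yaml.safe_dump(_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyManifest:
    """Provenance for a generated study: seeds, config hash, acquisitions."""

    config_hash: str
    base_seed: int
    acquisitions: list[dict] = field(default_factory=list)
    software_version: str = __version__

    def validate(self) -> None:
        if not self.acquisitions:
            raise ValueError("empty manifest")
        for acq in self.acquisitions:
            if not os.path.exists(acq["path"]):
                raise FileNotFoundError(acq["path"])

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "StudyManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_study(
    acquisitions: list[EventTable],
    out_dir: str,
    config: GeneratorConfig,
    base_seed: int,
) -> StudyManifest:
    """Write FCS files + ground-truth sidecars + manifest for a simulated study."""
    os.makedirs(out_dir, exist_ok=True)
    spill = SpilloverMatrix(config.spillover)
    manifest = StudyManifest(config_hash=config_hash(config), base_seed=base_seed)
    for i, ev in enumerate(acquisitions):
        stem = "_".join(
            str(ev.meta.get(k, "x")) for k in ("animal_id", "day", "duplicate")
        )
        fcs_path = os.path.join(out_dir, f"{i:04d}_{stem}.fcs")
        write_fcs(ev, fcs_path, spillover_keyword=spill.to_fcs_keyword())
        if ev.labels is not None:
            truth_path = fcs_path.replace(".fcs", "_truth.csv")
            pd.DataFrame(
                {"event_index": np.arange(ev.n_events),
                 "label": np.asarray(SUBSET_LABELS)[ev.labels]}
            ).to_csv(truth_path, index=False)
        manifest.acquisitions.append(
            {
                "path": fcs_path,
                "animal_id": ev.meta.get("animal_id"),
                "group": ev.meta.get("group"),
                "day": ev.meta.get("day"),
                "volume_ul": ev.meta.get("volume_ul"),
                "duplicate": ev.meta.get("duplicate"),
            }
        )
    manifest.save(os.path.join(out_dir, "manifest.json"))
    return manifest


def run_pipeline(
    manifest: StudyManifest,
    config: GeneratorConfig,
    out_dir: str,
    qc_exclude: bool = True,
) -> pd.DataFrame:
    """Replay a manifest from disk: read FCS, process, write tidy outputs.

    Deterministic: identical manifest + config give byte-identical CSVs.
    QC-failed samples are logged and excluded unless ``qc_exclude=False``.
    """
    manifest.validate()
    os.makedirs(out_dir, exist_ok=True)
    gates = template_midpoint_gates(config)
    spill = SpilloverMatrix(config.spillover)
    results: list[SampleResult] = []
    log_lines = [f"cytovar {__version__} | config {config_hash(config)} "
                 f"| seed {manifest.base_seed} | {len(manifest.acquisitions)} acquisitions"]
    for acq in manifest.acquisitions:
        events = read_fcs(acq["path"])
        events.meta.setdefault("beads_per_tube", config.beads_per_tube)
        for key in ("animal_id", "group", "day", "volume_ul", "duplicate"):
            if acq.get(key) is not None:
                events.meta[key] = acq[key]
        result = process_sample(events, spill, gates)
        if not result.qc.passed:
            log_lines.append(
                f"QC FAIL {acq['path']}: {','.join(result.qc.reasons)} "
                f"({result.qc.n_leukocyte_events} leuko, {result.qc.n_bead_events} beads)"
            )
            if qc_exclude:
                continue
        results.append(result)
    frame = results_to_tidy_csv(results, os.path.join(out_dir, "sample_results.csv"))
    with open(os.path.join(out_dir, "pipeline.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return frame
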