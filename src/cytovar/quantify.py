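"""Bead-based absolute counts, subset composition, and MFIs per sample.

Absolute concentration follows the TruCount single-platform formula:
(cells acquired / beads acquired) x (beads per tube / sample volume).
Because cells and beads are thinned by the same acquisition fraction, the
fraction cancels and the estimator is unbiased for any partial
acquisition.  MFIs are medians of compensated, untransformed intensities
(the transform is display-only) and require a minimum number of events to
avoid unstable medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .events import EventTable
from .panel import LABEL_CODE, LEUKOCYTE_SUBSETS, MONO_SUBSETS, SUBSET_LABELS
from .preprocess import QCReport

MIN_MFI_EVENTS = 20


def absolute_count(
    n_subset_events: int,
    n_bead_events: int,
    beads_per_tube: float,
    volume_ul: float,
) -> float:
    """Cells/ul from the acquired cell/bead event ratio."""
    if n_bead_events <= 0:
        raise ValueError(
            "no bead events acquired (QC failure); absolute counts are undefined"
        )
    if volume_ul <= 0:
        raise ValueError("volume_ul must be positive")
    return (n_subset_events / n_bead_events) * (beads_per_tube / volume_ul)


def subset_fractions(mono_counts: dict[str, int]) -> dict[str, float]:
    """Each MHCII-neg monocyte subset as % of their sum."""
    total = sum(mono_counts[s] for s in MONO_SUBSETS)
    if total <= 0:
        raise ValueError("zero monocyte events; fractions undefined")
    return {s: 100.0 * mono_counts[s] / total for s in MONO_SUBSETS}


def median_fluorescence(
    events: EventTable,
    labels: np.ndarray,
    subset: str,
    channel: str,
    min_events: int = MIN_MFI_EVENTS,
) -> float | None:
    """Median compensated intensity of one subset on one channel.

    Returns ``None`` when the subset has fewer than ``min_events`` events.
    """
    mask = labels == LABEL_CODE[subset]
    n = int(mask.sum())
    if n < min_events:
        return None
    return float(np.median(events.column(channel)[mask]))


@dataclass
class SampleResult:
    """Pipeline output for one acquisition."""

    event_counts: dict[str, int]
    absolute_counts: dict[str, float]  # cells/ul, per leukocyte subset
    fractions: dict[str, float] | None  # % of MHCII-neg monocytes
    mfi: dict[tuple[str, str], float | None]
    qc: QCReport
    meta: dict[str, Any] = field(default_factory=dict)

    def to_row(self) -> dict[str, Any]:
        row: dict[str, Any] = {
            "animal_id": self.meta.get("animal_id"),
            "group": self.meta.get("group"),
            "day": self.meta.get("day"),
            "duplicate": self.meta.get("duplicate"),
            "volume_ul": self.meta.get("volume_ul"),
            "qc_pass": self.qc.passed,
        }
        for s in LEUKOCYTE_SUBSETS:
            row[f"count_{s}"] = self.absolute_counts[s]
        if self.fractions:
            for s, v in self.fractions.items():
                row[f"fraction_{s}"] = v
        return row


def quantify_sample(
    events: EventTable,
    labels: np.ndarray,
    qc: QCReport,
    mfi_channels: tuple[str, ...] = ("F480",),
    min_mfi_events: int = MIN_MFI_EVENTS,
) -> SampleResult:
    """Counts, concentrations, composition, and MFIs from classified events."""
    counts = {
        name: int(np.count_nonzero(labels == code)) for name, code in LABEL_CODE.items()
    }
    n_beads = counts["bead"]
    beads_per_tube = events.meta["beads_per_tube"]
    volume = events.meta["volume_ul"]
    absolute = {
        s: absolute_count(counts[s], n_beads, beads_per_tube, volume)
        for s in LEUKOCYTE_SUBSETS
    }
    try:
        fractions = subset_fractions(counts)
    except ValueError:
        fractions = None
    mfi: dict[tuple[str, str], float | None] = {}
    for subset in ("classical_mono", "intermediate_mono", "nonclassical_mono",
                   "activated_monomac"):
        for channel in mfi_channels:
            mfi[(subset, channel)] = median_fluorescence(
                events, labels, subset, channel, min_mfi_events
            )
    return SampleResult(
        event_counts=counts,
        absolute_counts=absolute,
        fractions=fractions,
        mfi=mfi,
        qc=qc,
        meta=dict(events.meta),
    )


def results_to_frame(results: list[SampleResult]) -> pd.DataFrame:
    """Tidy table: one row per sample, stable column names."""
    return pd.DataFrame([r.to_row() for r in results])


def results_to_tidy_csv(results: list[SampleResult], path: str) -> pd.DataFrame:
    """One row per sample x subset (long format); also written to ``path``."""
    rows = []
    for r in results:
        for s in LEUKOCYTE_SUBSETS:
            rows.append(
                {
                    "animal_id": r.meta.get("animal_id"),
                    "group": r.meta.get("group"),
                    "day": r.meta.get("day"),
                    "duplicate": r.meta.get("duplicate"),
                    "volume_ul": r.meta.get("volume_ul"),
                    "subset": s,
                    "event_count": r.event_counts[s],
                    "cells_per_ul": r.absolute_counts[s],
                    "fraction_pct": (r.fractions or {}).get(s),
                    "mfi_f480": r.mfi.get((s, "F480")),
                    "qc_pass": r.qc.passed,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def volume_equivalence(
    results_50ul: list[SampleResult],
    results_20ul: list[SampleResult],
) -> pd.DataFrame:
    """Paired-volume agreement: per-subset rank correlation and mean count ratio.

    Inputs must be the same animals in the same order at both volumes.
    With fewer than 3 pairs the correlation is undefined and reported NaN
    with a flag.
    """
    ids_a = [r.meta.get("animal_id") for r in results_50ul]
    ids_b = [r.meta.get("animal_id") for r in results_20ul]
    if ids_a != ids_b:
        raise ValueError("volume_equivalence needs the same animals, paired in order")
    rows = []
    for s in LEUKOCYTE_SUBSETS:
        a = np.array([r.absolute_counts[s] for r in results_50ul])
        b = np.array([r.absolute_counts[s] for r in results_20ul])
        if len(a) < 3 or np.all(a == a[0]) or np.all(b == b[0]):
            rho = np.nan
            defined = len(a) >= 3
        else:
            rho = float(spearmanr(a, b).statistic)
            defined = True
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = float(np.mean(np.where(a > 0, b / np.where(a > 0, a, 1.0), np.nan)))
        rows.append(
            {"subset": s, "spearman_rho": rho, "mean_ratio_20_over_50": ratio,
             "n_pairs": len(a), "correlation_defined": defined}
        )
    return pd.DataFrame(rows)


def label_name(code: int) -> str:
    return SUBSET_LABELS[code]
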