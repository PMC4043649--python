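"""Listmode event container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .panel import CHANNELS, CHANNEL_INDEX


@dataclass
class EventTable:
    """One acquisition: n_events x n_channels raw (or compensated) intensities.

    ``data`` is float64, one row per event, columns in :data:`cytovar.panel.CHANNELS`
    order.  ``labels`` carries generator ground truth (label codes into
    :data:`cytovar.panel.SUBSET_LABELS`) when the table is synthetic; it is
    ``None`` for real acquisitions.  ``meta`` holds acquisition metadata
    (volume_ul, animal_id, day, group, duplicate, beads_per_tube, ...).
    """

    data: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    meta: dict[str, Any] = field(default_factory=dict)
    labels: np.ndarray | None = None
    compensated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data must be (n_events, {len(self.channels)}); got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("event intensities must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.data.shape[0]:
                raise ValueError("labels length must match event count")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def column(self, channel: str) -> np.ndarray:
        return self.data[:, CHANNEL_INDEX[channel]]

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Row-subset sharing metadata (copies the selected rows)."""
        return EventTable(
            data=self.data[mask],
            channels=self.channels,
            meta=dict(self.meta),
            labels=None if self.labels is None else self.labels[mask],
            compensated=self.compensated,
        )
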