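"""Spillover estimation, compensation, bi-exponential transform, and QC.

Spillover is estimated from single-stain controls by the standard
median-difference ratio; compensation is the exact linear inverse of the
mixing (negative compensated values are retained — truncation would bias
MFIs).  The display/gating transform is a scaled inverse hyperbolic sine,
the biexponential-family transform used throughout cytometry: linear-like
around zero (so compensated negatives stay on scale) and ~log10 at high
intensity.  Scatter channels are never compensated or spillover-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventTable
from .panel import CHANNEL_INDEX, FLUOR_CHANNELS, FLUOR_INDEX

DEFAULT_COFACTOR = 150.0


@dataclass
class SpilloverMatrix:
    """K x K spillover: entry (i, j) = fraction of channel-i signal in detector j."""

    matrix: np.ndarray
    channels: tuple[str, ...] = FLUOR_CHANNELS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.channels)
        if self.matrix.shape != (k, k):
            raise ValueError(f"spillover must be {k}x{k}")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover diagonal must be exactly 1")
        if np.any(self.matrix < 0):
            raise ValueError("spillover entries must be non-negative")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("spillover matrix is singular")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_csv(self, path: str) -> None:
        header = ",".join(self.channels)
        np.savetxt(path, self.matrix, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str) -> "SpilloverMatrix":
        with open(path) as fh:
            channels = tuple(fh.readline().strip().split(","))
        matrix = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(matrix, channels)

    def to_fcs_keyword(self) -> str:
        """$SPILLOVER keyword string: K, names..., row-major values."""
        parts = [str(len(self.channels)), *self.channels]
        parts += [repr(float(v)) for v in self.matrix.ravel()]
        return ",".join(parts)

    @classmethod
    def from_fcs_keyword(cls, keyword: str) -> "SpilloverMatrix":
        parts = keyword.split(",")
        k = int(parts[0])
        channels = tuple(parts[1 : 1 + k])
        values = np.array([float(v) for v in parts[1 + k :]]).reshape(k, k)
        return cls(values, channels)


def _split_control(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Separate positive/negative events on the primary channel.

    Works on the asinh scale: the threshold is the midpoint between the 10th
    and 90th percentiles, then each event is assigned by side.  A bimodality
    check requires both sides populated and well separated.
    """
    t = np.arcsinh(values / DEFAULT_COFACTOR)
    lo, hi = np.percentile(t, [10, 90])
    if hi - lo < 0.5:
        raise ValueError("control populations not separable on the primary channel")
    cut = 0.5 * (lo + hi)
    pos = t >= cut
    if pos.sum() < 10 or (~pos).sum() < 10:
        raise ValueError("control positive/negative split failed")
    return pos, ~pos


def estimate_spillover(controls: list[EventTable]) -> SpilloverMatrix:
    """Median-ratio spillover from one single-stain control per channel.

    For control i, entry (i, j) is
    (median_j(positive) - median_j(negative)) / (median_i(positive) -
    median_i(negative)); the diagonal is forced to 1.  Rows are keyed by the
    control's primary channel, so input order does not matter.
    """
    k = len(FLUOR_CHANNELS)
    if len(controls) != k:
        raise ValueError(f"need {k} controls, one per fluorescence channel")
    matrix = np.eye(k)
    seen: set[str] = set()
    for control in controls:
        primary = control.meta.get("control_channel")
        if primary is None:
            primary = _brightest_channel(control)
        if primary not in FLUOR_CHANNELS:
            raise ValueError(f"control has unknown primary channel {primary!r}")
        seen.add(primary)
        i = FLUOR_CHANNELS.index(primary)
        pos, neg = _split_control(control.column(primary))
        denom = np.median(control.column(primary)[pos]) - np.median(
            control.column(primary)[neg]
        )
        for j, ch in enumerate(FLUOR_CHANNELS):
            if j == i:
                continue
            num = np.median(control.column(ch)[pos]) - np.median(control.column(ch)[neg])
            matrix[i, j] = max(num / denom, 0.0)
    if len(seen) != k:
        raise ValueError("controls do not cover every fluorescence channel")
    return SpilloverMatrix(matrix)


def _brightest_channel(control: EventTable) -> str:
    meds = [np.median(control.column(ch)) for ch in FLUOR_CHANNELS]
    return FLUOR_CHANNELS[int(np.argmax(meds))]


def compensate(events: EventTable, spillover: SpilloverMatrix | np.ndarray) -> EventTable:
    """Invert the spillover mixing on the fluorescence channels.

    observed = true . S, so the compensated table is observed . S^-1.
    Negative compensated values are kept.  Scatter channels pass through
    bit-identical.
    """
    if isinstance(spillover, np.ndarray):
        spillover = SpilloverMatrix(spillover)
    data = events.data.copy()
    fl = list(FLUOR_INDEX)
    data[:, fl] = data[:, fl] @ spillover.inverse
    return EventTable(
        data=data,
        channels=events.channels,
        meta=dict(events.meta),
        labels=None if events.labels is None else events.labels.copy(),
        compensated=True,
    )


def biexp_transform(values: np.ndarray | float, cofactor: float = DEFAULT_COFACTOR):
    """f(x) = asinh(x / cofactor) / ln(10): ~log10(2x/cofactor) for large x."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor) / np.log(10.0)


def biexp_inverse(values: np.ndarray | float, cofactor: float = DEFAULT_COFACTOR):
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.sinh(np.asarray(values, dtype=float) * np.log(10.0)) * cofactor


@dataclass
class QCReport:
    n_leukocyte_events: int
    n_bead_events: int
    min_leukocytes: int
    min_beads: int
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def qc_check(
    events: EventTable,
    bead_mask: np.ndarray,
    min_leukocytes: int = 30_000,
    min_beads: int = 3_000,
) -> QCReport:
    """Acquisition QC: at least 30,000 leukocyte and 3,000 bead events (inclusive)."""
    n_beads = int(np.count_nonzero(bead_mask))
    n_leuko = int(events.n_events - n_beads)
    reasons = []
    if n_leuko < min_leukocytes:
        reasons.append("leukocytes")
    if n_beads < min_beads:
        reasons.append("beads")
    return QCReport(n_leuko, n_beads, min_leukocytes, min_beads, reasons)
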