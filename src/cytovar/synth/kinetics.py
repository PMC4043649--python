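"""Post-operative kinetics anchors for the longitudinal study designs.

Each subset and group carries a median multiplier m(t) (1 = baseline) at a
fixed set of anchor days, interpolated log-linearly in between, and a
dispersion scale s(t) applied to the animal-level log random effect in
sequential (repeated-measures) designs.  The published account of the
kinetics is qualitative — an early (day 1) dip most pronounced for
non-classical monocytes and eosinophils, followed by classical and
non-classical monocytosis, with MI and sham time courses indistinguishable
and non-operated controls flat — so the default anchor magnitudes are
package configuration values, not published numbers; only their shape is
asserted by tests.  The single printed dispersion fact (an up-to-four-fold
reduction of the classical-monocyte CV at day 7 under sequential analysis)
pins s(7) ~ 0.27.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..panel import LEUKOCYTE_SUBSETS

ANCHOR_DAYS: tuple[float, ...] = (0.0, 1.0, 3.0, 5.0, 7.0, 14.0, 21.0)

GROUPS: tuple[str, ...] = ("MI", "SHAM", "CTRL")

_DEFAULT_MULTIPLIER = {
    "classical_mono": (1.0, 0.7, 2.5, 2.0, 1.6, 1.1, 1.0),
    "nonclassical_mono": (1.0, 0.4, 1.2, 1.8, 2.0, 1.3, 1.0),
    "intermediate_mono": (1.0, 0.6, 1.8, 1.6, 1.3, 1.1, 1.0),
    "neutrophil": (1.0, 1.8, 1.4, 1.1, 1.0, 1.0, 1.0),
    "eosinophil": (1.0, 0.4, 0.7, 0.9, 1.0, 1.0, 1.0),
    "activated_monomac": (1.0, 0.7, 1.4, 1.5, 1.3, 1.1, 1.0),
    "lymphocyte": (1.0, 0.8, 0.9, 1.0, 1.0, 1.0, 1.0),
}
_DEFAULT_DISPERSION = (1.0, 0.6, 0.4, 0.32, 0.27, 0.5, 0.7)


@dataclass
class KineticsAnchors:
    days: tuple[float, ...] = ANCHOR_DAYS
    multiplier: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)
    dispersion: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nd = len(self.days)
        if list(self.days) != sorted(self.days) or self.days[0] != 0.0:
            raise ValueError("anchor days must start at 0 and be sorted")
        for table, name in ((self.multiplier, "multiplier"), (self.dispersion, "dispersion")):
            for group, per_subset in table.items():
                for subset, values in per_subset.items():
                    values = tuple(float(v) for v in values)
                    per_subset[subset] = values
                    if len(values) != nd:
                        raise ValueError(f"{name}[{group}][{subset}]: wrong anchor count")
                    if any(v <= 0 for v in values):
                        raise ValueError(f"{name}[{group}][{subset}]: values must be > 0")
                    if abs(values[0] - 1.0) > 1e-12:
                        raise ValueError(f"{name}[{group}][{subset}]: baseline anchor must be 1")

    def _lookup(self, table: dict, group: str, subset: str) -> np.ndarray | None:
        if group not in table:
            raise KeyError(f"unknown group {group!r}")
        return table[group].get(subset)

    def multiplier_at(self, group: str, subset: str, day: float) -> float:
        """Median concentration multiplier, log-linear between anchors."""
        self._check_day(day)
        values = self._lookup(self.multiplier, group, subset)
        if values is None:
            return 1.0
        return float(np.exp(np.interp(day, self.days, np.log(values))))

    def dispersion_at(self, group: str, subset: str, day: float) -> float:
        """Animal-effect dispersion scale for sequential designs."""
        self._check_day(day)
        values = self._lookup(self.dispersion, group, subset)
        if values is None:
            return 1.0
        return float(np.interp(day, self.days, values))

    def _check_day(self, day: float) -> None:
        if not self.days[0] <= day <= self.days[-1]:
            raise ValueError(f"day {day} outside anchor range [{self.days[0]}, {self.days[-1]}]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "days": list(self.days),
            "multiplier": {g: {s: list(v) for s, v in d.items()} for g, d in self.multiplier.items()},
            "dispersion": {g: {s: list(v) for s, v in d.items()} for g, d in self.dispersion.items()},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KineticsAnchors":
        return cls(
            days=tuple(d["days"]),
            multiplier={g: {s: tuple(v) for s, v in per.items()} for g, per in d["multiplier"].items()},
            dispersion={g: {s: tuple(v) for s, v in per.items()} for g, per in d["dispersion"].items()},
        )


def default_anchors() -> KineticsAnchors:
    """MI and sham share identical anchors; non-operated controls stay flat."""
    flat = tuple(1.0 for _ in ANCHOR_DAYS)
    multiplier = {
        "MI": {s: _DEFAULT_MULTIPLIER[s] for s in LEUKOCYTE_SUBSETS},
        "SHAM": {s: _DEFAULT_MULTIPLIER[s] for s in LEUKOCYTE_SUBSETS},
        "CTRL": {s: flat for s in LEUKOCYTE_SUBSETS},
    }
    dispersion = {
        "MI": {s: _DEFAULT_DISPERSION for s in LEUKOCYTE_SUBSETS},
        "SHAM": {s: _DEFAULT_DISPERSION for s in LEUKOCYTE_SUBSETS},
        "CTRL": {s: flat for s in LEUKOCYTE_SUBSETS},
    }
    return KineticsAnchors(multiplier=multiplier, dispersion=dispersion)
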