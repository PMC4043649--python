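"""Sequential gating hierarchy for the murine myeloid panel.

The hierarchy mirrors manual sequential gating practice: beads out first,
then the SSC-high (granulocyte) branch split by Lin(Ly6G)/F4-80, then the
SSC-low mononuclear branch where Lin-neg CD11b-pos MHCII-neg cells are
monocytes split on the Ly6C x CD43 plane, Lin-neg CD11b-pos MHCII-pos cells
with the non-classical-like Ly6C-low/int CD43-int/high phenotype are
activated monocytes/macrophages, and Lin-pos CD11b-neg cells are
lymphocytes.  All gates are axis-aligned thresholds on the bi-exponential
scale, combined with Boolean AND; every threshold uses the half-open
[cut, inf) convention, so an event exactly on a cut goes to the upper side.

The three MHCII-negative monocyte subsets partition the monocyte gate
exactly: Ly6C is the primary axis (high -> classical, low -> non-classical)
and the Ly6C-intermediate band is split by CD43 bin (int -> intermediate,
low -> classical, high -> non-classical), which agrees with the canonical
definitions (classical Ly6C-high CD43-low, non-classical Ly6C-low
CD43-high, intermediate both intermediate) on their home bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .events import EventTable
from .panel import LABEL_CODE, SUBSET_LABELS
from .preprocess import DEFAULT_COFACTOR, biexp_transform


@dataclass
class GateSet:
    """Thresholds on the transformed (asinh/ln10) scale realizing the hierarchy."""

    ssc_high_cut: float
    lin_pos_cut: float
    cd11b_pos_cut: float
    f480_pos_cut: float
    mhc2_pos_cut: float
    ly6c_lo_cut: float
    ly6c_hi_cut: float
    cd43_lo_cut: float
    cd43_hi_cut: float
    bead_cd11b_cut: float
    bead_ssc_lo: float
    bead_ssc_hi: float
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self) -> None:
        if not self.ly6c_lo_cut < self.ly6c_hi_cut:
            raise ValueError("Ly6C interval cuts must satisfy lo < hi")
        if not self.cd43_lo_cut < self.cd43_hi_cut:
            raise ValueError("CD43 interval cuts must satisfy lo < hi")
        if not self.bead_ssc_lo < self.bead_ssc_hi:
            raise ValueError("bead scatter band must satisfy lo < hi")
        for name, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"gate {name} must be finite")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_yaml(cls, path: str) -> "GateSet":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def from_json(cls, path: str) -> "GateSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def template_midpoint_gates(config) -> GateSet:
    """Deterministic gates at geometric midpoints of the template medians.

    This is the reference gate placement used by the analysis scripts: each
    cut sits halfway (on the log scale) between the two template medians it
    separates, then is mapped onto the transformed scale.
    """
    med = {p: t.medians for p, t in config.templates.items()}
    co = DEFAULT_COFACTOR

    def geo_mid(a: float, b: float) -> float:
        return float(np.sqrt(a * b))

    t = lambda x: float(biexp_transform(x, co))  # noqa: E731
    return GateSet(
        ssc_high_cut=t(geo_mid(med["activated_monomac"]["SSC"], med["eosinophil"]["SSC"])),
        lin_pos_cut=t(geo_mid(med["classical_mono"]["Lin"], med["lymphocyte"]["Lin"])),
        cd11b_pos_cut=t(geo_mid(med["lymphocyte"]["CD11b"], med["neutrophil"]["CD11b"])),
        f480_pos_cut=t(geo_mid(med["neutrophil"]["F480"], med["eosinophil"]["F480"])),
        mhc2_pos_cut=t(geo_mid(med["classical_mono"]["MHCII"], med["lymphocyte"]["MHCII"])),
        ly6c_lo_cut=t(geo_mid(med["nonclassical_mono"]["Ly6C"], med["intermediate_mono"]["Ly6C"])),
        ly6c_hi_cut=t(geo_mid(med["intermediate_mono"]["Ly6C"], med["classical_mono"]["Ly6C"])),
        cd43_lo_cut=t(geo_mid(med["classical_mono"]["CD43"], med["intermediate_mono"]["CD43"])),
        cd43_hi_cut=t(geo_mid(med["intermediate_mono"]["CD43"], med["nonclassical_mono"]["CD43"])),
        bead_cd11b_cut=t(geo_mid(med["classical_mono"]["CD11b"], med["bead"]["CD11b"])),
        bead_ssc_lo=t(med["bead"]["SSC"] / 2.5),
        bead_ssc_hi=t(med["bead"]["SSC"] * 2.5),
        cofactor=co,
    )


def kde_valley_cut(
    values: np.ndarray,
    fallback: float | None = None,
    bandwidth: float | str = "scott",
    grid_size: int = 512,
) -> float:
    """Minimum-density valley between the two tallest modes of a KDE.

    Deterministic given bandwidth and grid.  Falls back to ``fallback`` when
    the density is unimodal; raises if unimodal and no fallback is given.
    """
    values = np.asarray(values, dtype=float)
    kde = gaussian_kde(values, bw_method=bandwidth)
    grid = np.linspace(values.min(), values.max(), grid_size)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        if fallback is None:
            raise ValueError("density is unimodal and no fallback cut was supplied")
        return float(fallback)
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = np.sort(top_two)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def derive_gates(
    events: EventTable | None,
    config,
    data_driven: bool = False,
    min_events: int = 1000,
) -> GateSet:
    """Either return the config's template-midpoint gates verbatim, or place
    each 1-D cut at the KDE valley of a representative compensated sample.

    Data-driven placement refines the Ly6C and CD43 interval cuts and the
    major branch cuts from the sample itself, keeping the template midpoints
    as unimodal fallbacks.
    """
    base = template_midpoint_gates(config)
    if not data_driven:
        return base
    if events is None or events.n_events < min_events:
        raise ValueError(f"data-driven gating needs >= {min_events} events")
    t = biexp_transform(events.data, base.cofactor)
    col = {ch: t[:, i] for i, ch in enumerate(events.channels)}
    ssc = kde_valley_cut(col["SSC"], fallback=base.ssc_high_cut)
    low = col["SSC"] < ssc
    return GateSet(
        ssc_high_cut=ssc,
        lin_pos_cut=kde_valley_cut(col["Lin"][low], fallback=base.lin_pos_cut),
        cd11b_pos_cut=kde_valley_cut(col["CD11b"][low], fallback=base.cd11b_pos_cut),
        f480_pos_cut=base.f480_pos_cut,
        mhc2_pos_cut=base.mhc2_pos_cut,
        ly6c_lo_cut=base.ly6c_lo_cut,
        ly6c_hi_cut=base.ly6c_hi_cut,
        cd43_lo_cut=base.cd43_lo_cut,
        cd43_hi_cut=base.cd43_hi_cut,
        bead_cd11b_cut=base.bead_cd11b_cut,
        bead_ssc_lo=base.bead_ssc_lo,
        bead_ssc_hi=base.bead_ssc_hi,
        cofactor=base.cofactor,
    )


def boolean_combine(
    gates: Sequence[Callable[[EventTable], np.ndarray]],
) -> Callable[[EventTable], np.ndarray]:
    """Logical AND of event-wise gate predicates (the 'Boolean gate')."""
    if len(gates) == 0:
        raise ValueError("boolean_combine needs at least one predicate")
    gates = list(gates)

    def combined(events: EventTable) -> np.ndarray:
        mask = gates[0](events)
        for g in gates[1:]:
            mask = mask & g(events)
        return mask

    return combined


def interval_gate(
    channel: str, lo: float = -np.inf, hi: float = np.inf, cofactor: float = DEFAULT_COFACTOR
) -> Callable[[EventTable], np.ndarray]:
    """Half-open interval predicate [lo, hi) on a transformed channel."""

    def predicate(events: EventTable) -> np.ndarray:
        t = biexp_transform(events.column(channel), cofactor)
        return (t >= lo) & (t < hi)

    return predicate


def identify_beads(events: EventTable, gateset: GateSet) -> np.ndarray:
    """TruCount bead mask: above the bead brightness cut on the
    bead-visualization (AF700/CD11b) detector, inside the bead scatter band."""
    cd11b = biexp_transform(events.column("CD11b"), gateset.cofactor)
    ssc = biexp_transform(events.column("SSC"), gateset.cofactor)
    return (
        (cd11b >= gateset.bead_cd11b_cut)
        & (ssc >= gateset.bead_ssc_lo)
        & (ssc < gateset.bead_ssc_hi)
    )


def classify_events(
    events: EventTable,
    gateset: GateSet,
    bead_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Assign every event exactly one subset label code.

    Order of application: (1) beads out; (2) SSC-high branch: CD11b-pos
    Lin-pos F4/80-neg -> neutrophil, CD11b-pos Lin-neg F4/80-pos ->
    eosinophil; (3) SSC-low Lin-neg CD11b-pos MHCII-neg -> monocytes split
    on Ly6C x CD43; (4) same gate but MHCII-pos with Ly6C low/int and CD43
    int/high -> activated; (5) SSC-low Lin-pos CD11b-neg -> lymphocyte;
    (6) everything else -> ungated.  Returns int8 codes into
    :data:`cytovar.panel.SUBSET_LABELS`.
    """
    g = gateset
    t = biexp_transform(events.data, g.cofactor)
    col = {ch: t[:, i] for i, ch in enumerate(events.channels)}

    if bead_mask is None:
        bead_mask = identify_beads(events, g)

    labels = np.full(events.n_events, LABEL_CODE["ungated"], dtype=np.int8)
    labels[bead_mask] = LABEL_CODE["bead"]
    cell = ~bead_mask

    ssc_high = col["SSC"] >= g.ssc_high_cut
    lin_pos = col["Lin"] >= g.lin_pos_cut
    cd11b_pos = col["CD11b"] >= g.cd11b_pos_cut
    f480_pos = col["F480"] >= g.f480_pos_cut
    mhc2_pos = col["MHCII"] >= g.mhc2_pos_cut

    labels[cell & ssc_high & cd11b_pos & lin_pos & ~f480_pos] = LABEL_CODE["neutrophil"]
    labels[cell & ssc_high & cd11b_pos & ~lin_pos & f480_pos] = LABEL_CODE["eosinophil"]

    mononuclear = cell & ~ssc_high
    mono_gate = mononuclear & ~lin_pos & cd11b_pos & ~mhc2_pos

    ly6c_hi = col["Ly6C"] >= g.ly6c_hi_cut
    ly6c_lo = col["Ly6C"] < g.ly6c_lo_cut
    ly6c_int = ~ly6c_hi & ~ly6c_lo
    cd43_hi = col["CD43"] >= g.cd43_hi_cut
    cd43_lo = col["CD43"] < g.cd43_lo_cut
    # the combined interval ("Boolean") gate for the continuous intermediate population
    intermediate = boolean_combine([
        interval_gate("Ly6C", g.ly6c_lo_cut, g.ly6c_hi_cut, g.cofactor),
        interval_gate("CD43", g.cd43_lo_cut, g.cd43_hi_cut, g.cofactor),
    ])(events)

    labels[mono_gate & (ly6c_hi | (ly6c_int & cd43_lo))] = LABEL_CODE["classical_mono"]
    labels[mono_gate & intermediate] = LABEL_CODE["intermediate_mono"]
    labels[mono_gate & (ly6c_lo | (ly6c_int & cd43_hi))] = LABEL_CODE["nonclassical_mono"]

    activated = mononuclear & ~lin_pos & cd11b_pos & mhc2_pos & ~ly6c_hi & ~cd43_lo
    labels[activated] = LABEL_CODE["activated_monomac"]

    labels[mononuclear & lin_pos & ~cd11b_pos] = LABEL_CODE["lymphocyte"]
    return labels


def label_counts(labels: np.ndarray) -> dict[str, int]:
    """Event count per subset label; keys cover every label, values sum to n."""
    counts = np.bincount(labels, minlength=len(SUBSET_LABELS))
    return {name: int(counts[code]) for name, code in LABEL_CODE.items()}


def export_labels_csv(path: str, labels: np.ndarray, source: str = "") -> None:
    """Per-event label export: event index, label name, source acquisition."""
    names = np.asarray(SUBSET_LABELS)[labels]
    with open(path, "w") as fh:
        fh.write("event_index,label,source\n")
        for i, name in enumerate(names):
            fh.write(f"{i},{name},{source}\n")
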