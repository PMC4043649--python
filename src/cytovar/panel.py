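"""Antibody panel, detector layout, and cell-subset vocabulary.

The assay is a single-tube, lyse-no-wash murine whole-blood panel acquired
on a 3-laser instrument: two scatter parameters (FSC, SSC) plus six
fluorescence detectors.  The PE detector is a lineage "dump" channel
carrying Ly6G, CD90.2, B220, CD49b and NK1.1 simultaneously, so in the
granulocyte (SSC-high) branch "Lin-positive" operationally encodes Ly6G
positivity while in the mononuclear branch it encodes lymphoid lineage.
"""

from __future__ import annotations

# Channel order is fixed for every EventTable produced or read by this package.
CHANNELS: tuple[str, ...] = (
    "FSC",
    "SSC",
    "CD43",    # FITC
    "Lin",     # PE dump: Ly6G / CD90.2 / B220 / CD49b / NK1.1
    "MHCII",   # PE-Cy7 (I-A/I-E)
    "F480",    # APC
    "CD11b",   # AlexaFluor700 (also the bead-visualization detector)
    "Ly6C",    # Pacific Blue
)

SCATTER_CHANNELS: tuple[str, ...] = ("FSC", "SSC")
FLUOR_CHANNELS: tuple[str, ...] = CHANNELS[2:]

#: marker -> fluorochrome, as declared in FCS TEXT keywords ($PnS)
FLUOROCHROMES: dict[str, str] = {
    "CD43": "FITC",
    "Lin": "PE",
    "MHCII": "PE-Cy7",
    "F480": "APC",
    "CD11b": "AF700",
    "Ly6C": "PacificBlue",
}

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}
FLUOR_INDEX: tuple[int, ...] = tuple(CHANNEL_INDEX[c] for c in FLUOR_CHANNELS)

#: instrument dynamic range (18-bit ADC), arbitrary units
INSTRUMENT_RANGE: float = 262_144.0

# Subset labels. Order is the label-code order used in ground-truth and
# classification arrays; it never changes between releases.
POPULATIONS: tuple[str, ...] = (
    "neutrophil",
    "eosinophil",
    "classical_mono",
    "intermediate_mono",
    "nonclassical_mono",
    "activated_monomac",
    "lymphocyte",
    "bead",
)

#: labels assignable by the classifier (POPULATIONS plus the explicit rest class)
SUBSET_LABELS: tuple[str, ...] = POPULATIONS + ("ungated",)

LABEL_CODE: dict[str, int] = {name: i for i, name in enumerate(SUBSET_LABELS)}

MONO_SUBSETS: tuple[str, ...] = (
    "classical_mono",
    "intermediate_mono",
    "nonclassical_mono",
)

#: every subset reported as a leukocyte count (beads and ungated excluded)
LEUKOCYTE_SUBSETS: tuple[str, ...] = (
    "neutrophil",
    "eosinophil",
    "classical_mono",
    "intermediate_mono",
    "nonclassical_mono",
    "activated_monomac",
    "lymphocyte",
)
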