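"""Minimal FCS 3.0/3.1 listmode reader and FCS 3.1 writer.

Covers what this pipeline needs: list-mode ($MODE L) files with float
($DATATYPE F, written here) or unsigned integer ($DATATYPE I) data, little-
or big-endian $BYTEORD, channel names in $PnN, and the $SPILLOVER keyword.
Data are written as float32 so compensated negatives survive (integer
truncation would clip them).  Acquisition metadata travels in custom
CYTOVAR_* TEXT keywords plus the standard $VOL (nanoliters).
"""

from __future__ import annotations

import struct

import numpy as np

from .events import EventTable
from .panel import CHANNELS, FLUOROCHROMES

_DELIM = "/"
_HEADER_SIZE = 256  # TEXT starts here; generous padding after the 58-byte header

_META_KEYS = {
    "animal_id": "CYTOVAR_ANIMAL",
    "group": "CYTOVAR_GROUP",
    "day": "CYTOVAR_DAY",
    "duplicate": "CYTOVAR_DUPLICATE",
    "beads_per_tube": "CYTOVAR_BEADSPERTUBE",
    "acquisition_fraction": "CYTOVAR_ACQFRACTION",
}


def _encode_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        value = str(value)
        if value == "":
            value = " "
        if _DELIM in key or _DELIM in value:
            raise ValueError("delimiter character inside keyword or value")
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("utf-8")


def write_fcs(events: EventTable, path: str, spillover_keyword: str | None = None) -> None:
    """Write one acquisition as FCS 3.1, float32 little-endian data."""
    data = np.asarray(events.data, dtype="<f4")
    n_events, n_par = data.shape
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 9,  # placeholder, same width as the final offset
        "$ENDDATA": "0" * 9,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(events.channels, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}S"] = FLUOROCHROMES.get(name, name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(float(data[:, i - 1].max(initial=0.0)), 1.0)) + 1)
    if "volume_ul" in events.meta:
        keywords["$VOL"] = str(float(events.meta["volume_ul"]) * 1000.0)
    for meta_key, kw in _META_KEYS.items():
        if events.meta.get(meta_key) is not None:
            keywords[kw] = str(events.meta[meta_key])
    keywords["CYTOVAR_COMPENSATED"] = "1" if events.compensated else "0"
    if spillover_keyword is not None:
        keywords["$SPILLOVER"] = spillover_keyword

    # two-pass offsets: placeholder width is fixed, so text length is stable
    text = _encode_text(keywords)
    data_begin = _HEADER_SIZE + len(text)
    data_end = data_begin + data.nbytes - 1
    keywords["$BEGINDATA"] = "%09d" % data_begin
    keywords["$ENDDATA"] = "%09d" % data_end
    text = _encode_text(keywords)

    text_begin = _HEADER_SIZE
    text_end = _HEADER_SIZE + len(text) - 1
    header = b"FCS3.1    " + (
        f"{text_begin:>8d}{text_end:>8d}"
        + f"{data_begin if data_begin <= 99_999_999 else 0:>8d}"
        + f"{data_end if data_end <= 99_999_999 else 0:>8d}"
        + f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    with open(path, "wb") as fh:
        fh.write(header.ljust(_HEADER_SIZE, b" "))
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    delim = text[0]
    parts = text[1:].split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        raise ValueError("corrupt TEXT segment: odd number of delimited tokens")
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str) -> EventTable:
    """Read an FCS file and map its channels onto the declared panel.

    Channels are matched to panel markers by $PnN (case-insensitive);
    unknown channels are preserved in ``meta['extra_channels']`` but unused.
    A missing panel marker raises a panel error naming it.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if not blob[:6].startswith(b"FCS3"):
        raise ValueError(f"{path}: not an FCS 3.x file")
    try:
        text_begin = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise ValueError(f"{path}: corrupt header offsets") from exc
    if not (0 < text_begin <= text_end < len(blob)):
        raise ValueError(f"{path}: corrupt header offsets")
    keywords = _parse_text(blob[text_begin : text_end + 1])

    data_begin = int(keywords.get("$BEGINDATA") or blob[26:34])
    data_end = int(keywords.get("$ENDDATA") or blob[34:42])
    if not (0 < data_begin <= data_end < len(blob)):
        raise ValueError(f"{path}: corrupt data segment offsets")
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F").upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    raw = blob[data_begin : data_end + 1]
    if datatype == "F":
        values = np.frombuffer(raw, dtype=f"{endian}f4", count=n_par * n_tot)
    elif datatype == "D":
        values = np.frombuffer(raw, dtype=f"{endian}f8", count=n_par * n_tot)
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise ValueError(f"{path}: only uniform 16/32-bit integer data supported")
        width = int(keywords["$P1B"]) // 8
        values = np.frombuffer(raw, dtype=f"{endian}u{width}", count=n_par * n_tot)
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype}")
    table = values.reshape(n_tot, n_par).astype(float)

    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    upper = {n.upper(): i for i, n in enumerate(names)}
    missing = [ch for ch in CHANNELS if ch.upper() not in upper]
    if missing:
        raise ValueError(f"{path}: panel markers missing from file: {missing}")
    data = np.column_stack([table[:, upper[ch.upper()]] for ch in CHANNELS])
    extra = {
        n: table[:, i] for i, n in enumerate(names) if n.upper() not in
        {c.upper() for c in CHANNELS}
    }

    meta: dict = {"path": path, "keywords": keywords}
    if extra:
        meta["extra_channels"] = extra
    if "$VOL" in keywords:
        meta["volume_ul"] = float(keywords["$VOL"]) / 1000.0
    for meta_key, kw in _META_KEYS.items():
        if kw in keywords:
            value = keywords[kw]
            if meta_key in ("day", "beads_per_tube", "acquisition_fraction"):
                meta[meta_key] = float(value)
            elif meta_key == "duplicate":
                meta[meta_key] = int(value)
            else:
                meta[meta_key] = value
    return EventTable(
        data=data,
        meta=meta,
        compensated=keywords.get("CYTOVAR_COMPENSATED", "0") == "1",
    )
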