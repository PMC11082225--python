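"""Minimal FCS 3.1 list-mode codec and CSV mirror I/O.

Writes data type ``F`` (IEEE float32, little-endian) list-mode files with a
single dataset, and reads them back.  The TEXT segment carries the standard
required keywords including ``$PnN`` channel names.  Only the subset of the
standard needed for round-tripping simulator output is implemented: one
dataset, float data, no analysis segment.

The CSV mirror is a plain-text alternative carrying the same matrix plus,
for synthetic tubes, the ground-truth ``population`` and ``released``
columns that cannot be expressed in FCS.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .events import EventTable

__all__ = ["write_fcs", "read_fcs", "write_events_csv", "read_events_csv", "FCSParseError"]

_DELIM = "/"
_HEADER_LEN = 58


class FCSParseError(ValueError):
    """Raised when a file cannot be parsed as single-dataset FCS 3.x."""


def _text_segment(table: EventTable, data_begin: int, data_end: int) -> bytes:
    n_events, n_par = table.values.shape
    pairs = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$BEGINDATA", str(data_begin)), ("$ENDDATA", str(data_end)),
        ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)), ("$TOT", str(n_events)),
    ]
    for i, name in enumerate(table.channels, start=1):
        pairs += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1.0, float(table.values[:, i - 1].max(initial=0.0)) + 1)))),
        ]
    body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in pairs) + _DELIM
    return body.encode("ascii")


def write_fcs(table: EventTable, path) -> Path:
    """Write ``table`` as a single-dataset FCS 3.1 file (float32 list mode).

    Truth labels are not representable in FCS and are dropped; use
    :func:`write_events_csv` for a mirror that keeps them.
    """
    path = Path(path)
    data = np.ascontiguousarray(table.values, dtype="<f4").tobytes()

    # TEXT length depends on the data offsets it quotes; iterate to fixpoint.
    text_begin = _HEADER_LEN
    data_begin, data_end = 0, 0
    for _ in range(4):
        text = _text_segment(table, data_begin, data_end)
        new_begin = text_begin + len(text)
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (data_begin, data_end):
            break
        data_begin, data_end = new_begin, new_end
    text = _text_segment(table, data_begin, data_end)

    def fmt(off: int) -> bytes:
        s = str(off) if off <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_begin) + fmt(text_begin + len(text) - 1) \
        + fmt(data_begin) + fmt(data_end) + fmt(0) + fmt(0)
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)
    return path


def _parse_text(raw: bytes) -> dict:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FCSParseError("TEXT segment has an odd number of tokens")
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path) -> EventTable:
    """Read a single-dataset FCS 3.0/3.1 float list-mode file."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FCSParseError(f"{path}: file shorter than an FCS header")
    if not blob[:6].startswith(b"FCS3"):
        raise FCSParseError(f"{path}: not an FCS 3.x file")

    def off(i: int) -> int:
        field = blob[10 + 8 * i: 18 + 8 * i].decode("ascii", "replace").strip()
        try:
            return int(field) if field else 0
        except ValueError:
            raise FCSParseError(f"{path}: malformed header offset {field!r}")

    text_begin, text_end = off(0), off(1)
    if text_end <= text_begin or text_end >= len(blob):
        raise FCSParseError(f"{path}: TEXT segment offsets out of range")
    kw = _parse_text(blob[text_begin:text_end + 1])

    data_begin, data_end = off(2), off(3)
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"]
        byteord = kw["$BYTEORD"]
    except KeyError as exc:
        raise FCSParseError(f"{path}: missing required keyword {exc}")
    if datatype != "F":
        raise FCSParseError(f"{path}: unsupported $DATATYPE {datatype!r}")
    if kw.get("$MODE", "L") != "L":
        raise FCSParseError(f"{path}: unsupported $MODE {kw.get('$MODE')!r}")
    endian = "<" if byteord.startswith("1") else ">"

    channels = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N")
        if name is None:
            raise FCSParseError(f"{path}: missing $P{i}N channel name")
        channels.append(name)

    expected = n_par * n_tot * 4
    data = blob[data_begin:data_end + 1]
    if len(data) < expected:
        raise FCSParseError(
            f"{path}: DATA segment truncated ({len(data)} bytes, "
            f"expected {expected})"
        )
    values = np.frombuffer(data[:expected], dtype=f"{endian}f4").reshape(n_tot, n_par)
    return EventTable(channels, np.asarray(values, dtype=np.float64))


def write_events_csv(table: EventTable, path) -> Path:
    """Write the CSV mirror: header = channel names (+ truth columns)."""
    path = Path(path)
    df = table.to_dataframe(include_truth=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_events_csv(path) -> EventTable:
    """Read a CSV mirror, restoring truth labels when present."""
    df = pd.read_csv(path)
    truth = None
    cols = list(df.columns)
    if "population" in cols:
        truth = pd.DataFrame({
            "population": df["population"].astype(str),
            "released": df["released"].astype(bool)
            if "released" in cols else False,
        })
        cols = [c for c in cols if c not in ("population", "released")]
    return EventTable(cols, df[cols].to_numpy(dtype=np.float64), truth)
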