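"""Minimal FCS 3.0 / 3.1 list-mode reader and writer.

Covers the subset of the standard that area-parameter cytometry exports
use: one TEXT segment with $-keywords, list-mode ($MODE L) data of
$DATATYPE F (float32), D (float64) or I (uniform byte-width unsigned
integers), little- or big-endian per $BYTEORD.  Everything else —
analysis segments, supplemental text, compensation, log amplification
($PnE other than "0,0") — is out of scope and rejected explicitly.

The writer exists so that round-trip behaviour is testable and synthetic
event tables can be exercised through the same path as instrument files.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from ._exceptions import FormatError

_DELIM = "/"


def read_fcs(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Read an FCS file; returns {parameter short name ($PnN): values}."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FormatError(f"{path}: truncated FCS header")
    version = raw[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        return int(raw[lo:hi].decode("ascii").strip() or 0)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)

    text = raw[text_start : text_end + 1].decode("latin-1")
    delim = text[0]
    parts = text[1:].split(delim)
    kw = {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts) - 1, 2)
        if parts[i].strip()
    }

    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) supported")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw["$DATATYPE"].upper()
    byteord = kw["$BYTEORD"].replace(" ", "")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    bits = [int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)]
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    for i in range(1, n_par + 1):
        amp = kw.get(f"$P{i}E", "0,0").replace(" ", "")
        if datatype == "I" and amp not in ("0,0", "0.0,0.0"):
            raise FormatError(f"{path}: log-amplified parameter P{i} unsupported")

    if datatype == "F":
        dtype = np.dtype(endian + "f4")
        if any(b != 32 for b in bits):
            raise FormatError(f"{path}: $DATATYPE F requires 32-bit parameters")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
        if any(b != 64 for b in bits):
            raise FormatError(f"{path}: $DATATYPE D requires 64-bit parameters")
    elif datatype == "I":
        widths = {b for b in bits}
        if len(widths) != 1 or widths.pop() not in (8, 16, 32):
            raise FormatError(f"{path}: only uniform 8/16/32-bit integers supported")
        dtype = np.dtype(endian + f"u{bits[0] // 8}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    data = raw[data_start : data_start + expected]
    if len(data) < expected:
        raise FormatError(f"{path}: data segment shorter than $PAR*$TOT events")
    matrix = np.frombuffer(data, dtype=dtype).reshape(n_tot, n_par)
    return {
        name: np.ascontiguousarray(matrix[:, i], dtype=np.float64)
        for i, name in enumerate(names)
    }


def write_fcs(path: str | os.PathLike, parameters: dict[str, np.ndarray]) -> None:
    """Write a float32 FCS 3.0 list-mode file with the given parameters."""
    names = list(parameters)
    if not names:
        raise FormatError("no parameters to write")
    cols = [np.asarray(parameters[n], dtype=np.float32) for n in names]
    n_tot = cols[0].size
    if any(c.size != n_tot for c in cols):
        raise FormatError("parameter columns differ in length")
    matrix = np.stack(cols, axis=1)
    data = matrix.astype("<f4").tobytes()

    kw = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(len(names)),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1.0, float(np.max(cols[i - 1], initial=1.0)))) + 1)

    text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kw.items()) + _DELIM
    header_len = 58
    # pad TEXT so the data offset is stable after formatting the header
    text_start = header_len
    text_bytes = text.encode("ascii")
    data_start = text_start + len(text_bytes)
    data_end = data_start + len(data) - 1
    header = "FCS3.0    " + "".join(
        f"{v:>8d}" for v in (text_start, text_start + len(text_bytes) - 1, data_start, data_end)
    )
    header += " " * (header_len - len(header))
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text_bytes)
        fh.write(data)
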