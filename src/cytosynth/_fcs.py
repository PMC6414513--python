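"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer.

Mass-cytometry event data ships as FCS files: a fixed-width ASCII HEADER
giving byte offsets, a delimited TEXT segment of keyword/value pairs, and a
binary DATA segment. Only the subset of the standard needed for ion-count
event tables is supported: list mode (``$MODE/L``), float32 (``$DATATYPE/F``)
or float64 (``$DATATYPE/D``) data, little- or big-endian byte order, one
dataset per file. Writing always emits FCS 3.1, float32, little-endian.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs", "FCSFormatError"]

_HEADER_LEN = 58


class FCSFormatError(ValueError):
    """Raised when a file is not parseable as a supported FCS dataset."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    # First byte is the delimiter; doubled delimiters inside values are
    # escaped per the standard.
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    sentinel = b"\x00\x01\x02"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim).decode("utf-8", "replace") for p in parts]
    if len(parts) % 2:
        # Trailing empty value is tolerated.
        parts.append("")
    keys = [k.strip().upper() for k in parts[0::2]]
    return dict(zip(keys, parts[1::2]))


def read_fcs(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read one FCS dataset.

    Returns ``(short_names, long_names, data)`` where ``data`` is an
    ``(n_events, n_channels)`` float64 array, ``short_names`` come from
    ``$PnN`` and ``long_names`` from ``$PnS`` (empty string when absent).
    """
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FCSFormatError(f"{path}: file too short for an FCS header")
    version = blob[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        field = blob[lo:hi].decode("ascii", "replace").strip() or "0"
        try:
            return int(field)
        except ValueError as exc:
            raise FCSFormatError(f"{path}: bad header offset {field!r}") from exc

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_beg : text_end + 1])

    if data_beg == 0:
        data_beg = int(text.get("$BEGINDATA", "0"))
    if data_end == 0:
        data_end = int(text.get("$ENDDATA", "0"))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"{path}: only list-mode ($MODE/L) data supported, got {mode}")
    dtype_code = text.get("$DATATYPE", "F").upper()
    if dtype_code == "F":
        itemsize, fmt = 4, "f"
    elif dtype_code == "D":
        itemsize, fmt = 8, "d"
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {dtype_code!r} (need F or D)")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    widths = {int(text.get(f"$P{i}B", itemsize * 8)) for i in range(1, n_par + 1)}
    if widths != {itemsize * 8}:
        raise FCSFormatError(f"{path}: mixed or non-native $PnB widths {sorted(widths)}")

    n_values = n_par * n_tot
    raw = blob[data_beg : data_beg + n_values * itemsize]
    if len(raw) < n_values * itemsize:
        raise FCSFormatError(
            f"{path}: DATA segment holds {len(raw)} bytes, "
            f"need {n_values * itemsize} for {n_tot}x{n_par}"
        )
    data = np.frombuffer(raw, dtype=f"{endian}{fmt}").astype(np.float64)
    data = data.reshape(n_tot, n_par)

    short = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    long = [text.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    return short, long, data


def write_fcs(
    path: str | Path,
    names: list[str],
    data: np.ndarray,
    long_names: list[str] | None = None,
) -> None:
    """Write an event matrix as a single FCS 3.1 dataset (float32, list mode)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D (events x channels) array")
    n_tot, n_par = data.shape
    if len(names) != n_par:
        raise ValueError(f"{len(names)} names for {n_par} data columns")
    if long_names is not None and len(long_names) != n_par:
        raise ValueError("long_names length mismatch")

    delim = "/"
    kv: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    col_max = data.max(axis=0, initial=0.0)
    for i in range(n_par):
        rng = int(max(float(col_max[i]), 1.0)) + 1
        kv.append((f"$P{i + 1}B", "32"))
        kv.append((f"$P{i + 1}E", "0,0"))
        kv.append((f"$P{i + 1}N", str(names[i]).replace(delim, "_")))
        kv.append((f"$P{i + 1}R", str(rng)))
        if long_names is not None and long_names[i]:
            kv.append((f"$P{i + 1}S", str(long_names[i]).replace(delim, "_")))

    # DATA offsets use fixed-width placeholders so the TEXT size is stable.
    kv.append(("$BEGINDATA", "%012d"))
    kv.append(("$ENDDATA", "%012d"))

    def _render(begin_data: int, end_data: int) -> bytes:
        out = [delim]
        for k, v in kv:
            if v == "%012d":
                v = "%012d" % (begin_data if k == "$BEGINDATA" else end_data)
            out.append(f"{k}{delim}{v}{delim}")
        return "".join(out).encode("ascii")

    text_beg = _HEADER_LEN
    text_len = len(_render(0, 0))
    text_end = text_beg + text_len - 1
    data_beg = text_beg + text_len
    data_end = data_beg + data.size * 4 - 1 if data.size else 0

    header = (
        b"FCS3.1"
        + b" " * 4
        + f"{text_beg:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_beg:>8d}".encode() if data_beg <= 99_999_999 else b"       0")
        + (f"{data_end:>8d}".encode() if 0 < data_end <= 99_999_999 else b"       0")
        + b"       0"
        + b"       0"
    )
    assert len(header) == _HEADER_LEN
    payload = data.astype("<f4").tobytes(order="C")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(_render(data_beg, data_end))
        fh.write(payload)
        fh.write(struct.pack("<i", 0)[:0])  # no CRC segment
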