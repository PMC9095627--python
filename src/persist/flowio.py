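"""Event-table serialization: CSV and a minimal FCS3.1 dialect.

The FCS writer emits a standard header, a TEXT segment with the required
keywords ($MODE L, $DATATYPE F, little-endian $BYTEORD, $PnN/$PnB/$PnE/$PnR)
and a float32 DATA segment; the reader accepts what the writer produces
plus any FCS3.x file restricted to list-mode single-precision float data.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CSV dialect


def write_events_csv(table, path) -> None:
    df = table.data
    with open(path, "w") as fh:
        for k, v in table.metadata.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_events_csv(path):
    from .synthetic import EventTable

    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    try:
        df = pd.read_csv(path, skiprows=header_lines)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty or df.isna().any().any():
        first_bad = 1 + header_lines + (int(df.isna().any(axis=1).idxmax()) + 1
                                        if not df.empty else 1)
        raise ParseError(f"{path}: malformed or truncated CSV near line {first_bad}")
    return EventTable(df, meta)


# ---------------------------------------------------------------------------
# FCS dialect


def write_events_fcs(table, path) -> None:
    df = table.data
    n_par = df.shape[1]
    data = np.ascontiguousarray(df.to_numpy(dtype="<f4"))
    kw = {
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(len(df)),
    }
    for i, name in enumerate(df.columns, start=1):
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}R"] = str(int(max(float(np.nanmax(data[:, i - 1], initial=1.0)), 1)) + 1)
    for k, v in table.metadata.items():
        kw[f"#{k.upper()}"] = str(v)

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    # pad TEXT so offsets are stable regardless of digit growth
    header_len = 58
    text_start = header_len
    text_bytes = text.encode("ascii")
    data_start = text_start + len(text_bytes)
    data_end = data_start + data.nbytes - 1
    header = (b"FCS3.1    "
              + f"{text_start:8d}".encode()
              + f"{text_start + len(text_bytes) - 1:8d}".encode()
              + f"{data_start:8d}".encode()
              + f"{data_end:8d}".encode()
              + f"{0:8d}".encode() + f"{0:8d}".encode())
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data.tobytes())


def read_events_fcs(path):
    from .synthetic import EventTable

    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise ParseError(f"{path}: truncated header (byte {len(raw)})")
    if not raw[:6].startswith(b"FCS3"):
        raise ParseError(f"{path}: not an FCS3.x file (byte 0)")

    def _off(a: int, b: int) -> int:
        try:
            return int(raw[a:b].decode("ascii").strip() or 0)
        except ValueError:
            raise ParseError(f"{path}: bad segment offset at byte {a}") from None

    t0, t1, d0, d1 = _off(10, 18), _off(18, 26), _off(26, 34), _off(34, 42)
    if t1 >= len(raw) or t0 >= t1:
        raise ParseError(f"{path}: TEXT segment out of bounds (byte {t0})")
    text = raw[t0:t1 + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text[1:].split(delim)
    kw = {parts[i]: parts[i + 1] for i in range(0, len(parts) - 1, 2)}
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise ParseError(f"{path}: only list-mode float FCS supported")
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    nbytes = 4 * n_par * n_tot
    if d1 - d0 + 1 < nbytes or d1 >= len(raw):
        raise ParseError(f"{path}: DATA segment truncated at byte {min(d1, len(raw))}")
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    vals = struct.unpack(f"{order}{n_par * n_tot}f", raw[d0:d0 + nbytes])
    arr = np.asarray(vals, dtype=float).reshape(n_tot, n_par)
    meta = {k[1:].lower(): v for k, v in kw.items() if k.startswith("#")}
    return EventTable(pd.DataFrame(arr, columns=names), meta)


def write_events(table, path, dialect: str = "csv") -> None:
    if dialect == "csv":
        write_events_csv(table, path)
    elif dialect == "fcs":
        write_events_fcs(table, path)
    else:
        raise ValueError(f"unsupported dialect {dialect!r} (use 'csv' or 'fcs')")


def read_events(path, dialect: str | None = None):
    if dialect is None:
        dialect = "fcs" if str(path).endswith(".fcs") else "csv"
    if dialect == "csv":
        return read_events_csv(path)
    if dialect == "fcs":
        return read_events_fcs(path)
    raise ValueError(f"unsupported dialect {dialect!r} (use 'csv' or 'fcs')")
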