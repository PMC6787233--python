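"""Delimited-text transient tables.

One file per (density, observable): '#'-prefixed ``key=value`` metadata
header lines followed by a tab-separated table with columns ``time_ps``,
``value``, ``sem``.  The writer is canonical (``%.10g`` floats, header
keys in insertion order), so parse -> write round-trips byte-identically
for files this package wrote.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .observables import TransientSeries

__all__ = ["read_transient", "write_transient", "params_hash", "TableFormatError"]

_COLUMNS = ("time_ps", "value", "sem")


class TableFormatError(ValueError):
    """Malformed transient table; the message names the offending line."""


def params_hash(params) -> str:
    """Short stable hash of a parameter set for output provenance."""
    if is_dataclass(params) and not isinstance(params, type):
        params = asdict(params)
    items = sorted((str(k), repr(v)) for k, v in dict(params).items())
    return hashlib.sha1(repr(items).encode()).hexdigest()[:12]


def _fmt(x) -> str:
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return f"{float(x):.10g}"
    return str(x)


def _parse_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    return s


def write_transient(series: TransientSeries, path) -> None:
    path = Path(path)
    lines = []
    for k, v in series.meta.items():
        lines.append(f"# {k}={_fmt(v)}")
    lines.append("\t".join(_COLUMNS))
    for t, v, s in zip(series.times, series.values, series.sem):
        lines.append(f"{_fmt(float(t))}\t{_fmt(float(v))}\t{_fmt(float(s))}")
    path.write_text("\n".join(lines) + "\n")


def read_transient(path) -> TransientSeries:
    path = Path(path)
    meta: dict = {}
    times, values, sems = [], [], []
    header_seen = False
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TableFormatError(
                        f"{path.name}:{ln}: header line without key=value"
                    )
                k, v = body.split("=", 1)
                meta[k.strip()] = _parse_value(v.strip())
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != _COLUMNS:
                    raise TableFormatError(
                        f"{path.name}:{ln}: expected columns "
                        f"{'/'.join(_COLUMNS)}, got {'/'.join(fields)}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise TableFormatError(f"{path.name}:{ln}: expected 3 columns")
            try:
                t, v, s = (float(f) for f in fields)
            except ValueError:
                raise TableFormatError(
                    f"{path.name}:{ln}: non-numeric value"
                ) from None
            if times and t <= times[-1]:
                raise TableFormatError(
                    f"{path.name}:{ln}: times not strictly increasing"
                )
            times.append(t)
            values.append(v)
            sems.append(s)
    if not header_seen or not times:
        raise TableFormatError(f"{path.name}: missing column header or data rows")
    return TransientSeries(
        np.array(times), np.array(values), np.array(sems), meta
    )
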