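"""Reading and writing landmark datasets and their annotations.

Two dialects are supported:

* ``tps`` — Rohlf TPS interchange format (``LM3=`` / ``ID=`` records, one
  block per specimen).  TPS has no missing-value convention, so it is
  restricted to complete specimens.
* ``long_table`` — the canonical delimited format: one row per
  ``(specimen, landmark_id, x, y, z)``; absent rows become absent landmarks,
  which is what partial specimens need.

Landmark order is always defined by the scheme, never by file order; rows
are re-sorted on read.  Scheme annotations (type, module, pair, midline,
curves) travel in a YAML sidecar.
"""

from __future__ import annotations

import io as _io
from typing import TextIO

import numpy as np
import pandas as pd
import yaml

from .data import (LandmarkConfiguration, LandmarkScheme, SpecimenDataset,
                   ValidationError, validate_partition)
from .align import mirror_incomplete_side  # re-exported: part of the io surface

__all__ = [
    "read_landmarks", "write_landmarks", "read_scheme", "write_scheme",
    "mirror_incomplete_side", "validate_partition", "ParseError",
]


class ParseError(ValueError):
    """Malformed input; carries the offending line number where known."""


def _as_text(stream) -> TextIO:
    if isinstance(stream, (str, bytes)):
        raise TypeError("pass an open text stream or use the path helpers")
    return stream


# ---------------------------------------------------------------------------
# scheme sidecar

def write_scheme(scheme: LandmarkScheme, stream: TextIO) -> None:
    doc = {
        "landmarks": [
            {
                "id": lid,
                "type": scheme.types[i],
                "module": scheme.modules[i],
                "midline": bool(scheme.midline[i]),
                **({"pair": scheme.pairs[lid]} if lid in scheme.pairs else {}),
            }
            for i, lid in enumerate(scheme.landmark_ids)
        ],
        "curves": [list(c) for c in scheme.curves],
    }
    yaml.safe_dump(doc, stream, sort_keys=False)


def read_scheme(stream: TextIO) -> LandmarkScheme:
    doc = yaml.safe_load(stream)
    try:
        rows = doc["landmarks"]
        ids = tuple(str(r["id"]) for r in rows)
        types = tuple(str(r["type"]) for r in rows)
        modules = tuple(str(r["module"]) for r in rows)
        midline = tuple(bool(r.get("midline", False)) for r in rows)
        pairs = {str(r["id"]): str(r["pair"]) for r in rows if "pair" in r}
        curves = tuple(tuple(str(x) for x in c) for c in doc.get("curves", []))
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed scheme file: {exc}") from exc
    return LandmarkScheme(ids, types, modules, midline, pairs, curves)


# ---------------------------------------------------------------------------
# TPS dialect

def _read_tps(stream: TextIO, scheme: LandmarkScheme) -> SpecimenDataset:
    configs = []
    coords: list[list[float]] | None = None
    expected = 0
    spec_id: str | None = None
    counter = 0

    def flush(lineno: int) -> None:
        nonlocal coords, spec_id, counter
        if coords is None:
            return
        if len(coords) != expected:
            raise ParseError(
                f"line {lineno}: specimen block has {len(coords)} of "
                f"{expected} landmark rows")
        sid = spec_id if spec_id is not None else f"specimen_{counter}"
        counter += 1
        arr = np.asarray(coords, dtype=float)
        if arr.shape[0] != scheme.k:
            raise ParseError(
                f"line {lineno}: {arr.shape[0]} landmarks, scheme has {scheme.k}")
        configs.append(LandmarkConfiguration(scheme, arr, None, sid))
        coords, spec_id = None, None

    lineno = 0
    for lineno, raw in enumerate(_as_text(stream), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            flush(lineno)
            try:
                expected = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad LM3 record {line!r}") from exc
            coords = []
        elif upper.startswith("LM="):
            raise ParseError(
                f"line {lineno}: 2D TPS record (LM=); this reader is 3D-only")
        elif upper.startswith("ID="):
            spec_id = line.split("=", 1)[1].strip()
        elif upper.startswith(("IMAGE=", "SCALE=", "CURVES=", "POINTS=")):
            continue
        else:
            if coords is None:
                raise ParseError(f"line {lineno}: coordinate row outside LM3 block")
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(
                    f"line {lineno}: expected 3 coordinates, got {len(parts)}")
            try:
                coords.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad coordinate {line!r}") from exc
    flush(lineno + 1)
    if not configs:
        raise ParseError("no specimens found in TPS stream")
    return SpecimenDataset(scheme, configs)


def _write_tps(dataset: SpecimenDataset, stream: TextIO) -> None:
    for cfg in dataset.configurations:
        if not cfg.is_complete:
            raise ValidationError(
                f"TPS has no missing-value convention; specimen "
                f"{cfg.specimen_id!r} is partial (use the long_table dialect)")
        stream.write(f"LM3={cfg.scheme.k}\n")
        for row in cfg.coords:
            stream.write(f"{row[0]:.12g} {row[1]:.12g} {row[2]:.12g}\n")
        stream.write(f"ID={cfg.specimen_id}\n")


# ---------------------------------------------------------------------------
# long-table dialect

_COLUMNS = ["specimen", "landmark_id", "x", "y", "z"]


def _read_long_table(stream: TextIO, scheme: LandmarkScheme,
                     sep: str | None = None) -> SpecimenDataset:
    text = _as_text(stream).read()
    if sep is None:
        header = text.splitlines()[0] if text else ""
        sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(_io.StringIO(text), sep=sep, dtype={"specimen": str,
                                                             "landmark_id": str})
    except Exception as exc:
        raise ParseError(f"malformed delimited table: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"long table lacks columns {missing}")
    dup = df.duplicated(subset=["specimen", "landmark_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (specimen, landmark_id) = "
            f"({row['specimen']!r}, {row['landmark_id']!r})")
    unknown = set(df["landmark_id"]) - set(scheme.landmark_ids)
    if unknown:
        raise ValidationError(f"landmark ids not in scheme: {sorted(unknown)[:5]}")
    idx = scheme.index
    configs = []
    for sid, grp in df.groupby("specimen", sort=True):
        coords = np.full((scheme.k, 3), np.nan)
        present = np.zeros(scheme.k, dtype=bool)
        rows = grp[["landmark_id", "x", "y", "z"]].to_numpy()
        for lid, x, y, z in rows:
            i = idx[lid]
            coords[i] = (float(x), float(y), float(z))
            present[i] = True
        configs.append(LandmarkConfiguration(scheme, coords, present, str(sid)))
    if not configs:
        raise ParseError("no specimens found in long table")
    return SpecimenDataset(scheme, configs)


def _write_long_table(dataset: SpecimenDataset, stream: TextIO,
                      sep: str = ",") -> None:
    stream.write(sep.join(_COLUMNS) + "\n")
    for cfg in dataset.configurations:
        for i, lid in enumerate(cfg.scheme.landmark_ids):
            if not cfg.present[i]:
                continue  # absent landmarks are simply omitted
            x, y, z = cfg.coords[i]
            stream.write(sep.join([cfg.specimen_id, lid,
                                   f"{x:.17g}", f"{y:.17g}", f"{z:.17g}"]) + "\n")


# ---------------------------------------------------------------------------
# public surface

def read_landmarks(stream: TextIO, scheme: LandmarkScheme,
                   dialect: str = "long_table") -> SpecimenDataset:
    """Read a specimen dataset in the named dialect against a known scheme."""
    if dialect == "tps":
        return _read_tps(stream, scheme)
    if dialect == "long_table":
        return _read_long_table(stream, scheme)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_landmarks(dataset: SpecimenDataset, stream: TextIO,
                    dialect: str = "long_table") -> None:
    """Write a dataset so that ``read_landmarks`` reproduces it exactly."""
    if dialect == "tps":
        _write_tps(dataset, stream)
    elif dialect == "long_table":
        _write_long_table(dataset, stream)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
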