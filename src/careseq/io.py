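"""Readers and writers for the plain-CSV interchange formats.

Wide format: one row per individual — demographic columns followed by
``T_w``/``C_w``/``M_w`` indicator columns for calendar waves w = 1..7
(wave 1 = 2015).  Long format: one row per observed individual-year with
the demographics repeated.  Missing entries are empty fields in both.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix
from .sequences import (
    MISSING_WAVE,
    IndividualRecord,
    SequencePanel,
    StateSequence,
    WaveObservation,
)

__all__ = [
    "FormatError",
    "read_records",
    "write_records",
    "write_panel",
    "read_panel",
    "write_matrix",
    "read_matrix",
]

BASE_YEAR = 2015
MAX_WAVES = 7

DEMOGRAPHIC_COLUMNS = ("sex", "age", "age_dx", "education", "partner", "employment", "psychiatric")
_IND_PREFIX = {"T": "therapy", "C": "counseling", "M": "medication"}


class FormatError(ValueError):
    """A file does not conform to the expected CSV layout."""


def _parse_indicator(raw: str, where: str) -> Optional[int]:
    raw = raw.strip()
    if raw == "":
        return None
    if raw not in ("0", "1"):
        raise FormatError(f"{where}: indicator value {raw!r} not in {{0, 1, empty}}")
    return int(raw)


def _parse_demographics(row: dict, where: str) -> dict:
    out: dict[str, object] = {}
    for col in DEMOGRAPHIC_COLUMNS:
        raw = (row.get(col) or "").strip()
        if raw == "":
            out[col] = None
        elif col in ("age", "age_dx"):
            try:
                out[col] = float(raw)
            except ValueError:
                raise FormatError(f"{where}: column {col!r} value {raw!r} is not numeric") from None
        elif col in ("partner", "employment", "psychiatric"):
            out[col] = _parse_indicator(raw, f"{where} column {col!r}")
        else:
            out[col] = raw
    return out


def _trim_record(rec_id: str, demographics: dict, waves: dict[int, WaveObservation]) -> Optional[IndividualRecord]:
    present = sorted(w for w, obs in waves.items() if not obs.empty)
    if not present:
        return None
    first, last = present[0], present[-1]
    span = tuple(waves.get(w, MISSING_WAVE) for w in range(first, last + 1))
    return IndividualRecord(
        id=rec_id, first_year=BASE_YEAR + first - 1, waves=span, demographics=demographics
    )


def read_records(path: Union[str, Path], format: str = "wide") -> list[IndividualRecord]:
    """Read individual records from a wide or long CSV."""
    if format == "wide":
        return _read_wide(path)
    if format == "long":
        return _read_long(path)
    raise ValueError(f"unknown format {format!r}")


def _read_wide(path) -> list[IndividualRecord]:
    records: list[IndividualRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing header with an 'id' column")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path} line {lineno}"
            rec_id = (row.get("id") or "").strip()
            if not rec_id:
                raise FormatError(f"{where}: empty id")
            if rec_id in seen:
                raise FormatError(f"{where}: duplicate id {rec_id!r}")
            seen.add(rec_id)
            waves: dict[int, WaveObservation] = {}
            for w in range(1, MAX_WAVES + 1):
                vals = {}
                for pfx, name in _IND_PREFIX.items():
                    vals[name] = _parse_indicator(row.get(f"{pfx}_{w}", "") or "", f"{where} column {pfx}_{w}")
                waves[w] = WaveObservation(**vals)
            rec = _trim_record(rec_id, _parse_demographics(row, where), waves)
            if rec is not None:
                records.append(rec)
    return records


def _read_long(path) -> list[IndividualRecord]:
    per_id: dict[str, dict[int, WaveObservation]] = {}
    demo: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames or "wave" not in reader.fieldnames:
            raise FormatError(f"{path}: long format needs 'id' and 'wave' columns")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path} line {lineno}"
            rec_id = (row.get("id") or "").strip()
            if not rec_id:
                raise FormatError(f"{where}: empty id")
            try:
                wave = int((row.get("wave") or "").strip())
            except ValueError:
                raise FormatError(f"{where}: wave {row.get('wave')!r} is not an integer") from None
            if not (1 <= wave <= MAX_WAVES):
                raise FormatError(f"{where}: wave {wave} outside 1..{MAX_WAVES}")
            if rec_id not in per_id:
                per_id[rec_id] = {}
                order.append(rec_id)
                demo[rec_id] = _parse_demographics(row, where)
            if wave in per_id[rec_id]:
                raise FormatError(f"{where}: duplicate wave {wave} for id {rec_id!r}")
            per_id[rec_id][wave] = WaveObservation(
                therapy=_parse_indicator(row.get("therapy", "") or "", where),
                counseling=_parse_indicator(row.get("counseling", "") or "", where),
                medication=_parse_indicator(row.get("medication", "") or "", where),
            )
    records = []
    for rec_id in order:
        rec = _trim_record(rec_id, demo[rec_id], per_id[rec_id])
        if rec is not None:
            records.append(rec)
    return records


def _fmt(v) -> str:
    if v is None:
        return ""
    return str(v)


def write_records(records: Iterable[IndividualRecord], path_or_buf, format: str = "wide") -> None:
    """Write records as a wide or long CSV (empty fields for missing values)."""
    own = isinstance(path_or_buf, (str, Path))
    fh = open(path_or_buf, "w", newline="") if own else path_or_buf
    try:
        writer = csv.writer(fh, lineterminator="\n")
        if format == "wide":
            header = ["id", *DEMOGRAPHIC_COLUMNS]
            for pfx in _IND_PREFIX:
                header += [f"{pfx}_{w}" for w in range(1, MAX_WAVES + 1)]
            writer.writerow(header)
            for rec in records:
                row = [rec.id] + [_fmt(rec.demographics.get(c)) for c in DEMOGRAPHIC_COLUMNS]
                for name in _IND_PREFIX.values():
                    for w in range(1, MAX_WAVES + 1):
                        year = BASE_YEAR + w - 1
                        row.append(_fmt(getattr(rec.wave_in_year(year), name)))
                writer.writerow(row)
        elif format == "long":
            writer.writerow(["id", "wave", "therapy", "counseling", "medication", *DEMOGRAPHIC_COLUMNS])
            for rec in records:
                for i, wave_obs in enumerate(rec.waves):
                    if wave_obs.empty:
                        continue
                    w = rec.year_of(i) - BASE_YEAR + 1
                    writer.writerow(
                        [rec.id, w, _fmt(wave_obs.therapy), _fmt(wave_obs.counseling),
                         _fmt(wave_obs.medication)]
                        + [_fmt(rec.demographics.get(c)) for c in DEMOGRAPHIC_COLUMNS]
                    )
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if own:
            fh.close()


def write_panel(panel: SequencePanel, path) -> None:
    """Panel CSV: id, L, start_year, s1..s7 (blank beyond L)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "L", "start_year"] + [f"s{t}" for t in range(1, MAX_WAVES + 1)])
        for s in panel.sequences:
            states = list(s.states) + [""] * (MAX_WAVES - s.length)
            writer.writerow([s.id, s.length, _fmt(s.start_year), *states])


def read_panel(path, alphabet: str = "state8") -> SequencePanel:
    sequences = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            states = tuple(
                int(row[f"s{t}"]) for t in range(1, MAX_WAVES + 1) if (row.get(f"s{t}") or "").strip()
            )
            if len(states) != int(row["L"]):
                raise FormatError(f"{path} line {lineno}: L does not match the states present")
            start = row.get("start_year")
            sequences.append(
                StateSequence(row["id"], states, int(start) if start else None)
            )
    return SequencePanel(sequences, alphabet=alphabet)


def write_matrix(matrix: DissimilarityMatrix, path) -> None:
    """Square CSV with an id header row and column."""
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, index_label="id")


def read_matrix(path, method: str = "lcs", norm: str = "gmean") -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    mat = DissimilarityMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float), method=method, norm=norm)
    mat.validate(atol=1e-9)
    return mat


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
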