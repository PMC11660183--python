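"""CSV readers/writers and run manifests for the pipeline's file formats.

Directory CSV columns: record_id, name, meta_category, tags (;-delimited),
flags (;-delimited), survey_date, longitude, latitude, inspection_dates
(;-delimited ISO-8601), out_of_business_date, service_description, venue_tag.
Label CSV: record_id plus one 0/1 indicator column per class in the fixed
class order.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classes import FoodClass, LabelSet, labelset_to_vector
from .records import StoreRecord

__all__ = [
    "DIRECTORY_COLUMNS",
    "write_directory_csv",
    "read_directory_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_examples_csv",
    "read_examples_csv",
    "write_manifest",
]

DIRECTORY_COLUMNS = [
    "record_id",
    "name",
    "meta_category",
    "tags",
    "flags",
    "survey_date",
    "longitude",
    "latitude",
    "inspection_dates",
    "out_of_business_date",
    "service_description",
    "venue_tag",
]

_REQUIRED_COLUMNS = ["record_id", "name", "longitude", "latitude"]


def _join(items) -> str:
    return ";".join(sorted(items))


def _date_str(d: Optional[dt.date]) -> str:
    return d.isoformat() if d is not None else ""


def _parse_date(s) -> Optional[dt.date]:
    if s is None or (isinstance(s, float)) or not str(s).strip():
        return None
    return dt.date.fromisoformat(str(s).strip())


def write_directory_csv(
    records: Sequence[StoreRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "name": r.name,
                "meta_category": r.meta_category,
                "tags": _join(r.tags),
                "flags": _join(r.flags),
                "survey_date": _date_str(r.survey_date),
                "longitude": r.longitude,
                "latitude": r.latitude,
                "inspection_dates": ";".join(d.isoformat() for d in r.inspection_dates),
                "out_of_business_date": _date_str(r.out_of_business_date),
                "service_description": r.service_description or "",
                "venue_tag": r.venue_tag or "",
            }
        )
    pd.DataFrame(rows, columns=DIRECTORY_COLUMNS).to_csv(path, index=False)


def read_directory_csv(path: str | Path) -> List[StoreRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        def split(col):
            raw = row.get(col, "")
            return frozenset(t for t in str(raw).split(";") if t)

        inspections = tuple(
            dt.date.fromisoformat(s)
            for s in str(row.get("inspection_dates", "")).split(";")
            if s
        )
        records.append(
            StoreRecord(
                record_id=row["record_id"],
                name=row["name"],
                meta_category=row.get("meta_category", ""),
                tags=split("tags"),
                flags=split("flags"),
                survey_date=_parse_date(row.get("survey_date")),
                longitude=float(row["longitude"]),
                latitude=float(row["latitude"]),
                inspection_dates=inspections,
                out_of_business_date=_parse_date(row.get("out_of_business_date")),
                service_description=row.get("service_description") or None,
                venue_tag=row.get("venue_tag") or None,
            )
        )
    return records


def write_labels_csv(
    labeled: Sequence[Tuple[str, LabelSet]], path: str | Path
) -> None:
    """Write (record_id, labels) pairs as record_id + 10 indicator columns."""
    rows = []
    for record_id, labels in labeled:
        row = {"record_id": record_id}
        vec = labelset_to_vector(labels)
        for c in FoodClass:
            row[c.value] = int(vec[c.index])
        rows.append(row)
    cols = ["record_id"] + [c.value for c in FoodClass]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> Dict[str, LabelSet]:
    df = pd.read_csv(path)
    if "record_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'record_id'")
    for c in FoodClass:
        if c.value not in df.columns:
            raise ValueError(f"{path}: missing required column {c.value!r}")
    out: Dict[str, LabelSet] = {}
    for _, row in df.iterrows():
        out[str(row["record_id"])] = frozenset(
            c for c in FoodClass if int(row[c.value])
        )
    return out


def write_examples_csv(examples, path: str | Path) -> None:
    """Write LabeledExamples: normalized_name + 10 indicator columns."""
    rows = []
    for e in examples:
        row = {"normalized_name": e.normalized_name}
        vec = labelset_to_vector(e.labels)
        for c in FoodClass:
            row[c.value] = int(vec[c.index])
        rows.append(row)
    cols = ["normalized_name"] + [c.value for c in FoodClass]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_examples_csv(path: str | Path):
    from .datasets import LabeledExample

    df = pd.read_csv(path)
    if "normalized_name" not in df.columns:
        raise ValueError(f"{path}: missing required column 'normalized_name'")
    for c in FoodClass:
        if c.value not in df.columns:
            raise ValueError(f"{path}: missing required column {c.value!r}")
    return [
        LabeledExample(
            normalized_name=str(row["normalized_name"]),
            labels=frozenset(c for c in FoodClass if int(row[c.value])),
        )
        for _, row in df.iterrows()
    ]


def write_manifest(
    path: str | Path, *, command: str, seed: Optional[int], inputs: dict, **extra
) -> None:
    """Record how an output was produced (inputs, config hash, seed, version)."""
    from . import __version__

    payload = {
        "command": command,
        "seed": seed,
        "inputs": inputs,
        "package_version": __version__,
        **extra,
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
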