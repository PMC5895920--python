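"""Readers and writers for the package's plain-text interchange formats.

* Audience snapshot — JSON Lines; first record is a header carrying
  ``{"granularity": ..., "timestamp": ...}``, each following line one
  estimate ``{geography, gender, age, ethnicity, interests: [...], count}``.
* Health statistics — CSV with header ``state,condition,prevalence``,
  prevalence a fraction in [0, 1].
* Interest taxonomy — JSON array of ``{name, role, condition?}``.
* Control covariates — CSV keyed by ``state`` with named numeric columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Union

import pandas as pd

from .core import AudienceEstimate, AudienceQuery, AudienceSnapshot, HealthStatTable, InterestSpec
from .errors import ValidationError

PathLike = Union[str, Path]


def write_snapshot(snapshot: AudienceSnapshot, path: PathLike) -> None:
    with open(path, "w") as fh:
        header = {"granularity": snapshot.granularity, "timestamp": snapshot.timestamp}
        fh.write(json.dumps(header) + "\n")
        for est in snapshot.estimates:
            q = est.query
            rec = {
                "geography": q.geography,
                "gender": q.gender,
                "age": q.age_bracket,
                "ethnicity": q.ethnic_affinity,
                "interests": sorted(q.interests),
                "count": est.count,
            }
            fh.write(json.dumps(rec) + "\n")


def read_snapshot(path: PathLike) -> AudienceSnapshot:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"snapshot file {path} is empty (missing header record)")
    header = json.loads(lines[0])
    if "granularity" not in header:
        raise ValidationError(f"snapshot file {path}: first record must carry 'granularity'")
    estimates = []
    for ln in lines[1:]:
        rec = json.loads(ln)
        query = AudienceQuery(
            geography=rec["geography"],
            gender=rec.get("gender", "any"),
            age_bracket=rec.get("age", "any"),
            ethnic_affinity=rec.get("ethnicity", "any"),
            interests=frozenset(rec.get("interests", ())),
        )
        estimates.append(AudienceEstimate(query=query, count=int(rec["count"])))
    return AudienceSnapshot(
        estimates,
        granularity=int(header["granularity"]),
        timestamp=str(header.get("timestamp", "")),
    )


def write_health_table(table: HealthStatTable, path: PathLike) -> None:
    table.frame.to_csv(path, index=False)


def read_health_table(path: PathLike) -> HealthStatTable:
    frame = pd.read_csv(
        path, dtype={"state": str, "condition": str}, float_precision="round_trip"
    )
    if frame.empty and list(frame.columns) != ["state", "condition", "prevalence"]:
        raise ValidationError(
            f"health table {path}: expected header state,condition,prevalence, got {list(frame.columns)}"
        )
    return HealthStatTable(frame)


def write_taxonomy(taxonomy: Iterable[InterestSpec], path: PathLike) -> None:
    records = []
    for spec in taxonomy:
        rec = {"name": spec.name, "role": spec.role}
        if spec.condition is not None:
            rec["condition"] = spec.condition
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_taxonomy(path: PathLike) -> List[InterestSpec]:
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise ValidationError(f"taxonomy {path}: expected a JSON array")
    return [
        InterestSpec(name=rec["name"], role=rec["role"], condition=rec.get("condition"))
        for rec in records
    ]


def read_controls(path: PathLike) -> pd.DataFrame:
    """Control covariates indexed by state; all columns must be numeric."""
    frame = pd.read_csv(path, dtype={"state": str}, float_precision="round_trip")
    if "state" not in frame.columns:
        raise ValidationError(f"controls {path}: missing 'state' column")
    if frame["state"].duplicated().any():
        dups = frame.loc[frame["state"].duplicated(), "state"].tolist()
        raise ValidationError(f"controls {path}: duplicate states {dups}")
    frame = frame.set_index("state")
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise ValidationError(f"controls {path}: non-numeric columns {non_numeric}")
    return frame
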