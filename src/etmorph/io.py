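"""File formats: landmark CSV/JSON, measurement TSV, demographics CSV.

All writes are atomic (temp file in the destination directory, then rename),
so a failed run never leaves a partial output behind. Coordinates, angles
and lengths are serialized at full double precision (``repr``); rounding to
the 1-decimal table style happens only at console display.
"""

from __future__ import annotations

import contextlib
import csv
import json
import os
import tempfile
from pathlib import Path
from typing import Iterable

import pandas as pd

from .anatomy import ETMeasurement, LandmarkId, LandmarkSet, PlaneType, Side
from .errors import ParseError
from .geometry import Point3

__all__ = [
    "atomic_write",
    "read_landmarks",
    "write_landmarks",
    "measurements_to_frame",
    "write_measurements",
    "read_measurements",
    "read_demographics",
]

LANDMARK_COLUMNS = ["subject_id", "landmark_id", "x_mm", "y_mm", "z_mm"]
MEASUREMENT_COLUMNS = ["subject_id", "side", "plane", "angle_deg", "length_mm"]


@contextlib.contextmanager
def atomic_write(path, mode: str = "w"):
    """Context manager yielding a temp file handle; on success the temp file
    replaces ``path`` atomically, on error it is removed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode, newline="" if "b" not in mode else None) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def _parse_float(text: str, what: str, row: int) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: malformed {what}: {text!r}") from None


def read_landmarks(path) -> list[LandmarkSet]:
    """Read per-subject landmark sets from CSV or JSON.

    CSV schema: header ``subject_id,landmark_id,x_mm,y_mm,z_mm``, one row per
    landmark. JSON schema: a list of ``{"subject_id": ..., "landmarks":
    {"EAC_R": [x, y, z], ...}}`` objects. Duplicate (subject, landmark) pairs
    and unknown landmark ids are rejected with the offending row named.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_landmarks_json(path)
    per_subject: dict[str, dict[LandmarkId, Point3]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (expected header "
                             f"{','.join(LANDMARK_COLUMNS)})") from None
        if [h.strip() for h in header] != LANDMARK_COLUMNS:
            raise ParseError(f"{path}: bad header {header!r}; expected "
                             f"{','.join(LANDMARK_COLUMNS)}")
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"row {i}: expected 5 fields, got {len(row)}")
            sid, lid_raw = row[0].strip(), row[1].strip()
            try:
                lid = LandmarkId.parse(lid_raw)
            except Exception:
                raise ParseError(f"row {i}: unknown landmark id {lid_raw!r}") from None
            xyz = [_parse_float(row[2 + k], f"{'xyz'[k]}_mm", i) for k in range(3)]
            bucket = per_subject.setdefault(sid, {})
            if lid in bucket:
                raise ParseError(f"row {i}: duplicate landmark {lid.value} "
                                 f"for subject {sid!r}")
            bucket[lid] = Point3(*xyz)
    if not per_subject:
        raise ParseError(f"{path}: no landmark rows found")
    return [LandmarkSet(sid, lm) for sid, lm in per_subject.items()]


def _read_landmarks_json(path: Path) -> list[LandmarkSet]:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON: {e}") from None
    if isinstance(doc, dict) and "subjects" in doc:  # cohort file: pull landmarks
        doc = [{"subject_id": s["subject_id"], "landmarks": s["landmarks"]}
               for s in doc["subjects"]]
    if not isinstance(doc, list):
        raise ParseError(f"{path}: expected a JSON list of subject objects")
    out = []
    for k, entry in enumerate(doc):
        try:
            sid = entry["subject_id"]
            lm = {LandmarkId.parse(name): Point3(*map(float, xyz))
                  for name, xyz in entry["landmarks"].items()}
        except Exception as e:
            raise ParseError(f"{path}: subject #{k}: {e}") from None
        out.append(LandmarkSet(sid, lm))
    if not out:
        raise ParseError(f"{path}: no subjects found")
    return out


def write_landmarks(sets: Iterable[LandmarkSet], path) -> None:
    """Write landmark sets to the canonical CSV (full precision)."""
    with atomic_write(path) as fh:
        w = csv.writer(fh)
        w.writerow(LANDMARK_COLUMNS)
        for s in sets:
            for lid, p in s.landmarks.items():
                w.writerow([s.subject_id, lid.value, repr(p.x), repr(p.y), repr(p.z)])


def measurements_to_frame(measurements: Iterable[ETMeasurement]) -> pd.DataFrame:
    """ETMeasurements → tidy DataFrame (one row per ear)."""
    return pd.DataFrame(
        [
            {"subject_id": m.subject_id, "side": m.side.value, "plane": m.plane.value,
             "angle_deg": m.angle_deg, "length_mm": m.length_mm}
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def write_measurements(measurements, path) -> None:
    """Write a measurement table as TSV at full precision."""
    df = (measurements if isinstance(measurements, pd.DataFrame)
          else measurements_to_frame(measurements))
    with atomic_write(path) as fh:
        fh.write("\t".join(MEASUREMENT_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.subject_id}\t{row.side}\t{row.plane}\t"
                     f"{row.angle_deg!r}\t{row.length_mm!r}\n")


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement TSV; validates columns and value domains."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                         float_precision="round_trip")
    except Exception as e:
        raise ParseError(f"{path}: {e}") from None
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for name in df["side"]:
        Side.parse(str(name))
    for name in df["plane"]:
        PlaneType.parse(str(name))
    if not df["angle_deg"].between(0, 90).all():
        raise ParseError(f"{path}: angle_deg outside [0, 90]")
    if not (df["length_mm"] > 0).all():
        raise ParseError(f"{path}: non-positive length_mm")
    return df[MEASUREMENT_COLUMNS]


def read_demographics(path) -> pd.DataFrame:
    """Read a demographics CSV with columns subject_id, age_yr, sex."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except Exception as e:
        raise ParseError(f"{path}: {e}") from None
    missing = {"subject_id", "age_yr", "sex"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    sex = df["sex"].astype(str).str.upper().str.strip()
    if not sex.isin({"F", "M"}).all():
        bad = sorted(set(sex) - {"F", "M"})
        raise ParseError(f"{path}: sex values must be F or M, got {bad}")
    out = df.copy()
    out["sex"] = sex
    return out[["subject_id", "age_yr", "sex"]]


def write_demographics(cohort_subjects, path) -> None:
    """Write subject demographics (id, age, sex) as CSV."""
    with atomic_write(path) as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "age_yr", "sex"])
        for s in cohort_subjects:
            w.writerow([s.subject_id, repr(s.age_yr), s.sex])
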