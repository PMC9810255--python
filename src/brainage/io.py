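"""CSV readers/writers for participant and feature tables.

One flat dialect everywhere: UTF-8, comma-separated, header row, ``.``
decimal separator, empty cell = absent value.  Reading is tolerant of
CRLF line endings and quoted fields (pandas handles both).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import FeatureTable, ParticipantRecord

__all__ = [
    "ParticipantFileError",
    "PARTICIPANT_COLUMNS",
    "read_participants",
    "write_participants",
    "read_feature_table",
    "write_feature_table",
    "write_cohort",
    "read_ids",
    "write_ids",
]

PARTICIPANT_COLUMNS = [
    "participant_id", "diagnosis", "age", "sex", "education", "mmse",
    "duration", "panss_total", "panss_pos", "panss_neg", "panss_gen", "cpz",
]

_OPTIONAL = PARTICIPANT_COLUMNS[6:]


class ParticipantFileError(ValueError):
    """Malformed participant table (reported with the offending line)."""


def write_participants(records: Sequence[ParticipantRecord],
                       path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({col: getattr(r, col) for col in PARTICIPANT_COLUMNS})
    pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS).to_csv(path, index=False)


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read and validate a participant table.

    Enforces: unique ids, diagnosis/sex vocabulary, MMSE in [0, 30],
    duration >= 0 and present iff patient.  Errors name the offending
    1-based file line (header is line 1).
    """
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParticipantFileError(f"{path}: missing columns {missing}")
    seen: set[str] = set()
    records = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        pid = row["participant_id"]
        if pd.isna(pid) or str(pid).strip() == "":
            raise ParticipantFileError(f"{path}:{line}: empty participant_id")
        pid = str(pid)
        if pid in seen:
            raise ParticipantFileError(f"{path}:{line}: duplicate participant_id {pid!r}")
        seen.add(pid)
        kwargs: dict = {"participant_id": pid}
        try:
            kwargs["diagnosis"] = str(row["diagnosis"])
            kwargs["sex"] = str(row["sex"])
            for col in ("age", "education", "mmse"):
                kwargs[col] = float(row[col])
            for col in _OPTIONAL:
                kwargs[col] = None if pd.isna(row[col]) else float(row[col])
            record = ParticipantRecord(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ParticipantFileError(f"{path}:{line}: {exc}") from exc
        records.append(record)
    return records


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path: str | Path, modality: str) -> FeatureTable:
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    return FeatureTable.from_frame(df, modality)


def write_cohort(
    records: Sequence[ParticipantRecord],
    tables: Mapping[str, FeatureTable],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write participants.csv and features_<modality>.csv into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    participants = outdir / "participants.csv"
    write_participants(records, participants)
    paths["participants"] = participants
    for modality, table in tables.items():
        p = outdir / f"features_{modality}.csv"
        write_feature_table(table, p)
        paths[f"features_{modality}"] = p
    return paths


def write_ids(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


def read_ids(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]
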