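"""Respondent records and the CSV schema shared by the simulator and the
analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import pandas as pd

from .reference import ARMS

__all__ = ["ResponseRecord", "CSV_COLUMNS", "records_to_frame", "frame_to_records",
           "write_csv", "read_csv"]

CSV_COLUMNS = (
    "id", "arm", "posttest_answer", "management", "age_group", "sex", "status",
    "postgrad_training", "confidence", "q1", "q2", "q3", "q4", "q5",
    "tutorial_uptake",
)


@dataclass(frozen=True)
class ResponseRecord:
    """One respondent: allocation, answers, demographics, tutorial uptake.

    ``posttest_answer`` and ``q1``-``q4`` hold raw percent strings ("" for
    blank); ``q5`` holds "ruling_in"/"ruling_out"/"" as ticked.
    """

    id: str
    arm: str
    posttest_answer: str
    management: str
    age_group: str
    sex: str
    status: str
    postgrad_training: str
    confidence: int
    q1: str
    q2: str
    q3: str
    q4: str
    q5: str
    tutorial_uptake: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm label {self.arm!r}; expected one of {ARMS}")
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ValueError(f"confidence must be 1-5, got {self.confidence!r}")


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in fields(ResponseRecord)} for r in records]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[ResponseRecord]:
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing CSV columns: {sorted(missing)}")

    def s(v) -> str:
        return "" if pd.isna(v) else str(v)

    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        out.append(ResponseRecord(
            id=s(d["id"]), arm=s(d["arm"]),
            posttest_answer=s(d["posttest_answer"]), management=s(d["management"]),
            age_group=s(d["age_group"]), sex=s(d["sex"]), status=s(d["status"]),
            postgrad_training=s(d["postgrad_training"]),
            confidence=int(d["confidence"]),
            q1=s(d["q1"]), q2=s(d["q2"]), q3=s(d["q3"]), q4=s(d["q4"]), q5=s(d["q5"]),
            tutorial_uptake=s(d["tutorial_uptake"]),
        ))
    return out


def write_csv(records: Sequence[ResponseRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_csv(path: str) -> list[ResponseRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame["confidence"] = frame["confidence"].astype(int)
    return frame_to_records(frame)
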