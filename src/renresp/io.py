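"""Long-format CSV dataset reading/writing and DataFrame conversion.

Dialect: one row per subject-visit with columns

    ID, TIME (days), DV (0/1 response), TRT (0/1), PROTBL (g/g),
    CAVG4 (µg/ml, blank if missing), CAVG12 (µg/ml, blank if missing),
    T1 (days), T2 (days, blank unless dropped), DROPPED (0/1)

Subject-level columns must be constant within ID and TIME strictly increasing.
A subject with no on-treatment observations (dropout before the first visit)
is represented by a single row with blank TIME and DV so the subject-level
fields survive the round trip. The missing-value token is an empty field.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .likelihood import impute_post_dropout
from .types import (
    DEFAULT_SCHEDULE,
    CovariateSet,
    DataConsistencyError,
    SubjectRecord,
    VisitObservation,
    STUDY_END,
)

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "to_frame", "from_frame", "as_records"]

logger = logging.getLogger(__name__)

COLUMNS = ["ID", "TIME", "DV", "TRT", "PROTBL", "CAVG4", "CAVG12", "T1", "T2", "DROPPED"]


def to_frame(
    subjects: Sequence[SubjectRecord],
    view: str = "on_treatment",
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Long-format DataFrame of a dataset in the given analysis view."""
    if view not in ("on_treatment", "imputed"):
        raise ValueError(f"unknown view {view!r}")
    rows = []
    for s in subjects:
        # the imputed (composite) view is a self-consistent schedule-complete
        # dataset: its records are "completers" by construction
        rec = impute_post_dropout(s, schedule) if view == "imputed" else s
        base = {
            "ID": rec.id,
            "TRT": rec.cov.trt,
            "PROTBL": rec.cov.prot_bl,
            "CAVG4": rec.cov.cavg4,
            "CAVG12": rec.cov.cavg12,
            "T1": rec.t1,
            "T2": rec.t2,
            "DROPPED": int(rec.dropped),
        }
        if rec.observations:
            for obs in rec.observations:
                rows.append({**base, "TIME": obs.t, "DV": obs.response})
        else:
            rows.append({**base, "TIME": None, "DV": None})
    return pd.DataFrame(rows, columns=COLUMNS)


def from_frame(df: pd.DataFrame) -> List[SubjectRecord]:
    """Validated SubjectRecords from a long-format DataFrame.

    Raises :class:`DataConsistencyError` naming the offending row for invalid
    response coding, non-monotone times, or inconsistent subject-level fields.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataConsistencyError(f"missing required columns: {missing}")
    if df.empty:
        logger.warning("dataset is empty")
        return []

    bad_dv = df["DV"].dropna()
    bad_rows = bad_dv[~bad_dv.isin([0, 1])]
    if len(bad_rows):
        raise DataConsistencyError(
            f"DV outside {{0,1}} at row(s) {list(bad_rows.index[:5])}"
        )

    records: List[SubjectRecord] = []
    for sid, g in df.groupby("ID", sort=False):
        for col in ("TRT", "PROTBL", "CAVG4", "CAVG12", "T1", "T2", "DROPPED"):
            vals = g[col]
            uniq = vals.dropna().unique()
            if len(uniq) > 1 or (vals.isna().any() and not vals.isna().all()):
                raise DataConsistencyError(
                    f"subject {sid}: column {col} not constant within subject "
                    f"(rows {list(g.index[:5])})"
                )
        times = g["TIME"].dropna().to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise DataConsistencyError(
                f"subject {sid}: TIME must be strictly increasing (rows "
                f"{list(g.index[:5])})"
            )
        first = g.iloc[0]
        cov = CovariateSet(
            trt=int(first["TRT"]),
            prot_bl=float(first["PROTBL"]),
            cavg4=None if pd.isna(first["CAVG4"]) else float(first["CAVG4"]),
            cavg12=None if pd.isna(first["CAVG12"]) else float(first["CAVG12"]),
        )
        obs = tuple(
            VisitObservation(t=float(r.TIME), response=int(r.DV))
            for r in g.itertuples()
            if not pd.isna(r.TIME)
        )
        records.append(
            SubjectRecord(
                id=str(sid),
                cov=cov,
                observations=obs,
                t1=float(first["T1"]),
                t2=None if pd.isna(first["T2"]) else float(first["T2"]),
                dropped=bool(int(first["DROPPED"])),
                study_end=STUDY_END,
            )
        )
    return records


def write_dataset(
    subjects: Sequence[SubjectRecord],
    path: Union[str, Path],
    view: str = "on_treatment",
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
) -> Path:
    """Write the dataset as UTF-8 CSV with header; empty field = missing."""
    path = Path(path)
    try:
        df = to_frame(subjects, view=view, schedule=schedule)
        # integer-valued fields as integers, floats as shortest round-trip repr
        for col in ("TIME", "DV", "T1", "TRT", "DROPPED", "PROTBL", "CAVG4", "CAVG12", "T2"):
            df[col] = df[col].map(
                lambda v: ""
                if pd.isna(v)
                else (str(int(v)) if float(v) == int(v) else repr(float(v)))
            )
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing dataset to {path}: {exc}") from exc
    return path


def read_dataset(path: Union[str, Path]) -> List[SubjectRecord]:
    """Read a long-format CSV dataset into validated SubjectRecords."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("dataset file %s is empty", path)
        return []
    return from_frame(df)


def as_records(X) -> List[SubjectRecord]:
    """Coerce dataset input: a list of SubjectRecord, a DataFrame, or a CSV path."""
    if isinstance(X, pd.DataFrame):
        return from_frame(X)
    if isinstance(X, (str, Path)):
        return read_dataset(X)
    records = list(X)
    if records and not isinstance(records[0], SubjectRecord):
        raise TypeError(
            "expected SubjectRecord sequence, DataFrame, or CSV path; got "
            f"{type(records[0]).__name__}"
        )
    return records
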