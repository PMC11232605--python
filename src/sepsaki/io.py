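"""Delimited-table readers and writers for the pipeline.

Formats (all plain text, UTF-8):

* patient records CSV — columns ``patient_id, record_type, time_h,
  start_h, end_h, value`` with record_type in {scr, urine}; creatinine
  rows fill time_h/value, urine rows fill start_h/end_h/value (the rate);
* patient metadata CSV — ``patient_id, age, rrt, gfr,
  historical_baseline_scr`` (gfr and the historical baseline may be
  blank);
* feature tables CSV — ``patient_id, center, label, x0..`` with label
  blank for target-center rows;
* concept links TSV — two columns ``patient_id, entity_id``;
* knowledge-graph triples TSV — see :mod:`sepsaki.kg`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import atomic_write_text
from .embedding import EmbeddingState, extract_knowledge_features
from .exceptions import ValidationError
from .staging import (PatientTimeline, ScrMeasurement, StagingResult,
                      UrineEpoch)

__all__ = ["read_patient_timelines", "write_staging_results",
           "read_feature_table", "read_links", "write_predictions",
           "read_predictions", "knowledge_feature_frame"]


def read_patient_timelines(records_path, meta_path=None
                           ) -> list[PatientTimeline]:
    """Assemble one `PatientTimeline` per patient from the records table
    and the optional metadata table."""
    try:
        rec = pd.read_csv(records_path)
    except Exception as exc:
        raise ValidationError(
            f"cannot parse records table {records_path}: {exc}") from exc
    needed = {"patient_id", "record_type", "value"}
    if not needed <= set(rec.columns):
        raise ValidationError(
            f"records table {records_path} must have columns "
            f"{sorted(needed)}; found {list(rec.columns)}")
    meta = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path)
        if "patient_id" not in mdf.columns:
            raise ValidationError(
                f"metadata table {meta_path} lacks patient_id")
        for _, row in mdf.iterrows():
            meta[str(row["patient_id"])] = row

    timelines = []
    for pid, grp in rec.groupby("patient_id", sort=True):
        pid = str(pid)
        scr, urine = [], []
        for idx, row in grp.iterrows():
            kind = str(row["record_type"]).strip().lower()
            if kind == "scr":
                if pd.isna(row.get("time_h")):
                    raise ValidationError(
                        f"{records_path}: scr row {idx + 2} for patient "
                        f"{pid} lacks time_h")
                scr.append(ScrMeasurement(float(row["time_h"]),
                                          float(row["value"])))
            elif kind == "urine":
                if pd.isna(row.get("start_h")) or pd.isna(row.get("end_h")):
                    raise ValidationError(
                        f"{records_path}: urine row {idx + 2} for patient "
                        f"{pid} lacks start_h/end_h")
                urine.append(UrineEpoch(float(row["start_h"]),
                                        float(row["end_h"]),
                                        float(row["value"])))
            else:
                raise ValidationError(
                    f"{records_path}: row {idx + 2} has unknown "
                    f"record_type {row['record_type']!r}")
        m = meta.get(pid)

        def _opt(field):
            if m is None or field not in m or pd.isna(m[field]):
                return None
            return float(m[field])

        timelines.append(PatientTimeline(
            patient_id=pid, scr=scr, urine=urine,
            historical_baseline_scr=_opt("historical_baseline_scr"),
            age=_opt("age") if _opt("age") is not None else 50.0,
            rrt=bool(int(m["rrt"])) if m is not None
            and "rrt" in m and not pd.isna(m["rrt"]) else False,
            gfr=_opt("gfr")))
    if not timelines:
        raise ValidationError(f"records table {records_path} is empty")
    return timelines


def write_staging_results(results: Sequence[StagingResult], path) -> None:
    """One row per patient with the stage, the comprehensive flag and a
    fired-criteria audit column (semicolon-separated
    criterion@[start,end])."""
    lines = ["patient_id,stage,comprehensive_positive,fired_criteria"]
    for r in results:
        audit = ";".join(
            f"{f.criterion}@[{f.window[0]:g},{f.window[1]:g}]"
            for f in r.fired_criteria)
        lines.append(f"{r.patient_id},{r.stage},"
                     f"{int(r.comprehensive_positive)},{audit}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_feature_table(path) -> pd.DataFrame:
    """Feature table with patient_id, center, optional label and x*
    feature columns."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(
            f"cannot parse feature table {path}: {exc}") from exc
    for col in ("patient_id", "center"):
        if col not in df.columns:
            raise ValidationError(
                f"feature table {path} lacks column {col!r}")
    bad = set(df["center"].dropna().unique()) - {"source", "target"}
    if bad:
        raise ValidationError(
            f"feature table {path}: unknown center values {sorted(bad)}")
    if not any(c.startswith("x") for c in df.columns):
        raise ValidationError(
            f"feature table {path} has no x* feature columns")
    return df


def read_links(path) -> pd.DataFrame:
    """Two-column patient -> concept link TSV (headered or not)."""
    text = Path(path).read_text(encoding="utf-8")
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected 2 tab-separated columns "
                f"(patient_id, entity_id), got {len(parts)}")
        rows.append((parts[0].strip(), parts[1].strip()))
    if rows and rows[0] == ("patient_id", "entity_id"):
        rows = rows[1:]
    return pd.DataFrame(rows, columns=["patient_id", "entity_id"])


def knowledge_feature_frame(links: pd.DataFrame, state: EmbeddingState,
                            patient_ids: Sequence[str]) -> pd.DataFrame:
    """Per-patient knowledge features x^k (columns k0..k{d_e-1}), the
    mean embedding of each patient's linked concepts; zero rows for
    patients without links."""
    by_patient = links.groupby("patient_id")["entity_id"].apply(list)
    rows = []
    import warnings as _warnings
    for pid in patient_ids:
        linked = by_patient.get(pid, [])
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            rows.append(extract_knowledge_features(linked, state))
    out = pd.DataFrame(np.vstack(rows),
                       columns=[f"k{j}" for j in range(state.d_e)])
    out.insert(0, "patient_id", list(patient_ids))
    return out


def write_predictions(patient_ids: Sequence[str], risks: np.ndarray,
                      path, labels=None) -> None:
    """Predictions CSV: patient_id, risk and (when known) label."""
    header = "patient_id,risk" + (",label" if labels is not None else "")
    lines = [header]
    for i, (pid, r) in enumerate(zip(patient_ids, risks)):
        row = f"{pid},{float(r)!r}"
        if labels is not None:
            row += f",{int(labels[i])}"
        lines.append(row)
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_predictions(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(
            f"cannot parse predictions file {path}: {exc}") from exc
    for col in ("patient_id", "risk"):
        if col not in df.columns:
            raise ValidationError(
                f"predictions file {path} lacks column {col!r}")
    return df
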