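"""Trial-level data model for the Attention Network Test (ANT).

The ANT crosses three cue conditions (no cue, center cue, spatial cue) with
two flanker target conditions (congruent, incongruent), yielding six cells
identified throughout this package by their condition codes::

    ncc  no cue,      congruent        (baseline)
    nci  no cue,      incongruent      (baseline + executive control)
    ccc  center cue,  congruent        (baseline + alerting)
    cci  center cue,  incongruent      (baseline + alerting + executive control)
    scc  spatial cue, congruent        (baseline + alerting + orienting)
    sci  spatial cue, incongruent      (baseline + alerting + orienting + executive control)

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns in :data:`TRIAL_COLUMNS` plus a derived ``condition`` column.  A
trial on which no response was registered before the deadline (a miss) has
``rt_ms`` and ``correct`` both NaN; misses count as errors in accuracy.
``correct`` is encoded as 1.0 / 0.0 / NaN.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

CUES = ("none", "center", "spatial")
TARGETS = ("congruent", "incongruent")

#: The six condition codes, in canonical order.
CONDITION_CODES = ("ncc", "nci", "ccc", "cci", "scc", "sci")

_CUE_LETTER = {"none": "n", "center": "c", "spatial": "s"}
_TARGET_LETTER = {"congruent": "c", "incongruent": "i"}

_CODE_TO_PAIR = {
    f"{cl}c{tl}": (cue, target)
    for cue, cl in _CUE_LETTER.items()
    for target, tl in _TARGET_LETTER.items()
}

#: Required columns of a trial table (before the derived ``condition`` column).
TRIAL_COLUMNS = ("subject", "block", "cue", "target", "soa_ms", "rt_ms", "correct")

SOA_MIN_MS = 200.0
SOA_MAX_MS = 600.0


class SchemaError(ValueError):
    """A required column is missing from a trial file."""


class ValidationError(ValueError):
    """Trial rows violate the schema (bad labels, impossible values)."""


def condition_code(cue: str, target: str) -> str:
    """Map a (cue, target) pair to its condition code.

    The mapping is a bijection between the six pairs and
    ``{ncc, nci, ccc, cci, scc, sci}``.
    """
    if cue not in CUES:
        raise ValidationError(f"unknown cue label {cue!r}; expected one of {CUES}")
    if target not in TARGETS:
        raise ValidationError(
            f"unknown target label {target!r}; expected one of {TARGETS}"
        )
    return f"{_CUE_LETTER[cue]}c{_TARGET_LETTER[target]}"


def decode_condition(code: str) -> tuple[str, str]:
    """Inverse of :func:`condition_code`."""
    try:
        return _CODE_TO_PAIR[code]
    except KeyError:
        raise ValidationError(
            f"unknown condition code {code!r}; expected one of {CONDITION_CODES}"
        ) from None


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw trial table and return a normalized copy.

    Checks column presence, cue/target labels (reporting offending row
    numbers), SOA range, RT positivity, and the miss convention (``rt_ms``
    NaN iff ``correct`` NaN).  Adds the derived ``condition`` column.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out = df.loc[:, list(TRIAL_COLUMNS)].copy()
    out["subject"] = out["subject"].astype(str)
    out["block"] = out["block"].astype(int)
    out["soa_ms"] = out["soa_ms"].astype(float)
    out["rt_ms"] = pd.to_numeric(out["rt_ms"], errors="coerce").astype(float)
    out["correct"] = pd.to_numeric(out["correct"], errors="coerce").astype(float)

    def _bad_rows(mask: pd.Series, column: str) -> None:
        if mask.any():
            rows = out.index[mask].tolist()[:20]
            values = sorted(set(out.loc[mask, column].astype(str)))
            raise ValidationError(
                f"invalid {column} value(s) {values} in row(s) {rows}"
            )

    _bad_rows(~out["cue"].isin(CUES), "cue")
    _bad_rows(~out["target"].isin(TARGETS), "target")

    if (out["block"] < 1).any():
        rows = out.index[out["block"] < 1].tolist()[:20]
        raise ValidationError(f"block must be >= 1; offending row(s) {rows}")
    bad_soa = (out["soa_ms"] < SOA_MIN_MS) | (out["soa_ms"] > SOA_MAX_MS)
    if bad_soa.any():
        rows = out.index[bad_soa].tolist()[:20]
        raise ValidationError(
            f"soa_ms outside [{SOA_MIN_MS:g}, {SOA_MAX_MS:g}] in row(s) {rows}"
        )
    responded = out["rt_ms"].notna()
    if (out.loc[responded, "rt_ms"] <= 0).any():
        rows = out.index[responded & (out["rt_ms"] <= 0)].tolist()[:20]
        raise ValidationError(f"rt_ms must be > 0 when present; row(s) {rows}")
    # miss convention: no RT <=> no correctness flag
    inconsistent = responded != out["correct"].notna()
    if inconsistent.any():
        rows = out.index[inconsistent].tolist()[:20]
        raise ValidationError(
            f"rt_ms and correct must be both present or both absent; row(s) {rows}"
        )
    bad_flag = responded & ~out["correct"].isin([0.0, 1.0])
    if bad_flag.any():
        rows = out.index[bad_flag].tolist()[:20]
        raise ValidationError(f"correct must be 0 or 1 when present; row(s) {rows}")

    out["condition"] = [
        condition_code(c, t) for c, t in zip(out["cue"], out["target"])
    ]
    return out


def read_trials(
    path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a trial-level CSV into a validated trial table.

    Parameters
    ----------
    path
        CSV file with a header row; comma-separated, UTF-8.
    schema
        Optional mapping from canonical column names (:data:`TRIAL_COLUMNS`)
        to the names used in the file, to accommodate E-Prime-style exports
        (e.g. ``{"rt_ms": "Target.RT"}``).
    """
    df = pd.read_csv(path)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in df.columns}
        missing = [
            canon
            for canon, src in schema.items()
            if src not in df.columns and canon not in df.columns
        ]
        if missing:
            raise SchemaError(
                f"mapped column(s) not found in {path}: "
                + ", ".join(f"{schema[c]!r} (for {c})" for c in missing)
            )
        df = df.rename(columns=rename)
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (misses become empty rt/correct fields)."""
    out = trials.loc[:, list(TRIAL_COLUMNS)].copy()
    out["correct"] = out["correct"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, index=False)


# --- condition summaries ---------------------------------------------------

#: Columns of the tidy per-subject × condition summary table.
SUMMARY_COLUMNS = (
    "subject",
    "condition",
    "n_trials",
    "n_correct",
    "accuracy",
    "median_rt_ms",
)


def medians_wide(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy summary into a subject × condition table of median RTs.

    Rows are sorted by subject id; columns follow :data:`CONDITION_CODES`.
    Raises if any retained subject is missing one of the six conditions.
    """
    wide = summary.pivot(index="subject", columns="condition", values="median_rt_ms")
    missing = [c for c in CONDITION_CODES if c not in wide.columns]
    if missing or wide.isna().any().any():
        holes = missing + [
            f"{s}:{c}"
            for s in wide.index
            for c in wide.columns
            if pd.isna(wide.at[s, c])
        ]
        raise ValidationError(f"summary is missing condition cells: {holes}")
    return wide.loc[sorted(wide.index), list(CONDITION_CODES)]


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write condition summaries as one wide CSV row per subject.

    Columns are ``median_<code>``, ``accuracy_<code>``, ``n_<code>``,
    ``n_correct_<code>`` for each of the six condition codes; the layout
    round-trips losslessly through :func:`read_summary`.
    """
    if len(summary) == 0:
        raise ValueError("refusing to write an empty summary")
    wide = summary.pivot(
        index="subject",
        columns="condition",
        values=["median_rt_ms", "accuracy", "n_trials", "n_correct"],
    )
    cols = {}
    for code in CONDITION_CODES:
        cols[f"median_{code}"] = wide[("median_rt_ms", code)]
        cols[f"accuracy_{code}"] = wide[("accuracy", code)]
        cols[f"n_{code}"] = wide[("n_trials", code)].astype(int)
        cols[f"n_correct_{code}"] = wide[("n_correct", code)].astype(int)
    pd.DataFrame(cols, index=wide.index).sort_index().to_csv(path)


def read_summary(path) -> pd.DataFrame:
    """Read a wide summary CSV (from :func:`write_summary`) back to tidy form."""
    wide = pd.read_csv(path, index_col="subject")
    records = []
    for subject, row in wide.iterrows():
        for code in CONDITION_CODES:
            records.append(
                {
                    "subject": str(subject),
                    "condition": code,
                    "n_trials": int(row[f"n_{code}"]),
                    "n_correct": int(row[f"n_correct_{code}"]),
                    "accuracy": float(row[f"accuracy_{code}"]),
                    "median_rt_ms": float(row[f"median_{code}"]),
                }
            )
    return pd.DataFrame.from_records(records, columns=list(SUMMARY_COLUMNS))
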