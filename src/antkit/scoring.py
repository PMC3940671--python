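"""ANT network scores and directed inter-network influence scores.

Both scoring methods operate on a subject's six condition medians.  Writing
the cells by their additive dissection (ncc = baseline, nci = baseline +
executive control, ccc = baseline + alerting, ...), the condition-dissection
("new") method isolates each network with a single subtraction::

    alerting  = ncc - ccc        orienting = ccc - scc
    executive = nci - ncc

while the traditional ("old") method averages over cells::

    alerting  = mean(ncc, nci) - mean(ccc, cci)
    orienting = mean(ccc, cci) - mean(scc, sci)
    executive = mean(nci, cci, sci) - mean(ncc, ccc, scc)

The four directed influence scores are interaction contrasts: how much one
network's engagement changes another network's effect::

    al_to_ex = (cci - ccc) - (nci - ncc)     # alerting enlarges the conflict effect
    or_to_ex = (sci - scc) - (cci - ccc)     # orienting changes the conflict effect
    ex_to_al = (nci - cci) - (ncc - ccc)     # conflict changes the alerting benefit
    ex_to_or = (cci - sci) - (ccc - scc)     # conflict changes the orienting benefit

In raw (millisecond) mode ``ex_to_al == -al_to_ex`` and ``ex_to_or ==
-or_to_ex`` exactly.  Normalized modes divide by the relevant baseline RT
(network scores) or by the relevant pure network score (influence scores),
which breaks the antisymmetry.

Sign convention: positive alerting/orienting is an RT benefit, positive
executive control is an RT cost, and a positive influence score means the
source network enlarges the target network's effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .trialdata import CONDITION_CODES, medians_wide

NEW_ITEMS = ("alerting", "orienting", "executive")
OLD_ITEMS = NEW_ITEMS
RELATION_ITEMS = ("al_to_ex", "or_to_ex", "ex_to_al", "ex_to_or")


class ScoreError(ValueError):
    """Invalid input to a scoring operation (missing or nonpositive median)."""


@dataclass(frozen=True)
class ScoreSet:
    """Alerting/orienting/executive scores for one subject and one method."""

    method: str                 # "old" | "new"
    normalization: str          # "raw" | "baseline"
    alerting: float
    orienting: float
    executive: float


@dataclass(frozen=True)
class RelationSet:
    """The four directed influence scores for one subject."""

    normalization: str          # "raw" | "score"
    al_to_ex: float
    or_to_ex: float
    ex_to_al: float
    ex_to_or: float


def _check_medians(m: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CONDITION_CODES if c not in m.columns]
    if missing:
        raise ScoreError(f"missing condition median(s): {missing}")
    m = m.loc[:, list(CONDITION_CODES)].astype(float)
    if m.isna().any().any() or (m <= 0).any().any():
        bad = [
            f"{s}:{c}"
            for s in m.index
            for c in CONDITION_CODES
            if not (m.at[s, c] > 0)
        ]
        raise ScoreError(f"condition medians must be positive, got invalid {bad}")
    return m


def new_scores_cohort(
    medians: pd.DataFrame, normalization: str = "baseline"
) -> pd.DataFrame:
    """Condition-dissection scores for a subject × condition median table."""
    m = _check_medians(medians)
    out = pd.DataFrame(
        {
            "alerting": m["ncc"] - m["ccc"],
            "orienting": m["ccc"] - m["scc"],
            "executive": m["nci"] - m["ncc"],
        }
    )
    if normalization == "baseline":
        out["alerting"] /= m["ncc"]
        out["orienting"] /= m["ccc"]
        out["executive"] /= m["ncc"]
    elif normalization != "raw":
        raise ScoreError(f"unknown normalization {normalization!r}")
    return out


def old_scores_cohort(
    medians: pd.DataFrame, normalization: str = "baseline"
) -> pd.DataFrame:
    """Traditional condition-mean scores for a subject × condition table."""
    m = _check_medians(medians)
    no_cue = (m["ncc"] + m["nci"]) / 2
    center = (m["ccc"] + m["cci"]) / 2
    spatial = (m["scc"] + m["sci"]) / 2
    incong = (m["nci"] + m["cci"] + m["sci"]) / 3
    cong = (m["ncc"] + m["ccc"] + m["scc"]) / 3
    out = pd.DataFrame(
        {
            "alerting": no_cue - center,
            "orienting": center - spatial,
            "executive": incong - cong,
        }
    )
    if normalization == "baseline":
        # relevant baseline = the minuend condition mean
        out["alerting"] /= no_cue
        out["orienting"] /= center
        out["executive"] /= incong
    elif normalization != "raw":
        raise ScoreError(f"unknown normalization {normalization!r}")
    return out


def relation_scores_cohort(
    medians: pd.DataFrame, normalization: str = "score"
) -> pd.DataFrame:
    """Directed influence scores for a subject × condition median table.

    In ``score`` mode each contrast is divided by the relevant pure network
    score; a zero denominator yields NaN for that subject (the relationship
    cannot be measured from a zero score), never an exception.
    """
    m = _check_medians(medians)
    conflict_none = m["nci"] - m["ncc"]
    conflict_center = m["cci"] - m["ccc"]
    conflict_spatial = m["sci"] - m["scc"]
    alerting = m["ncc"] - m["ccc"]
    orienting = m["ccc"] - m["scc"]
    out = pd.DataFrame(
        {
            "al_to_ex": conflict_center - conflict_none,
            "or_to_ex": conflict_spatial - conflict_center,
            "ex_to_al": -(conflict_center - conflict_none),
            "ex_to_or": -(conflict_spatial - conflict_center),
        }
    )
    if normalization == "score":
        denoms = {
            "al_to_ex": conflict_none,
            "or_to_ex": conflict_center,
            "ex_to_al": alerting,
            "ex_to_or": orienting,
        }
        with np.errstate(divide="ignore", invalid="ignore"):
            for item, d in denoms.items():
                out[item] = out[item].where(d != 0) / d.where(d != 0)
    elif normalization != "raw":
        raise ScoreError(f"unknown normalization {normalization!r}")
    return out


def _one_row(summary: Mapping[str, float]) -> pd.DataFrame:
    return pd.DataFrame([dict(summary)], index=["_subject"])


def new_scores(
    summary: Mapping[str, float], normalization: str = "baseline"
) -> ScoreSet:
    """Condition-dissection scores from one subject's six condition medians."""
    row = new_scores_cohort(_one_row(summary), normalization).iloc[0]
    return ScoreSet("new", normalization, *(float(row[i]) for i in NEW_ITEMS))


def old_scores(
    summary: Mapping[str, float], normalization: str = "baseline"
) -> ScoreSet:
    """Traditional scores from one subject's six condition medians."""
    row = old_scores_cohort(_one_row(summary), normalization).iloc[0]
    return ScoreSet("old", normalization, *(float(row[i]) for i in OLD_ITEMS))


def relation_scores(
    summary: Mapping[str, float], normalization: str = "score"
) -> RelationSet:
    """Directed influence scores from one subject's six condition medians."""
    row = relation_scores_cohort(_one_row(summary), normalization).iloc[0]
    return RelationSet(normalization, *(float(row[i]) for i in RELATION_ITEMS))


def score_cohort(
    summary: pd.DataFrame,
    method: str = "both",
    normalization: str | None = None,
) -> pd.DataFrame:
    """Score every subject of a tidy condition summary.

    Parameters
    ----------
    summary
        Tidy per-subject × condition summary (from ``preprocess``).
    method
        ``"new"``, ``"old"``, ``"both"`` (network scores of both methods plus
        the four influence scores), or ``"relations"``.
    normalization
        ``"raw"`` or the method's normalized mode (``baseline`` for network
        scores, ``score`` for influence scores).  Default: normalized.

    Returns a DataFrame with one row per subject, deterministically ordered
    by subject id; column names are prefixed ``new_``/``old_``/``rel_`` when
    several score families are combined.
    """
    m = medians_wide(summary)
    if len(m) == 0:
        raise ScoreError("no subjects to score")
    parts = []
    if method in ("new", "both"):
        parts.append(
            new_scores_cohort(m, normalization or "baseline").add_prefix("new_")
        )
    if method in ("old", "both"):
        parts.append(
            old_scores_cohort(m, normalization or "baseline").add_prefix("old_")
        )
    if method in ("relations", "both"):
        norm = "raw" if normalization == "raw" else "score"
        parts.append(relation_scores_cohort(m, norm).add_prefix("rel_"))
    if not parts:
        raise ScoreError(f"unknown method {method!r}")
    out = pd.concat(parts, axis=1)
    if method in ("new", "old", "relations"):
        out.columns = [c.split("_", 1)[1] for c in out.columns]
    out.index.name = "subject"
    return out
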