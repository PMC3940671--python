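"""Trial- and subject-level preprocessing for ANT data.

The pipeline order is fixed:

1. remove outlier RTs outside the [200, 1200] ms window (bounds retained);
2. compute per-condition accuracy on the remaining trials, counting misses
   (no response before the deadline) as errors;
3. exclude any subject whose accuracy falls strictly below 75% in at least
   one of the six conditions;
4. summarize retained subjects by the median RT of correct trials per
   condition (even counts: midpoint of the two middle order statistics).

All steps are pure functions of the trial table; trial order never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trialdata import CONDITION_CODES, SUMMARY_COLUMNS


class ConfigurationError(ValueError):
    """Invalid preprocessing parameters."""


class MissingConditionError(ValueError):
    """A subject has no usable trials in one of the six conditions."""


def filter_rt_window(
    trials: pd.DataFrame, low_ms: float = 200.0, high_ms: float = 1200.0
) -> tuple[pd.DataFrame, float]:
    """Remove responses with RT strictly below ``low_ms`` or above ``high_ms``.

    Returns the retained trials and the removed fraction, computed over
    responses only: misses carry no RT, pass through unchanged, and appear
    in neither numerator nor denominator.
    """
    if low_ms >= high_ms:
        raise ConfigurationError(
            f"rt window lower bound {low_ms} must be below upper bound {high_ms}"
        )
    rt = trials["rt_ms"]
    responded = rt.notna()
    removed = responded & ((rt < low_ms) | (rt > high_ms))
    n_responses = int(responded.sum())
    removed_fraction = float(removed.sum()) / n_responses if n_responses else 0.0
    return trials.loc[~removed].copy(), removed_fraction


def accuracy_by_condition(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject × condition accuracy over window-filtered trials.

    ``accuracy = n_correct / n_trials`` where ``n_trials`` counts every
    remaining trial of the condition, misses included.  Conditions with no
    remaining trials simply do not appear (they are flagged downstream, not
    reported as zero accuracy).
    """
    grouped = trials.groupby(["subject", "condition"], sort=True)
    out = grouped.agg(
        n_trials=("condition", "size"),
        n_correct=("correct", lambda c: int((c == 1.0).sum())),
    ).reset_index()
    out["accuracy"] = out["n_correct"] / out["n_trials"]
    return out


@dataclass
class ExclusionReport:
    """Subjects excluded for low accuracy, with the offending conditions."""

    threshold: float
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def as_records(self) -> list[dict]:
        return [
            {"subject": s, "conditions": conds}
            for s, conds in sorted(self.excluded.items())
        ]


def exclude_low_accuracy(
    accuracy: pd.DataFrame, threshold: float = 0.75
) -> tuple[list[str], ExclusionReport]:
    """Split subjects into retained and excluded by the accuracy criterion.

    A subject is excluded iff accuracy is strictly below ``threshold`` in at
    least one condition, or a condition is missing entirely.  Exactly at
    threshold is retained.
    """
    report = ExclusionReport(threshold=threshold)
    retained: list[str] = []
    for subject, rows in accuracy.groupby("subject", sort=True):
        present = set(rows["condition"])
        missing = [c for c in CONDITION_CODES if c not in present]
        low = rows.loc[rows["accuracy"] < threshold, "condition"].tolist()
        offending = sorted(low) + [f"{c} (no trials)" for c in missing]
        if offending:
            report.excluded[str(subject)] = offending
        else:
            retained.append(str(subject))
    return retained, report


def summarize(trials: pd.DataFrame) -> pd.DataFrame:
    """Reduce window-filtered trials to the tidy per-condition summary.

    The median RT is taken over correct responses only; accuracy over all
    window-filtered trials of the condition.  A subject × condition cell
    with zero correct trials raises :class:`MissingConditionError`.
    """
    acc = accuracy_by_condition(trials)
    correct = trials.loc[trials["correct"] == 1.0]
    med = (
        correct.groupby(["subject", "condition"], sort=True)["rt_ms"]
        .median()
        .rename("median_rt_ms")
        .reset_index()
    )
    out = acc.merge(med, on=["subject", "condition"], how="left")
    holes = [
        f"{r.subject}:{r.condition}"
        for r in out.itertuples()
        if np.isnan(r.median_rt_ms)
    ]
    for subject, rows in out.groupby("subject"):
        holes += [
            f"{subject}:{c} (no trials)"
            for c in CONDITION_CODES
            if c not in set(rows["condition"])
        ]
    if holes:
        raise MissingConditionError(
            "no correct trials for subject:condition " + ", ".join(sorted(holes))
        )
    return out.loc[:, list(SUMMARY_COLUMNS)]


@dataclass
class PreprocessResult:
    summary: pd.DataFrame            # tidy summary of retained subjects
    trials: pd.DataFrame             # window-filtered trials of retained subjects
    removed_fraction: float          # RT-window removals / responses
    exclusions: ExclusionReport

    def report(self) -> dict:
        return {
            "removed_fraction": self.removed_fraction,
            "n_retained": int(self.summary["subject"].nunique()),
            "n_excluded": len(self.exclusions.excluded),
            "accuracy_threshold": self.exclusions.threshold,
            "exclusions": self.exclusions.as_records(),
        }


def preprocess(
    trials: pd.DataFrame,
    low_ms: float = 200.0,
    high_ms: float = 1200.0,
    accuracy_threshold: float = 0.75,
) -> PreprocessResult:
    """Run the full fixed-order pipeline on a validated trial table."""
    kept, removed_fraction = filter_rt_window(trials, low_ms, high_ms)
    acc = accuracy_by_condition(kept)
    retained, exclusions = exclude_low_accuracy(acc, accuracy_threshold)
    kept = kept.loc[kept["subject"].isin(retained)].copy()
    if not retained:
        summary = pd.DataFrame(columns=list(SUMMARY_COLUMNS))
    else:
        summary = summarize(kept)
    return PreprocessResult(
        summary=summary,
        trials=kept,
        removed_fraction=removed_fraction,
        exclusions=exclusions,
    )
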