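"""Reliability of ANT scores: one-way random-effects ICC and split-half.

Test–retest reliability uses the one-way random-effects intraclass
correlation across the k experimental runs (blocks).  The total sum of
squares is split into between-subject (MSb) and within-subject residual
(MSw) mean squares, and

    ICC = (MSb - MSw) / (MSb + (k - 1) * MSw)

Internal consistency uses the permutation split-half procedure: within each
subject × condition, the correct window-filtered trials are randomly
partitioned into two halves; each half is reduced to condition medians and
scored; the two per-subject score vectors are correlated across subjects
(Pearson); the reliability of an item is the mean correlation over the
permutations (1000 by default; no Spearman–Brown correction unless
requested).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scoring
from .trialdata import CONDITION_CODES

_SCORER = {
    "new": (scoring.new_scores_cohort, scoring.NEW_ITEMS, "baseline"),
    "old": (scoring.old_scores_cohort, scoring.OLD_ITEMS, "baseline"),
    "relations": (scoring.relation_scores_cohort, scoring.RELATION_ITEMS, "score"),
}


def _resolve_normalization(method: str, normalization: str) -> str:
    """Map the generic 'normalized' request to each family's own mode."""
    if normalization == "raw":
        return "raw"
    return _SCORER[method][2]


@dataclass(frozen=True)
class ICCResult:
    """One-way random-effects ICC with its variance decomposition."""

    ms_between: float
    ms_within: float
    n: int    # subjects
    k: int    # repeated observations per subject
    icc: float


@dataclass(frozen=True)
class SplitHalfResult:
    """Permutation split-half reliability of one score item."""

    item: str
    correlations: np.ndarray   # one Pearson r per permutation
    mean: float
    n_subjects: int

    @staticmethod
    def spearman_brown(r: float) -> float:
        """Full-length reliability prophecy for a half-length correlation."""
        return 2.0 * r / (1.0 + r)


def icc_oneway(matrix) -> ICCResult:
    """One-way random-effects ICC on a complete subject × run score grid."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-d subject × run matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 runs")
    if np.isnan(x).any():
        raise ValueError("grid contains missing cells; no imputation is performed")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    ms_between = k * float(np.sum((subj_means - grand) ** 2)) / (n - 1)
    ms_within = float(np.sum((x - subj_means[:, None]) ** 2)) / (n * (k - 1))
    icc = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
    return ICCResult(ms_between, ms_within, n=n, k=k, icc=float(icc))


def _correct_rts_by_cell(trials: pd.DataFrame, min_trials: int):
    """Group correct-response RTs per subject × condition; drop thin subjects."""
    correct = trials.loc[trials["correct"] == 1.0]
    cells: dict[str, dict[str, np.ndarray]] = {}
    for (subject, condition), grp in correct.groupby(["subject", "condition"]):
        cells.setdefault(str(subject), {})[condition] = grp["rt_ms"].to_numpy()
    kept, dropped = {}, []
    for subject in sorted(cells):
        by_cond = cells[subject]
        if all(len(by_cond.get(c, ())) >= min_trials for c in CONDITION_CODES):
            kept[subject] = by_cond
        else:
            dropped.append(subject)
    if dropped:
        warnings.warn(
            f"split_half: dropped subject(s) with <{min_trials} correct trials "
            f"in some condition: {dropped}",
            stacklevel=3,
        )
    return kept


def split_half(
    trials: pd.DataFrame,
    method: str = "new",
    normalization: str = "raw",
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, SplitHalfResult]:
    """Permutation split-half reliability per score item.

    ``trials`` must already be window-filtered (the preprocessed trial
    table).  Subjects with fewer than two correct trials in any condition
    are dropped with a warning.  Odd trial counts assign the extra trial to
    a random half.  Reproducible given ``seed``.
    """
    scorer, items, _ = _SCORER[method]
    normalization = _resolve_normalization(method, normalization)
    rng = rng if rng is not None else np.random.default_rng(seed)
    cells = _correct_rts_by_cell(trials, min_trials=2)
    subjects = sorted(cells)
    if len(subjects) < 3:
        raise ValueError("split_half needs at least 3 usable subjects")

    sums = {item: 0.0 for item in items}
    all_r = {item: np.empty(n_perm) for item in items}
    rts_grid = [[cells[s][c] for c in CONDITION_CODES] for s in subjects]
    buf_a = np.empty((len(subjects), len(CONDITION_CODES)))
    buf_b = np.empty_like(buf_a)
    for p in range(n_perm):
        for i, row in enumerate(rts_grid):
            for j, rts in enumerate(row):
                shuffled = rts[rng.permutation(len(rts))]
                cut = len(rts) // 2
                if len(rts) % 2 and rng.integers(2):
                    cut += 1  # odd count: extra trial to a random half
                buf_a[i, j] = np.median(shuffled[:cut])
                buf_b[i, j] = np.median(shuffled[cut:])
        half_a = pd.DataFrame(buf_a, index=subjects, columns=list(CONDITION_CODES))
        half_b = pd.DataFrame(buf_b, index=subjects, columns=list(CONDITION_CODES))
        scores_a = scorer(half_a, normalization)
        scores_b = scorer(half_b, normalization)
        for item in items:
            a = scores_a[item].to_numpy()
            b = scores_b[item].to_numpy()
            ok = ~(np.isnan(a) | np.isnan(b))
            r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            all_r[item][p] = r
            sums[item] += r
    return {
        item: SplitHalfResult(
            item=item,
            correlations=all_r[item],
            mean=sums[item] / n_perm,
            n_subjects=len(subjects),
        )
        for item in items
    }


def per_run_scores(
    trials: pd.DataFrame, method: str = "new", normalization: str = "raw"
) -> dict[str, pd.DataFrame]:
    """Score each run (block) separately from run-level condition medians.

    Returns ``{item: subject × run DataFrame}``; only subjects with at least
    one correct trial in every condition of every run are kept.
    """
    scorer, items, _ = _SCORER[method]
    normalization = _resolve_normalization(method, normalization)
    correct = trials.loc[trials["correct"] == 1.0]
    med = (
        correct.groupby(["subject", "block", "condition"])["rt_ms"]
        .median()
        .unstack("condition")
    )
    runs = sorted(trials["block"].unique())
    per_run = {}
    complete: set[str] | None = None
    for run in runs:
        m = med.xs(run, level="block")
        m = m.dropna(axis=0, how="any")
        if not all(c in m.columns for c in CONDITION_CODES):
            m = pd.DataFrame(columns=list(CONDITION_CODES))
        per_run[run] = m
        subjects = set(map(str, m.index))
        complete = subjects if complete is None else complete & subjects
    subjects = sorted(complete or ())
    if len(subjects) < 2:
        raise ValueError("per-run scoring needs >= 2 subjects complete in every run")
    out = {item: pd.DataFrame(index=subjects, columns=runs, dtype=float) for item in items}
    for run in runs:
        scores = scorer(per_run[run].loc[subjects, list(CONDITION_CODES)], normalization)
        for item in items:
            out[item][run] = scores[item]
    return out


def reliability_report(
    trials: pd.DataFrame,
    methods: tuple[str, ...] = ("old", "new", "relations"),
    normalization: str = "raw",
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """ICC across runs plus split-half reliability for every score item.

    With the default methods this yields the 10 items — 3 old network
    scores, 3 new network scores, 4 influence scores.  Deterministic given
    ``seed``; ICC is skipped (with a notice) when fewer than 2 runs exist.
    """
    report: dict = {
        "seed": seed,
        "n_perm": n_perm,
        "normalization": normalization,
        "icc": {},
        "split_half": {},
        "notices": [],
    }
    n_runs = trials["block"].nunique()
    rng = np.random.default_rng(seed)
    for method in methods:
        if n_runs >= 2:
            grids = per_run_scores(trials, method, normalization)
            by_item = {}
            for item, grid in grids.items():
                res = icc_oneway(grid.to_numpy())
                by_item[item] = {
                    "icc": res.icc,
                    "ms_between": res.ms_between,
                    "ms_within": res.ms_within,
                    "n": res.n,
                    "k": res.k,
                }
            report["icc"][method] = by_item
        else:
            report["notices"].append(
                f"icc skipped for {method}: fewer than 2 runs present"
            )
        halves = split_half(
            trials, method, normalization, n_perm=n_perm, rng=rng
        )
        report["split_half"][method] = {
            item: {"mean_r": res.mean, "n_subjects": res.n_subjects}
            for item, res in halves.items()
        }
    return report
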