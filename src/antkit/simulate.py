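"""Synthetic ANT experiments with known ground truth.

The generator reproduces the condensed ANT design — 3 blocks of 54 trials,
each block one counterbalanced pass through 3 cues × 2 targets × 9 SOAs
(200–600 ms in 50 ms steps), a 100 ms cue, and a 1700 ms response deadline —
and draws reaction times from an additive condition-effect model.  With
baseline B, alerting benefit A, orienting benefit O, conflict cost E, and
interaction terms gamma_AE (alerting × conflict) and gamma_OE (orienting ×
conflict), the six expected cell means are::

    ncc = B                    nci = B + E
    ccc = B - A                cci = B - A + E + gamma_AE
    scc = B - A - O            sci = B - A - O + E + gamma_AE + gamma_OE

Cue benefits subtract RT, conflict adds RT.  Per subject, the baseline (and
optionally each effect parameter) receives a Normal between-subject offset;
per trial, an ex-Gaussian residual (Normal(0, sigma) + Exponential(tau)) is
added — right-skewed, as empirical RT distributions are, which is why the
scoring pipeline summarises conditions by medians.  RTs at or beyond the
deadline are recorded as misses (no RT, no correctness flag).  Correctness
is Bernoulli with a target-dependent error rate, independent of RT — a
documented simplification.  SOA is schedule metadata only: the analysis
collapses over it, and the default model gives it no effect on RT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trialdata import CONDITION_CODES, condition_code, validate_trials

#: The nine cue–target SOAs (ms): equally spaced over the 200–600 ms range.
SOA_GRID_MS = tuple(float(v) for v in range(200, 601, 50))

CUE_DURATION_MS = 100.0


class ConfigError(ValueError):
    """A simulation parameter is out of range."""


@dataclass
class SimConfig:
    """Generative parameters of a synthetic ANT cohort.

    All effect parameters are in milliseconds.  The ``*_sd_ms`` fields give
    between-subject SDs; the effect SDs default to 0 (only the baseline
    varies across subjects), in which case every difference score has zero
    between-subject variance.
    """

    n_subjects: int = 36
    n_blocks: int = 3
    baseline_ms: float = 600.0
    alerting_ms: float = 40.0
    orienting_ms: float = 35.0
    conflict_ms: float = 90.0
    gamma_ae_ms: float = 20.0
    gamma_oe_ms: float = 10.0
    subject_sd_ms: float = 40.0
    alerting_sd_ms: float = 0.0
    orienting_sd_ms: float = 0.0
    conflict_sd_ms: float = 0.0
    gamma_ae_sd_ms: float = 0.0
    gamma_oe_sd_ms: float = 0.0
    sigma_ms: float = 50.0
    tau_ms: float = 100.0
    error_rate_congruent: float = 0.02
    error_rate_incongruent: float = 0.10
    deadline_ms: float = 1700.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_blocks < 1:
            raise ConfigError("n_subjects and n_blocks must be >= 1")
        for name in (
            "subject_sd_ms",
            "alerting_sd_ms",
            "orienting_sd_ms",
            "conflict_sd_ms",
            "gamma_ae_sd_ms",
            "gamma_oe_sd_ms",
            "sigma_ms",
            "tau_ms",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("error_rate_congruent", "error_rate_incongruent"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.deadline_ms <= 0:
            raise ConfigError("deadline_ms must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


def _cell_means(
    baseline: float,
    alerting: float,
    orienting: float,
    conflict: float,
    gamma_ae: float,
    gamma_oe: float,
) -> dict[str, float]:
    return {
        "ncc": baseline,
        "nci": baseline + conflict,
        "ccc": baseline - alerting,
        "cci": baseline - alerting + conflict + gamma_ae,
        "scc": baseline - alerting - orienting,
        "sci": baseline - alerting - orienting + conflict + gamma_ae + gamma_oe,
    }


def expected_cell_means(config: SimConfig) -> dict[str, float]:
    """Closed-form expected RT of each condition cell (noise excluded)."""
    config.validate()
    return _cell_means(
        config.baseline_ms,
        config.alerting_ms,
        config.orienting_ms,
        config.conflict_ms,
        config.gamma_ae_ms,
        config.gamma_oe_ms,
    )


def make_schedule(
    n_blocks: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Counterbalanced trial plan: per block, one trial per (cue, target, SOA).

    Each block holds exactly 3 × 2 × 9 = 54 trials in an order randomized by
    the seed; every condition code appears 9 times per block.
    """
    if n_blocks < 1:
        raise ConfigError("n_blocks must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cells = [
        (cue, target, soa)
        for cue in ("none", "center", "spatial")
        for target in ("congruent", "incongruent")
        for soa in SOA_GRID_MS
    ]
    rows = []
    for block in range(1, n_blocks + 1):
        for idx in rng.permutation(len(cells)):
            cue, target, soa = cells[idx]
            rows.append(
                {
                    "block": block,
                    "cue": cue,
                    "target": target,
                    "soa_ms": soa,
                    "condition": condition_code(cue, target),
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate a full cohort; returns a validated trial table.

    Reproducible from ``config.seed``: subject parameters, schedules, RT
    noise and correctness are all drawn from one seeded generator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    error_rate = {
        "congruent": config.error_rate_congruent,
        "incongruent": config.error_rate_incongruent,
    }
    frames = []
    for s in range(1, config.n_subjects + 1):
        means = _cell_means(
            config.baseline_ms + config.subject_sd_ms * rng.standard_normal(),
            config.alerting_ms + config.alerting_sd_ms * rng.standard_normal(),
            config.orienting_ms + config.orienting_sd_ms * rng.standard_normal(),
            config.conflict_ms + config.conflict_sd_ms * rng.standard_normal(),
            config.gamma_ae_ms + config.gamma_ae_sd_ms * rng.standard_normal(),
            config.gamma_oe_ms + config.gamma_oe_sd_ms * rng.standard_normal(),
        )
        sched = make_schedule(config.n_blocks, rng=rng)
        n = len(sched)
        rt = np.array([means[c] for c in sched["condition"]])
        if config.sigma_ms > 0:
            rt = rt + config.sigma_ms * rng.standard_normal(n)
        if config.tau_ms > 0:
            rt = rt + rng.exponential(config.tau_ms, size=n)
        rt = np.maximum(rt, 1.0)  # physically impossible negatives
        p_err = np.array([error_rate[t] for t in sched["target"]])
        correct = (rng.random(n) >= p_err).astype(float)
        missed = rt >= config.deadline_ms
        rt[missed] = np.nan
        correct[missed] = np.nan
        frame = sched.copy()
        frame.insert(0, "subject", f"S{s:03d}")
        frame["rt_ms"] = rt
        frame["correct"] = correct
        frames.append(frame)
    return validate_trials(pd.concat(frames, ignore_index=True))


def inject_artifacts(
    trials: pd.DataFrame,
    fast_guess_rate: float = 0.01,
    lapse_rate: float = 0.005,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replace a random fraction of response RTs with out-of-window values.

    Fast guesses are drawn uniformly below 200 ms, lapses uniformly between
    1200 ms and the largest observed in-window margin below the deadline, so
    the standard RT-window filter has a known expected removal fraction of
    ``fast_guess_rate + lapse_rate``.
    """
    for name, rate in (("fast_guess_rate", fast_guess_rate), ("lapse_rate", lapse_rate)):
        if not 0.0 <= rate <= 0.2:
            raise ConfigError(f"{name} must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    out = trials.copy()
    responded = out["rt_ms"].notna().to_numpy()
    u = rng.random(len(out))
    fast = responded & (u < fast_guess_rate)
    lapse = responded & (u >= fast_guess_rate) & (u < fast_guess_rate + lapse_rate)
    out.loc[fast, "rt_ms"] = rng.uniform(80.0, 199.0, size=int(fast.sum()))
    out.loc[lapse, "rt_ms"] = rng.uniform(1210.0, 1690.0, size=int(lapse.sum()))
    return out
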