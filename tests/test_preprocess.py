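"""RT-window filtering, accuracy, subject exclusion, and condition medians."""

import numpy as np
import pandas as pd
import pytest

import antkit as ak
from antkit.preprocess import ConfigurationError, MissingConditionError


def _trials(rts, subject="s1", condition="ncc", correct=1.0, block=1):
    cue, target = ak.decode_condition(condition)
    return pd.DataFrame(
        {
            "subject": subject,
            "block": block,
            "cue": cue,
            "target": target,
            "soa_ms": 400.0,
            "rt_ms": rts,
            "correct": correct,
            "condition": condition,
        }
    )


class TestRtWindow:
    def test_bounds_are_retained(self):
        trials = _trials([150.0, 200.0, 700.0, 1200.0, 1250.0])
        kept, removed = ak.filter_rt_window(trials)
        assert sorted(kept["rt_ms"]) == [200.0, 700.0, 1200.0]
        assert removed == pytest.approx(0.4)

    def test_all_in_window(self):
        kept, removed = ak.filter_rt_window(_trials([300.0, 600.0, 1100.0]))
        assert removed == 0.0 and len(kept) == 3

    def test_misses_pass_through(self):
        trials = _trials([150.0, np.nan, 500.0])
        trials.loc[trials["rt_ms"].isna(), "correct"] = np.nan
        kept, removed = ak.filter_rt_window(trials)
        # the miss stays, and does not enter the removed fraction denominator
        assert kept["rt_ms"].isna().sum() == 1
        assert removed == pytest.approx(0.5)

    def test_bad_window_config(self):
        with pytest.raises(ConfigurationError):
            ak.filter_rt_window(_trials([500.0]), low_ms=1200, high_ms=200)

    def test_injected_artifact_recovery(self):
        trials = ak.simulate_dataset(ak.SimConfig(n_subjects=8, seed=2))
        dirty = ak.inject_artifacts(trials, fast_guess_rate=0.02, lapse_rate=0.01, seed=4)
        _, removed = ak.filter_rt_window(dirty)
        n = dirty["rt_ms"].notna().sum()
        se = np.sqrt(0.03 * 0.97 / n)
        # baseline contamination from the generator's own tails is tiny but >= 0
        assert 0.03 - 3 * se <= removed <= 0.03 + 3 * se + 0.01


class TestAccuracy:
    def test_fractions(self):
        perfect = _trials([500.0] * 9)
        mixed = _trials([500.0] * 9, condition="nci",
                        correct=[1, 1, 1, 1, 1, 1, 0, 0, 0])
        acc = ak.accuracy_by_condition(pd.concat([perfect, mixed]))
        by_cond = acc.set_index("condition")["accuracy"]
        assert by_cond["ncc"] == pytest.approx(1.0)
        assert by_cond["nci"] == pytest.approx(6 / 9, abs=1e-12)

    def test_misses_count_as_errors(self):
        trials = _trials([500.0, 600.0, np.nan, np.nan])
        trials.loc[trials["rt_ms"].isna(), "correct"] = np.nan
        acc = ak.accuracy_by_condition(trials)
        assert acc["accuracy"].iloc[0] == pytest.approx(0.5)
        assert acc["n_trials"].iloc[0] == 4

    def test_simulated_error_rates_recovered(self):
        cfg = ak.SimConfig(
            n_subjects=10,
            error_rate_congruent=0.05,
            error_rate_incongruent=0.15,
            seed=9,
        )
        trials = ak.simulate_dataset(cfg)
        kept, _ = ak.filter_rt_window(trials)
        acc = ak.accuracy_by_condition(kept)
        for target_rate, codes in [(0.05, ("ncc", "ccc", "scc")),
                                   (0.15, ("nci", "cci", "sci"))]:
            sub = acc.loc[acc["condition"].isin(codes)]
            n = sub["n_trials"].sum()
            p_hat = sub["n_correct"].sum() / n
            se = np.sqrt(target_rate * (1 - target_rate) / n)
            assert abs((1 - p_hat) - target_rate) < 3 * se + 0.005


class TestExclusion:
    def _accuracy_frame(self, per_condition):
        rows = [
            {"subject": s, "condition": c, "n_trials": 20,
             "n_correct": int(round(20 * a)), "accuracy": a}
            for s, conds in per_condition.items()
            for c, a in conds.items()
        ]
        return pd.DataFrame(rows)

    def test_exactly_threshold_is_retained(self):
        acc = self._accuracy_frame(
            {"s1": {c: 0.75 for c in ak.CONDITION_CODES}}
        )
        retained, report = ak.exclude_low_accuracy(acc, threshold=0.75)
        assert retained == ["s1"] and not report.excluded

    def test_single_low_condition_excludes_and_is_named(self):
        conds = {c: 0.9 for c in ak.CONDITION_CODES}
        conds["cci"] = 0.70
        acc = self._accuracy_frame({"s1": conds})
        retained, report = ak.exclude_low_accuracy(acc)
        assert retained == []
        assert report.excluded["s1"] == ["cci"]

    def test_cohort_with_seeded_low_accuracy_subjects(self):
        trials = ak.simulate_dataset(
            ak.SimConfig(n_subjects=39, seed=14,
                         error_rate_congruent=0.02, error_rate_incongruent=0.05)
        )
        # force three subjects below threshold in one condition
        bad = ["S005", "S017", "S031"]
        mask = trials["subject"].isin(bad) & (trials["condition"] == "sci")
        trials.loc[mask, "correct"] = 0.0
        result = ak.preprocess(trials)
        assert result.summary["subject"].nunique() == 36
        assert sorted(result.exclusions.excluded) == bad


class TestSummarize:
    def test_odd_count_median(self):
        trials = pd.concat(
            [_trials([500.0, 600.0, 700.0], condition=c) for c in ak.CONDITION_CODES]
        )
        summary = ak.summarize(trials)
        assert (summary["median_rt_ms"] == 600.0).all()

    def test_even_count_midpoint(self):
        trials = pd.concat(
            [_trials([500.0, 600.0, 700.0, 800.0], condition=c)
             for c in ak.CONDITION_CODES]
        )
        summary = ak.summarize(trials)
        assert (summary["median_rt_ms"] == 650.0).all()

    def test_median_over_correct_trials_only(self):
        base = [_trials([500.0, 600.0, 700.0], condition=c) for c in ak.CONDITION_CODES]
        slow_errors = _trials([1100.0, 1150.0], condition="ncc", correct=0.0)
        summary = ak.summarize(pd.concat(base + [slow_errors]))
        ncc = summary.set_index("condition").loc["ncc"]
        assert ncc["median_rt_ms"] == 600.0
        assert ncc["accuracy"] == pytest.approx(3 / 5)

    def test_zero_correct_condition_raises(self):
        frames = [_trials([500.0, 600.0], condition=c) for c in ak.CONDITION_CODES]
        frames.append(_trials([500.0], subject="s2", condition="ncc", correct=0.0))
        for c in ak.CONDITION_CODES[1:]:
            frames.append(_trials([500.0], subject="s2", condition=c))
        with pytest.raises(MissingConditionError, match="s2:ncc"):
            ak.summarize(pd.concat(frames))

    def test_trial_order_never_matters(self, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=5)
        a = ak.preprocess(small_cohort).summary
        b = ak.preprocess(shuffled).summary
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_large_sample_median_matches_generative_law(self):
        # ex-Gaussian noise: the population median of each condition is the
        # cell mean plus the same noise median, so condition differences of
        # sample medians converge on the generative effects
        cfg = ak.SimConfig(n_subjects=1, n_blocks=60, subject_sd_ms=0.0, seed=21)
        trials = ak.simulate_dataset(cfg)
        summary = ak.summarize(ak.filter_rt_window(trials)[0])
        med = summary.set_index("condition")["median_rt_ms"]
        assert med["ncc"] - med["ccc"] == pytest.approx(cfg.alerting_ms, abs=12)
        assert med["nci"] - med["ncc"] == pytest.approx(cfg.conflict_ms, abs=12)
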