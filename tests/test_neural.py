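import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gsmvar import (
    QCRules,
    apply_inclusion,
    average_over_conditions,
    baseline_stats,
    condition_stats,
    count_spikes,
    estimate_latency,
    load_trial_table,
    mean_match_ff,
    nearest_size,
    percent_change_ff,
    save_trial_table,
    significance_by_ci_overlap,
)
from gsmvar.synthetic import ConditionSpec, GeneratorSpec, generate


def _table(rows):
    defaults = dict(duration_ms=200.0, epoch_start_ms=-50.0, epoch_end_ms=300.0)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestCounting:
    def test_no_spikes_counts_zero(self):
        t = _table([dict(neuron="a", condition="c", trial=0, spike_times=np.empty(0))])
        assert count_spikes(t, 50.0).iloc[0] == 0

    def test_window_is_half_open(self):
        # latency 50, duration 200: window [50, 250) -> the spike at 49 ms is
        # out, the one at 51 ms is in
        t = _table([dict(neuron="a", condition="c", trial=0, spike_times=np.array([49.0, 51.0]))])
        assert count_spikes(t, 50.0).iloc[0] == 1

    def test_window_beyond_epoch_raises(self):
        t = _table([dict(neuron="a", condition="c", trial=0, spike_times=np.empty(0))])
        with pytest.raises(ValueError, match="exceeds recorded epoch"):
            count_spikes(t, 150.0)

    def test_homogeneous_rate_recovered(self):
        rate, dur = 40.0, 200.0
        spec = GeneratorSpec(
            conditions=(ConditionSpec("c", evoked_rate_hz=rate, gain_cv=0.0),),
            n_trials=2000, latency_ms=50.0, duration_ms=dur, baseline_rate_hz=0.0, seed=0,
        )
        table, _ = generate(spec)
        counts = count_spikes(table, 50.0)
        assert counts.mean() == pytest.approx(rate * dur / 1000.0, rel=0.05)

    def test_per_neuron_latency_mapping(self):
        t = _table(
            [
                dict(neuron="a", condition="c", trial=0, spike_times=np.array([55.0])),
                dict(neuron="b", condition="c", trial=0, spike_times=np.array([55.0])),
            ]
        )
        counts = count_spikes(t, {"a": 50.0, "b": 60.0})
        assert list(counts) == [1, 0]


class TestBaseline:
    def test_silent_baseline(self):
        t = _table([dict(neuron="a", condition="c", trial=i, spike_times=np.empty(0)) for i in range(3)])
        b = baseline_stats(t).iloc[0]
        assert b["baseline_mean"] == 0.0 and b["baseline_sd"] == 0.0

    def test_constant_baseline_has_zero_sd(self):
        t = _table([dict(neuron="a", condition="c", trial=i, spike_times=np.array([0.0])) for i in range(4)])
        b = baseline_stats(t).iloc[0]
        assert b["baseline_mean"] == 1.0 and b["baseline_sd"] == 0.0

    def test_missing_preonset_epoch_raises(self):
        t = _table([dict(neuron="a", condition="c", trial=0, spike_times=np.empty(0), epoch_start_ms=0.0)])
        with pytest.raises(ValueError, match="baseline window"):
            baseline_stats(t)

    def test_poisson_baseline_mean_matches_variance(self):
        spec = GeneratorSpec(
            conditions=(ConditionSpec("c", evoked_rate_hz=0.0, gain_cv=0.0),),
            n_trials=4000, baseline_rate_hz=40.0, latency_ms=60.0, seed=1,
        )
        table, _ = generate(spec)
        b = baseline_stats(table).iloc[0]
        assert b["baseline_sd"] ** 2 == pytest.approx(b["baseline_mean"], rel=0.1)


class TestLatency:
    def _step_table(self, latency_ms, evoked=30.0, seed=0, n_trials=200):
        spec = GeneratorSpec(
            conditions=(ConditionSpec("c", evoked_rate_hz=evoked, gain_cv=0.0),),
            n_trials=n_trials, latency_ms=latency_ms, baseline_rate_hz=5.0, seed=seed,
        )
        return generate(spec)[0]

    @pytest.mark.parametrize("true_latency", [55.0, 60.0, 75.0])
    def test_step_latency_recovered_within_10ms(self, true_latency):
        table = self._step_table(true_latency)
        est = estimate_latency(table, "n0")
        assert est is not None
        assert abs(est - true_latency) <= 10.0

    def test_flat_psth_flags_nonresponsive(self):
        spec = GeneratorSpec(
            conditions=(ConditionSpec("c", evoked_rate_hz=5.0, gain_cv=0.0),),
            n_trials=100, latency_ms=60.0, baseline_rate_hz=5.0, seed=2,
        )
        table, _ = generate(spec)
        assert estimate_latency(table, "n0") is None

    def test_stronger_step_detected_no_later(self):
        weak = estimate_latency(self._step_table(60.0, evoked=20.0, seed=3), "n0")
        strong = estimate_latency(self._step_table(60.0, evoked=80.0, seed=3), "n0")
        assert strong is not None and weak is not None
        assert strong <= weak


class TestInclusion:
    def _recording(self, gain_cv=0.2, evoked=(10.0, 40.0, 30.0), seed=0, n_trials=60):
        conds = tuple(
            ConditionSpec(f"s{i}", evoked_rate_hz=e, gain_cv=gain_cv, size_deg=s)
            for i, (e, s) in enumerate(zip(evoked, (0.3, 1.0, 2.0)))
        )
        spec = GeneratorSpec(conditions=conds, n_trials=n_trials, latency_ms=60.0, seed=seed)
        return generate(spec)[0]

    def test_well_behaved_neuron_passes_all_rules(self):
        table = self._recording()
        qc, kept, log = apply_inclusion(table, QCRules(size_peak_min_deg=0.3, size_peak_max_deg=4.0))
        assert qc[0].included and qc[0].rules_fired == []
        assert len(kept) == len(table)

    def test_high_ff_neuron_excluded(self):
        # huge gain variability pushes the average FF over 2
        table = self._recording(gain_cv=1.0, seed=1)
        qc, kept, _ = apply_inclusion(table, QCRules())
        assert not qc[0].ff_ok and not qc[0].included
        assert kept.empty

    def test_peak_at_smallest_size_excluded(self):
        table = self._recording(evoked=(50.0, 20.0, 10.0), seed=2)
        qc, kept, _ = apply_inclusion(table, QCRules(size_peak_min_deg=0.3))
        assert not qc[0].centering_ok and kept.empty

    def test_rf_offset_rule(self):
        table = self._recording()
        table["rf_offset_deg"] = 0.6
        qc, kept, _ = apply_inclusion(table, QCRules(max_rf_offset_deg=0.4))
        assert not qc[0].centering_ok


class TestConditionStats:
    def test_constant_counts(self):
        st_ = condition_stats(np.full(8, 4.0), seed=0)
        assert st_.mean == 4.0 and st_.ff == 0.0
        assert st_.mean_ci == (4.0, 4.0)

    def test_two_trial_unbiased_variance(self):
        st_ = condition_stats(np.array([1.0, 3.0]), seed=0)
        assert st_.mean == 2.0 and st_.variance == 2.0 and st_.ff == 1.0

    def test_poisson_ff_ci_covers_one(self):
        rng = np.random.default_rng(3)
        st_ = condition_stats(rng.poisson(8.0, size=500).astype(float), seed=1)
        assert st_.ff_ci[0] <= 1.0 <= st_.ff_ci[1]

    def test_single_trial_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            condition_stats(np.array([1.0]))


class TestAveraging:
    def test_geometric_mean_of_ffs(self):
        df = pd.DataFrame({"mean": [2.0, 4.0], "ff": [1.0, 4.0]})
        out = average_over_conditions(df)
        assert out["ff"] == pytest.approx(2.0)
        assert out["mean"] == pytest.approx(3.0)

    def test_single_condition_identity(self):
        df = pd.DataFrame({"mean": [5.0], "ff": [1.3]})
        out = average_over_conditions(df)
        assert out["mean"] == 5.0 and out["ff"] == pytest.approx(1.3)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.1, 10), min_size=2, max_size=8))
    def test_geometric_never_exceeds_arithmetic(self, ffs):
        df = pd.DataFrame({"mean": np.ones(len(ffs)), "ff": ffs})
        assert average_over_conditions(df)["ff"] <= np.mean(ffs) + 1e-12

    def test_zero_ff_excluded_with_count(self):
        df = pd.DataFrame({"mean": [1.0, 1.0], "ff": [0.0, 2.0]})
        out = average_over_conditions(df)
        assert out["ff"] == pytest.approx(2.0) and out["n_ff_excluded"] == 1


class TestPercentChange:
    def test_population_ff_values(self):
        # the small/large population FFs 1.22 vs 1.15 correspond to a ~5.9%
        # symmetric change
        assert percent_change_ff(1.22, 1.15) == pytest.approx(5.907, abs=0.01)

    def test_no_change_is_zero(self):
        assert percent_change_ff(1.3, 1.3) == 0.0

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(0.01, 10), st.floats(0.01, 10))
    def test_antisymmetry(self, a, b):
        assert percent_change_ff(a, b) == pytest.approx(-percent_change_ff(b, a))

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            percent_change_ff(0.0, 0.0)


class TestMeanMatching:
    def test_per_bin_minimum_subsampling(self):
        a = pd.DataFrame({"mean": [2, 2, 2, 5, 5], "ff": [1.0, 1.1, 1.2, 1.3, 1.4]})
        b = pd.DataFrame({"mean": [2, 5, 5, 9, 9, 9, 9], "ff": [2.0, 2.1, 2.2, 2.3, 2.4, 2.5, 2.6]})
        res = mean_match_ff(a, b, seed=0)
        assert len(res.matched_a) == len(res.matched_b) == 3
        assert sorted(res.matched_a["mean"]) == [2, 5, 5]
        assert sorted(res.matched_b["mean"]) == [2, 5, 5]

    def test_identical_groups_fully_retained(self):
        g = pd.DataFrame({"mean": [1, 2, 3, 3], "ff": [1.1, 1.2, 1.3, 1.4]})
        res = mean_match_ff(g, g.copy(), seed=1)
        assert len(res.matched_a) == 4
        assert res.ff_mean_a == pytest.approx(res.ff_mean_b)
        assert res.percent_change == pytest.approx(0.0)

    def test_disjoint_supports_raise(self):
        a = pd.DataFrame({"mean": [1, 1], "ff": [1.0, 1.0]})
        b = pd.DataFrame({"mean": [9, 9], "ff": [1.0, 1.0]})
        with pytest.raises(ValueError, match="disjoint"):
            mean_match_ff(a, b)

    def test_detects_real_ff_difference(self):
        rng = np.random.default_rng(4)
        means = rng.integers(2, 10, size=200).astype(float)
        a = pd.DataFrame({"mean": means, "ff": rng.normal(1.3, 0.1, 200)})
        b = pd.DataFrame({"mean": means, "ff": rng.normal(1.1, 0.1, 200)})
        res = mean_match_ff(a, b, seed=2)
        assert res.percent_change > 0 and res.p_value < 0.01


class TestCIOverlap:
    @pytest.mark.parametrize(
        "ci_a, ci_b, expected",
        [((1, 2), (3, 4), True), ((1, 3), (2, 4), False), ((1, 2), (2, 3), False)],
    )
    def test_overlap_convention(self, ci_a, ci_b, expected):
        assert significance_by_ci_overlap(ci_a, ci_b) is expected
        assert significance_by_ci_overlap(ci_b, ci_a) is expected


class TestHelpers:
    def test_nearest_size_uses_log_scale(self):
        sizes = [0.34, 0.55, 0.90, 2.4, 3.8]
        # RF 0.9: half RF 0.45 is log-closer to 0.55 than to 0.34
        assert nearest_size(sizes, 0.45) == 0.55
        assert nearest_size(sizes, 1.8) == 2.4

    def test_trial_table_roundtrip(self, tmp_path):
        spec = GeneratorSpec(
            conditions=(ConditionSpec("c", evoked_rate_hz=20.0, gain_cv=0.1, size_deg=1.0),),
            n_trials=5, seed=0,
        )
        table, _ = generate(spec)
        path = tmp_path / "t.csv"
        save_trial_table(table, path)
        loaded = load_trial_table(path)
        assert len(loaded) == len(table)
        assert np.array_equal(
            count_spikes(loaded, 50.0).to_numpy(), count_spikes(table, 50.0).to_numpy()
        )
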