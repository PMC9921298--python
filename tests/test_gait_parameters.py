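import numpy as np
import pandas as pd
import pytest

from stridewarp import (
    AngleTrace,
    Condition,
    FootPositionTrace,
    GaitEventTable,
    Joint,
    Side,
    compute_gait_parameters,
    double_support_pct,
    range_of_motion,
    significance_report,
    stance_symmetry_ratio,
    stance_time,
    step_length,
)


def _events(rows) -> GaitEventTable:
    return GaitEventTable(pd.DataFrame(rows, columns=["time_s", "side", "event"]))


class TestStanceTime:
    def test_single_cycle(self):
        ev = _events([(0.0, "pro", "foot_strike"), (0.62, "pro", "foot_off")])
        np.testing.assert_allclose(stance_time(ev, Side.PRO), [0.62])

    def test_two_cycles(self):
        ev = _events(
            [
                (0.0, "pro", "foot_strike"),
                (0.6, "pro", "foot_off"),
                (1.0, "pro", "foot_strike"),
                (1.6, "pro", "foot_off"),
            ]
        )
        np.testing.assert_allclose(stance_time(ev, Side.PRO), [0.6, 0.6])

    def test_leading_off_ignored(self):
        ev = _events(
            [
                (0.1, "pro", "foot_off"),
                (0.5, "pro", "foot_strike"),
                (1.1, "pro", "foot_off"),
            ]
        )
        np.testing.assert_allclose(stance_time(ev, Side.PRO), [0.6])

    def test_trailing_strike_skipped_with_warning(self):
        ev = _events(
            [
                (0.0, "pro", "foot_strike"),
                (0.6, "pro", "foot_off"),
                (1.0, "pro", "foot_strike"),
            ]
        )
        with pytest.warns(UserWarning, match="trailing"):
            out = stance_time(ev, Side.PRO)
        np.testing.assert_allclose(out, [0.6])


class TestSymmetryRatio:
    @pytest.mark.parametrize(
        "pro,nonpro,expected", [(0.6, 0.6, 1.0), (0.5, 0.625, 0.8), (0.625, 0.5, 1.25)]
    )
    def test_directionality(self, pro, nonpro, expected):
        assert stance_symmetry_ratio(pro, nonpro) == pytest.approx(expected)

    def test_reciprocal_property(self, rng):
        for _ in range(10):
            a, b = rng.uniform(0.3, 1.0, size=2)
            assert stance_symmetry_ratio(a, b) * stance_symmetry_ratio(b, a) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            stance_symmetry_ratio(0.0, 0.6)


class TestDoubleSupport:
    def _constructed(self):
        # pro stance [0, 0.65]; nonpro stances [-0.35, 0.15] and [0.5, 1.15]
        return _events(
            [
                (-0.35, "nonpro", "foot_strike"),
                (0.0, "pro", "foot_strike"),
                (0.15, "nonpro", "foot_off"),
                (0.5, "nonpro", "foot_strike"),
                (0.65, "pro", "foot_off"),
                (1.0, "pro", "foot_strike"),
                (1.15, "nonpro", "foot_off"),
                (1.62, "pro", "foot_off"),
            ]
        )

    def test_constructed_example(self):
        # overlap within [0, 1]: (0.15 - 0) + (0.65 - 0.5) = 0.30
        assert double_support_pct(self._constructed(), (0.0, 1.0)) == pytest.approx(30.0)

    def test_matches_dense_grid_oracle(self):
        # brute-force: fraction of a fine time grid where both feet are down
        ev = self._constructed()
        t = np.linspace(0.0, 1.0, 100001)
        pro_down = (t >= 0.0) & (t <= 0.65)
        non_down = ((t >= -0.35) & (t <= 0.15)) | ((t >= 0.5) & (t <= 1.15))
        oracle = 100.0 * np.mean(pro_down & non_down)
        assert double_support_pct(ev, (0.0, 1.0)) == pytest.approx(oracle, abs=0.01)

    def test_instantaneous_transfer_is_zero(self):
        ev = _events(
            [
                (0.0, "pro", "foot_strike"),
                (0.5, "pro", "foot_off"),
                (0.5, "nonpro", "foot_strike"),
                (1.0, "nonpro", "foot_off"),
                (1.0, "pro", "foot_strike"),
                (1.5, "pro", "foot_off"),
            ]
        )
        assert double_support_pct(ev, (0.0, 1.0)) == 0.0

    def test_both_feet_always_down(self):
        ev = _events(
            [
                (0.0, "pro", "foot_strike"),
                (0.0, "nonpro", "foot_strike"),
                (2.0, "pro", "foot_off"),
                (2.0, "nonpro", "foot_off"),
            ]
        )
        assert double_support_pct(ev, (0.0, 1.0)) == pytest.approx(100.0)

    def test_missing_contralateral_flagged_nan(self):
        ev = _events([(0.0, "pro", "foot_strike"), (0.65, "pro", "foot_off")])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(double_support_pct(ev, (0.0, 1.0)))

    def test_stance_phases_partition_the_cycle(self):
        # both-down + exactly-one-down + none-down durations sum to the cycle
        ev = self._constructed()
        t = np.linspace(0.0, 1.0, 200001)
        pro_down = (t >= 0.0) & (t <= 0.65)
        non_down = ((t >= -0.35) & (t <= 0.15)) | ((t >= 0.5) & (t <= 1.15))
        both = np.mean(pro_down & non_down)
        one = np.mean(pro_down ^ non_down)
        none = np.mean(~pro_down & ~non_down)
        assert both + one + none == pytest.approx(1.0)
        assert 100.0 * both == pytest.approx(
            double_support_pct(ev, (0.0, 1.0)), abs=0.01
        )


class TestStepLength:
    def _positions(self, pro_val, non_val, n=200, rate=100.0):
        return {
            Side.PRO: FootPositionTrace(Side.PRO, rate, np.full(n, pro_val)),
            Side.NONPRO: FootPositionTrace(Side.NONPRO, rate, np.full(n, non_val)),
        }

    def test_inter_foot_distance_at_strike(self):
        ev = _events([(1.0, "pro", "foot_strike"), (1.6, "pro", "foot_off")])
        steps = step_length(self._positions(1.30, 0.65), ev)
        np.testing.assert_allclose(steps[Side.PRO], [0.65])

    def test_level_feet_give_zero(self):
        ev = _events([(1.0, "pro", "foot_strike"), (1.6, "pro", "foot_off")])
        steps = step_length(self._positions(0.8, 0.8), ev)
        np.testing.assert_allclose(steps[Side.PRO], [0.0])

    def test_strike_outside_trace_skipped(self):
        ev = _events([(5.0, "pro", "foot_strike"), (5.6, "pro", "foot_off")])
        with pytest.warns(UserWarning, match="skipped"):
            steps = step_length(self._positions(1.0, 0.0, n=100), ev)
        assert len(steps[Side.PRO]) == 0

    def test_symmetric_walker_steps_equal(self, small_config):
        # generator configured with identical step-length means per side
        import dataclasses

        from stridewarp import generate_session

        cfg = dataclasses.replace(
            small_config,
            step_length_means={Side.PRO: (0.6, 0.6), Side.NONPRO: (0.6, 0.6)},
            step_jitter_sd=0.0,
        )
        session = generate_session(cfg)
        ev = session.events[Condition.PRE_NP]
        steps = step_length(session.positions[Condition.PRE_NP], ev)
        n = min(len(steps[Side.PRO]), len(steps[Side.NONPRO]))
        np.testing.assert_allclose(
            steps[Side.PRO][:n], steps[Side.NONPRO][:n], atol=1e-9
        )


class TestRangeOfMotion:
    def test_sinusoid_amplitude(self):
        t = np.arange(0, 2, 0.01)
        trace = AngleTrace(Joint.KNEE_PRO, 100.0, 30.0 * np.sin(2 * np.pi * t))
        assert range_of_motion(trace, (0.0, 2.0)) == pytest.approx(60.0, abs=0.01)

    def test_constant_angle(self):
        trace = AngleTrace(Joint.HIP_PRO, 100.0, np.full(100, 12.0))
        assert range_of_motion(trace, (0.0, 1.0)) == 0.0

    def test_sawtooth(self):
        vals = np.concatenate([np.linspace(10, 70, 50), np.linspace(70, 10, 50)])
        trace = AngleTrace(Joint.HIP_PRO, 100.0, vals)
        assert range_of_motion(trace, (0.0, 1.0)) == pytest.approx(60.0)

    def test_offset_invariance(self, rng):
        vals = rng.normal(size=150)
        a = AngleTrace(Joint.KNEE_PRO, 100.0, vals)
        b = AngleTrace(Joint.KNEE_PRO, 100.0, vals + 37.0)
        assert range_of_motion(a, (0.0, 1.5)) == pytest.approx(
            range_of_motion(b, (0.0, 1.5)), abs=1e-10
        )

    def test_empty_interval_rejected(self):
        trace = AngleTrace(Joint.HIP_PRO, 100.0, np.zeros(100))
        with pytest.raises(ValueError):
            range_of_motion(trace, (5.0, 6.0))


def _param_frame(rng, shifts: dict[str, float], n=50) -> pd.DataFrame:
    """Synthetic parameter samples: POST_P shifted by `shifts[param]` SDs."""
    rows = []
    for param, shift in shifts.items():
        for cond in Condition:
            delta = shift if cond == Condition.POST_P else 0.0
            for i, v in enumerate(rng.normal(delta, 1.0, size=n)):
                rows.append((param, v, i, cond.value))
    return pd.DataFrame(rows, columns=["parameter", "value", "stride_index", "condition"])


class TestSignificanceReport:
    def test_huge_effect_flagged(self, rng):
        samples = _param_frame(rng, {"a": 5.0})
        report = significance_report(samples)
        assert report.parameters["a"].changed
        assert report.overall_changed

    def test_fifty_percent_rule(self, rng):
        shifts = {f"p{i}": (5.0 if i < 5 else 0.0) for i in range(10)}
        report = significance_report(_param_frame(rng, shifts))
        assert report.n_tested == 10
        assert report.n_changed >= 5
        assert report.overall_changed

    def test_untestable_parameter_excluded_from_denominator(self, rng):
        samples = _param_frame(rng, {"a": 5.0})
        extra = pd.DataFrame(
            [("locked_knee", 0.0, 0, Condition.PRE_NP.value)],
            columns=["parameter", "value", "stride_index", "condition"],
        )
        report = significance_report(pd.concat([samples, extra], ignore_index=True))
        assert not report.parameters["locked_knee"].testable
        assert report.n_tested == 1

    def test_tukey_gated_on_omnibus(self, rng):
        samples = _param_frame(rng, {"a": 0.0})
        report = significance_report(samples, alpha=1e-12)
        assert report.parameters["a"].pairwise == {}

    def test_pairwise_matches_statsmodels_directly(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        samples = _param_frame(rng, {"a": 1.0})
        report = significance_report(samples)
        sub = samples[samples["parameter"] == "a"]
        tukey = pairwise_tukeyhsd(sub["value"], sub["condition"], alpha=0.05)
        key = "|".join(sorted([Condition.PRE_NP.value, Condition.POST_P.value]))
        gu = list(tukey.groupsunique)
        import itertools

        expected = {
            "|".join(sorted([str(gu[i]), str(gu[j])])): float(p)
            for (i, j), p in zip(itertools.combinations(range(len(gu)), 2), tukey.pvalues)
        }[key]
        assert report.parameters["a"].pairwise[key] == pytest.approx(expected)


class TestComputeGaitParameters:
    def test_full_parameter_table_from_synthetic_session(self, small_session):
        cond = Condition.PRE_NP
        df = compute_gait_parameters(
            small_session.events[cond],
            small_session.angles[cond],
            small_session.positions[cond],
            cond,
        )
        names = set(df["parameter"])
        assert {
            "stance_time_pro",
            "stance_time_nonpro",
            "stance_symmetry_ratio",
            "double_support_pct",
            "step_length_pro",
            "step_length_nonpro",
            "knee_rom_pro",
            "hip_rom_nonpro",
        } <= names
        truth = small_session.truth[cond]
        st = df[df["parameter"] == "stance_time_pro"]["value"].to_numpy()
        np.testing.assert_allclose(st[: truth["n_strides"]], truth["stance_time_pro"])
        ds = df[df["parameter"] == "double_support_pct"]["value"].to_numpy()
        assert np.all((ds > 5.0) & (ds < 45.0))
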