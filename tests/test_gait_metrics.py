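"""Spatiotemporal metrics, cycle normalisation, aggregation, Welch test."""

import numpy as np
import pytest

import gaitloop as gl
from gaitloop.gait_events import GaitCycle, PhaseLabel
from gaitloop.gait_metrics import (
    AnimalSummary,
    aggregate_group,
    average_normalized_cycles,
    duty_factor,
    joint_rom,
    normalize_cycle,
    percent_change,
    stick_diagram,
    summarize_animal,
    welch_t_from_summary,
)


class TestDutyFactor:
    def test_simple_ratio(self):
        assert duty_factor(200, 300) == pytest.approx(66.667, abs=1e-3)

    def test_ratio_of_group_mean_durations(self):
        # direct ratio of group mean stance/cycle durations; note this is
        # a different statistic from the mean of per-animal duty factors
        assert duty_factor(298.72, 438.87) == pytest.approx(68.07, abs=0.01)

    def test_stance_equal_cycle_rejected(self):
        with pytest.raises(ValueError):
            duty_factor(300, 300)

    def test_complementarity(self):
        stance, swing = 287.3, 151.9
        cycle = stance + swing
        assert duty_factor(stance, cycle) + duty_factor(swing, cycle) == pytest.approx(100.0)


class TestJointRom:
    def test_constant_trace(self):
        assert joint_rom([90.0] * 10) == (90.0, 90.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            joint_rom([])


class TestNormalizeCycle:
    def _cycle(self, n):
        return GaitCycle(0, max(1, n * 2 // 3), n, 1.0, 1.0, 2.0, True)

    def test_constant_input(self):
        out = normalize_cycle(np.full(50, 90.0), self._cycle(49))
        assert out.grid[0] == 0.0 and out.grid[-1] == 100.0
        np.testing.assert_allclose(out.trace, 90.0)

    def test_linear_ramp_midpoint(self):
        out = normalize_cycle(np.linspace(0, 100, 101), self._cycle(100))
        assert out.trace[50] == pytest.approx(50.0)

    def test_sinusoid_extremum_preserved(self):
        # analytic oracle: peak of 90 + 20 sin at a quarter period
        t = np.linspace(0, 2 * np.pi, 120)
        trace = 90 + 20 * np.sin(t)
        out = normalize_cycle(trace, self._cycle(119))
        assert out.trace.max() == pytest.approx(110.0, abs=0.5)

    def test_qc_fail_rejected(self):
        bad = GaitCycle(0, 5, 10, 1, 1, 2, False)
        with pytest.raises(ValueError):
            normalize_cycle(np.arange(11.0), bad)

    def test_pointwise_average(self):
        a = normalize_cycle(np.full(20, 80.0), self._cycle(19))
        b = normalize_cycle(np.full(20, 100.0), self._cycle(19))
        avg = average_normalized_cycles([a, b])
        np.testing.assert_allclose(avg.trace, 90.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,test,expected",
        [
            (298.72, 200.15, 33),  # stance duration reduction after injury
            (438.87, 295.36, 33),  # cycle duration reduction
            (140.14, 95.95, 32),  # swing duration reduction
        ],
    )
    def test_group_mean_reductions(self, ref, test, expected):
        assert round(percent_change(ref, test)) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0, 10)


class TestWelch:
    def test_against_closed_form_oracle(self):
        # independent closed-form oracle for the sham/SCI stance summaries
        m1, s1, n1, m2, s2, n2 = 298.72, 30.76, 3, 200.15, 30.50, 3
        se1, se2 = s1**2 / n1, s2**2 / n2
        t_oracle = (m1 - m2) / np.sqrt(se1 + se2)
        df_oracle = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
        t, df, p = welch_t_from_summary(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(t_oracle, abs=1e-9)
        assert df == pytest.approx(df_oracle, abs=1e-9)
        assert t == pytest.approx(3.94, abs=0.01)
        assert df == pytest.approx(4.0, abs=0.01)
        assert 0 < p < 1

    def test_identical_groups(self):
        t, df, p = welch_t_from_summary(10, 2, 5, 10, 2, 5)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_satterthwaite_limit_equal_variances(self):
        _, df, _ = welch_t_from_summary(12, 3, 7, 10, 3, 7)
        assert df == pytest.approx(12.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(5, 0, 3, 5, 0, 3)


class TestAggregation:
    def _summary(self, i, stance=300.0, cycle=440.0):
        return AnimalSummary(f"a{i}", 100, cycle, stance, cycle - stance,
                             100 * stance / cycle)

    def test_identical_animals_sd_zero(self):
        stats = aggregate_group("sham", [self._summary(i) for i in range(3)])
        assert stats.sd["stance_ms"] == 0.0
        assert stats.n == 3

    def test_single_animal_sd_flagged_zero(self):
        stats = aggregate_group("sham", [self._summary(0)])
        assert stats.mean["stance_ms"] == 300.0
        assert stats.sd["stance_ms"] == 0.0

    def test_only_qc_cycles_counted(self):
        cycles = [
            GaitCycle(0, 67, 100, 429.5, 211.5, 641.0, True),
            GaitCycle(100, 167, 200, 429.5, 211.5, 641.0, False),
            GaitCycle(200, 267, 300, 429.5, 211.5, 641.0, True),
        ]
        s = summarize_animal("a", cycles)
        assert s.n_cycles_used == 2

    def test_duty_factor_modes_differ(self):
        cycles = [
            GaitCycle(0, 50, 100, 320.5, 320.5, 641.0, True),
            GaitCycle(100, 180, 200, 512.8, 128.2, 641.0, True),
        ]
        mor = summarize_animal("a", cycles, duty_mode="mean_of_ratios")
        rom_ = summarize_animal("a", cycles, duty_mode="ratio_of_means")
        assert mor.duty_factor_pct == pytest.approx((50.0 + 80.0) / 2)
        assert rom_.duty_factor_pct == pytest.approx(65.0)


class TestStickDiagram:
    def _session_and_labels(self, labels):
        rng = np.random.default_rng(0)
        frames = [
            gl.LandmarkFrame(i, rng.uniform(0, 100, (5, 2)), np.ones(5))
            for i in range(len(labels))
        ]
        return gl.Session(frames, fps=156.0), labels

    def test_four_segments_per_frame(self):
        session, labels = self._session_and_labels([PhaseLabel.STANCE])
        df = stick_diagram(session, labels)
        assert len(df) == 4

    def test_phase_colors(self):
        session, labels = self._session_and_labels(
            [PhaseLabel.STANCE, PhaseLabel.SWING]
        )
        df = stick_diagram(session, labels)
        assert set(df[df.phase == "stance"].color) == {"black"}
        assert set(df[df.phase == "swing"].color) == {"red"}

    def test_abnormal_frames_omitted(self):
        session, labels = self._session_and_labels(
            [PhaseLabel.STANCE, PhaseLabel.ABNORMAL, PhaseLabel.SWING]
        )
        df = stick_diagram(session, labels)
        assert set(df.frame) == {0, 2}


def test_sham_ankle_template_extrema_recovered(noise_free_sham):
    """The pipeline must recover the sham ankle excursion keypoints."""
    session, _ = noise_free_sham
    samples, labels, transitions, cycles = gl.label_session(session)
    ankle = np.array([s.ankle_deg for s in samples])
    traces = [normalize_cycle(ankle, c) for c in cycles if c.qc_pass]
    avg = average_normalized_cycles(traces)
    lo, hi, _ = joint_rom(avg.trace)
    assert hi == pytest.approx(118.30, abs=0.5)
    assert lo == pytest.approx(74.37, abs=0.5)


def test_sci_ankle_template_minimum_recovered():
    """Injured ankle trace reaches its depressed minimum."""
    cfg = gl.GaitGenConfig(group="sci", duration_s=15.0, seed=7, noise_deg=0.0,
                           abnormal_rate_per_s=0.0)
    session, _ = gl.generate_session(cfg)
    samples, labels, transitions, cycles = gl.label_session(session)
    ankle = np.array([s.ankle_deg for s in samples])
    traces = [normalize_cycle(ankle, c) for c in cycles if c.qc_pass]
    avg = average_normalized_cycles(traces)
    lo, hi, _ = joint_rom(avg.trace)
    assert lo == pytest.approx(42.32, abs=0.5)
    assert hi == pytest.approx(76.42, abs=0.5)
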