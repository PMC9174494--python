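"""CORC estimation (both methods), labeling and the apnea summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neoapnea as na
from neoapnea.apnea import CORCError, atf_at_threshold

from conftest import bimodal_durations, make_series


class TestPoincarePoints:
    def test_consecutive_pairs(self):
        pts = na.poincare_points(make_series([0.4, 0.4, 2.5]))
        assert pts.tolist() == [[0.4, 0.4], [0.4, 2.5]]

    def test_constant_series_on_diagonal(self):
        pts = na.poincare_points(make_series([0.4] * 10))
        assert np.all(pts[:, 0] == pts[:, 1])

    def test_isolated_long_cycle_gives_two_off_diagonal_points(self):
        d = [0.4] * 5 + [3.0] + [0.4] * 5
        pts = na.poincare_points(make_series(d))
        off = np.abs(pts[:, 0] - pts[:, 1]) > 0.5
        assert off.sum() == 2

    def test_fewer_than_two_cycles_rejected(self):
        with pytest.raises(ValueError):
            na.poincare_points(make_series([0.4]))


class TestCorcPoincare:
    def test_pure_gaussian_boundary(self):
        rng = np.random.default_rng(1)
        s = make_series(rng.normal(0.4, 0.02, 1000))
        est = na.corc_poincare(s)
        # repetitive mean + 4 SD of N(0.4, 0.02) ~ 0.48, and no apneic cycle
        assert est.corc == pytest.approx(0.48, abs=0.02)
        assert (na.label_cycles(s, est) == "apneic").sum() == 0

    def test_bimodal_boundary_between_populations(self):
        rng = np.random.default_rng(2)
        d, apneic = bimodal_durations(rng)
        s = make_series(d)
        est = na.corc_poincare(s)
        assert d[~apneic].max() * 0.95 < est.corc < d[apneic].min()

    def test_too_few_cycles_rejected(self):
        with pytest.raises(CORCError):
            na.corc_poincare(make_series([0.4, 0.4]))


class TestCorcLogThd:
    def test_agrees_with_poincare_on_apnea_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d, _ = bimodal_durations(rng)
            s = make_series(d)
            set_p = set(np.flatnonzero(
                na.label_cycles(s, na.corc_poincare(s)) == "apneic"))
            set_l = set(np.flatnonzero(
                na.label_cycles(s, na.corc_logthd(s)) == "apneic"))
            assert len(set_p ^ set_l) / max(len(set_p), 1) < 0.05

    def test_corc_lies_between_populations(self):
        rng = np.random.default_rng(4)
        d, apneic = bimodal_durations(rng)
        s = make_series(d)
        est = na.corc_logthd(s)
        assert d[~apneic].max() * 0.9 < est.corc < d[apneic].min()

    def test_no_long_cycles_gives_flagged_floor(self):
        rng = np.random.default_rng(5)
        s = make_series(rng.normal(0.4, 0.02, 500))
        est = na.corc_logthd(s)
        assert "flagged" in est.diagnostics
        assert est.corc == pytest.approx(
            est.diagnostics["grid_floor_s"], rel=1e-9)

    def test_atf_monotone_on_example(self):
        rng = np.random.default_rng(6)
        d, _ = bimodal_durations(rng)
        s = make_series(d)
        assert atf_at_threshold(s, 1.0) >= atf_at_threshold(s, 2.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=200),
       st.lists(st.floats(0.05, 12.0), min_size=2, max_size=20))
def test_atf_is_non_increasing_in_threshold(durations, grid):
    s = make_series(durations)
    atf = atf_at_threshold(s, np.sort(grid))
    assert np.all(np.diff(atf) <= 1e-12)
    assert np.all((0.0 <= atf) & (atf <= 1.0))


class TestLabelsAndSummary:
    def test_single_long_cycle_labeled(self):
        d = [0.4] * 5 + [3.0] + [0.4] * 5
        s = make_series(d)
        est = na.CORCEstimate(corc=1.0, method="poincare")
        labels = na.label_cycles(s, est)
        assert list(np.flatnonzero(labels == "apneic")) == [5]

    def test_label_conservation(self):
        rng = np.random.default_rng(7)
        d, _ = bimodal_durations(rng)
        s = make_series(d)
        labels = na.label_cycles(s, na.corc_poincare(s))
        assert ((labels == "apneic") | (labels == "repetitive")).all()

    def test_summary_arithmetic(self):
        d = [0.4] * 5 + [3.0] + [0.4] * 5
        s = make_series(d, total_duration=7.0)
        summ = na.apnea_summary(s, na.CORCEstimate(corc=1.0, method="poincare"))
        assert summ.atf == pytest.approx(3.0 / 7.0)
        assert summ.n_apneas == 1
        assert summ.n_consecutive_flagged == 0

    def test_zero_apneic(self):
        s = make_series([0.4] * 40)
        summ = na.apnea_summary(s, na.CORCEstimate(corc=1.0, method="poincare"))
        assert summ.atf == 0.0 and summ.n_apneas == 0

    def test_consecutive_apneas_flagged(self):
        s = make_series([0.4] * 10 + [3.0, 3.0] + [0.4] * 10)
        summ = na.apnea_summary(s, na.CORCEstimate(corc=1.0, method="poincare"))
        assert summ.n_apneas == 2
        assert summ.n_consecutive_flagged == 1


def test_labeling_recovers_simulated_apneas(mutant_recording):
    """On a mutant recording the labeled set matches ground truth."""
    trace, _, truth = mutant_recording
    series = na.segment_breaths(trace, t_start=1.0, t_end=299.0)
    est = na.corc_poincare(series)
    apneic_onsets = series.onsets[na.label_cycles(series, est) == "apneic"]
    tru = truth.cycles[truth.cycles.kind.isin(["breath_hold", "central_like"])]
    tru_onsets = tru.onset_s.to_numpy()
    tru_onsets = tru_onsets[(tru_onsets > 1.5) & (tru_onsets < 295.0)]
    d = np.abs(apneic_onsets[:, None] - tru_onsets[None, :])
    recall = (d.min(axis=0) < 0.1).mean()
    assert recall >= 0.95
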