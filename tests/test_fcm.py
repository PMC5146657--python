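"""G0/G1 peak detection, ratio arithmetic, ploidy calling and replicate QC."""

from __future__ import annotations

import numpy as np
import pytest

from salixploidy import datasets
from salixploidy.fcm import (EventStream, FCMError, PeakConfig, PeakEstimate,
                             QCFlag, aggregate_replicates, call_ploidy,
                             compute_ratio, find_g0g1_peak, read_events,
                             round_ratio, write_events)
from salixploidy.synthetic import FCMSimConfig, simulate_fcm_stream


def make_stream(rng, mu=10739.0, cv=4.5, n=10000, debris=0.05, g2=0.0,
                sample_id="t"):
    cfg = FCMSimConfig(unit_position=mu, cv_percent=cv, n_events=n,
                       debris_fraction=debris, g2_fraction=g2)
    return simulate_fcm_stream(cfg, ploidy=2, reference_ploidy=2, rng=rng,
                               sample_id=sample_id)


class TestFindG0G1Peak:
    def test_recovers_peak_of_noisy_stream(self, rng):
        est = find_g0g1_peak(make_stream(rng))
        assert abs(est.mean_position - 10739) / 10739 < 0.01
        assert 3.5 <= est.cv_percent <= 5.5
        assert est.gate[0] < est.mean_position < est.gate[1]
        assert est.n_gated <= 10000

    def test_lowest_major_peak_wins_over_g2(self, rng):
        # 4:1 G1-to-G2 mass: the doubled-position peak must not be picked
        stream = make_stream(rng, debris=0.0, g2=0.2)
        est = find_g0g1_peak(stream)
        assert abs(est.mean_position - 10739) / 10739 < 0.02

    def test_degenerate_delta_cluster(self):
        stream = EventStream("d", 0, np.full(6000, 10739.0))
        est = find_g0g1_peak(stream)
        assert est.mean_position == pytest.approx(10739.0)
        assert est.cv_percent == pytest.approx(0.0, abs=1e-9)

    def test_scale_equivariance(self, rng):
        base_events = make_stream(rng).events
        base = find_g0g1_peak(EventStream("b", 0, base_events))
        for c in (0.5, 2.0, 10.0):
            scaled = find_g0g1_peak(EventStream("s", 0, c * base_events))
            assert scaled.mean_position == pytest.approx(
                c * base.mean_position, rel=5e-3)

    def test_too_few_events_is_an_error_unless_overridden(self, rng):
        stream = make_stream(rng, n=200)
        with pytest.raises(FCMError, match="too_few_events"):
            find_g0g1_peak(stream)
        est = find_g0g1_peak(stream, PeakConfig(allow_few_events=True))
        assert est.mean_position > 0

    def test_flat_stream_has_no_peak(self):
        stream = EventStream("flat", 0, np.linspace(1, 20000, 6000))
        with pytest.raises(FCMError, match="no major"):
            find_g0g1_peak(stream)

    def test_negative_or_empty_stream_rejected(self):
        with pytest.raises(FCMError):
            EventStream("x", 0, np.array([]))
        with pytest.raises(FCMError):
            EventStream("x", 0, np.array([1.0, -2.0]))


class TestComputeRatio:
    @pytest.mark.parametrize(
        "m_sample,expected",
        [(15753, 1.47), (10739, 1.00), (22557, 2.10),
         (22182, 2.07), (10686, 1.00), (9712, 0.90)],
    )
    def test_published_spot_values(self, m_sample, expected):
        assert compute_ratio(m_sample, 10739) == expected

    def test_all_survey_ratios_reproduced(self):
        survey = datasets.load_fcm_survey()
        for _, row in survey.iterrows():
            assert compute_ratio(row.g0g1_mean, datasets.REFERENCE_G0G1) == \
                pytest.approx(row.ratio, abs=1e-12), row.accessions

    def test_half_away_from_zero_rounding(self):
        assert round_ratio(2.0650000) == 2.07
        assert round_ratio(0.995) == 1.00
        assert round_ratio(1.004999) == 1.00

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(FCMError):
            compute_ratio(0, 10739)
        with pytest.raises(FCMError):
            compute_ratio(10739, -1)


class TestCallPloidy:
    @pytest.mark.parametrize(
        "ratio,expected_ploidy,expected_estimate",
        [(1.47, 3, 2.94), (0.90, 2, 1.80), (1.00, 2, 2.00), (2.10, 4, 4.20)],
    )
    def test_ratio_to_ploidy(self, ratio, expected_ploidy, expected_estimate):
        call = call_ploidy(ratio, reference_ploidy=2)
        assert call.ploidy == expected_ploidy
        assert call.ploidy_estimate == pytest.approx(expected_estimate)
        assert call.qc_pass and not call.flags

    def test_all_survey_ploidy_labels_reproduced(self):
        survey = datasets.load_fcm_survey()
        for _, row in survey.iterrows():
            call = call_ploidy(compute_ratio(row.g0g1_mean, datasets.REFERENCE_G0G1),
                               reference_ploidy=datasets.REFERENCE_PLOIDY)
            assert f"{call.ploidy}x" == row.ploidy_level
            assert QCFlag.ambiguous_ploidy not in call.flags

    def test_midpoint_estimate_is_flagged_ambiguous(self):
        call = call_ploidy(1.25, reference_ploidy=2, tolerance=0.3)
        assert call.ploidy_estimate == pytest.approx(2.5)
        assert QCFlag.ambiguous_ploidy in call.flags
        assert not call.qc_pass

    def test_invalid_inputs(self):
        with pytest.raises(FCMError):
            call_ploidy(0.0)
        with pytest.raises(FCMError):
            call_ploidy(1.0, reference_ploidy=0)


class TestAggregateReplicates:
    def _estimate(self, mean, cv=4.0, n=5000):
        sd = cv / 100 * mean
        return PeakEstimate(mean_position=mean, sd=sd, cv_percent=cv,
                            n_gated=n, gate=(mean - 2 * sd, mean + 2 * sd))

    def test_pooled_mean_is_unweighted(self):
        pooled, ok, flags = aggregate_replicates(
            [self._estimate(m) for m in (10700, 10739, 10778)])
        assert pooled.mean_position == pytest.approx(10739)
        assert ok and not flags

    def test_high_cv_replicate_fails_qc_but_stays_in_pool(self):
        pooled, ok, flags = aggregate_replicates(
            [self._estimate(10700), self._estimate(10780, cv=5.3)])
        assert not ok
        assert QCFlag.cv_above_threshold in flags
        assert pooled.mean_position == pytest.approx(10740)

    def test_simulated_tetraploid_ratio_near_two(self):
        cfg = FCMSimConfig(cv_percent=4.0, n_events=5000)
        rng = np.random.default_rng(99)
        def pooled_mean(ploidy):
            ests = [find_g0g1_peak(simulate_fcm_stream(cfg, ploidy, rng=rng))
                    for _ in range(3)]
            return aggregate_replicates(ests, min_events=1000)[0].mean_position
        ratio = pooled_mean(4) / pooled_mean(2)
        assert abs(ratio - 2.0) < 0.05

    def test_empty_list_is_an_error(self):
        with pytest.raises(FCMError):
            aggregate_replicates([])


class TestReadEvents:
    def test_reads_simple_csv(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("100\n200\n300\n")
        stream = read_events(path, sample_id="S1", replicate=2)
        assert stream.events.tolist() == [100.0, 200.0, 300.0]
        assert stream.sample_id == "S1" and stream.replicate == 2

    def test_negative_value_names_the_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("100\n-5\n")
        with pytest.raises(FCMError, match="line 2"):
            read_events(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FCMError, match="no events"):
            read_events(path)

    def test_round_trip_preserves_values(self, tmp_path, rng):
        stream = EventStream("rt", 0, rng.uniform(1, 2e4, size=500))
        path = tmp_path / "rt.csv"
        write_events(stream, path)
        back = read_events(path, sample_id="rt")
        np.testing.assert_allclose(back.events, stream.events, rtol=1e-9)
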