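"""Cycle segmentation, QC, inhibition calling, aggregation, dose estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungsurf.errors import (
    DoseNotEstimableError,
    InsufficientDataError,
    NoCallError,
    ParameterError,
    SegmentationError,
)
from lungsurf.simulate import CyclingProtocol, FilmModelParams, simulate_trace
from lungsurf.traces import (
    AssayCriteria,
    CycleSummary,
    InhibitionCall,
    SurfaceTensionTrace,
    analyze_trace,
    classify_chemical,
    detect_inhibition,
    estimate_inhibitory_dose,
    qc_baseline,
    segment_cycles,
    summarize_cycles,
)


def make_summaries(minima, compression=0.25):
    return [
        CycleSummary(
            cycle_index=i + 1,
            min_surface_tension=float(m),
            time_at_min=1.5 + 3.0 * i,
            area_at_min=37.5,
            max_area=50.0,
            min_area=50.0 * (1 - compression),
        )
        for i, m in enumerate(minima)
    ]


def brute_force_inhibition(minima, threshold=10.0, run_length=3):
    """Oracle: scan every window of >= run_length consecutive minima."""
    for start in range(len(minima) - run_length + 1):
        if all(m >= threshold for m in minima[start : start + run_length]):
            return True, start + 1
    return False, None


class TestSegmentation:
    def test_area_jitter_does_not_change_cycle_count(self):
        protocol = CyclingProtocol(duration=60.0)
        trace = simulate_trace(protocol, FilmModelParams(noise_sd=0.0))
        n_clean = len(segment_cycles(trace))
        rng = np.random.default_rng(11)
        jittered = SurfaceTensionTrace(
            time=trace.time,
            surface_tension=trace.surface_tension,
            surface_area=trace.surface_area + rng.normal(0, 1e-3 * protocol.baseline_area, len(trace)),
            frame_rate=trace.frame_rate,
        )
        assert len(segment_cycles(jittered)) == n_clean == 20

    def test_constant_area_has_no_cycles(self):
        trace = SurfaceTensionTrace(
            time=np.arange(100) / 10.0,
            surface_tension=np.full(100, 20.0),
            surface_area=np.full(100, 50.0),
        )
        with pytest.raises(SegmentationError):
            segment_cycles(trace)

    def test_ranges_are_contiguous_half_open(self, functional_trace):
        ranges = segment_cycles(functional_trace)
        for (s1, e1), (s2, _) in zip(ranges, ranges[1:]):
            assert e1 == s2
            assert e1 > s1


class TestCycleSummaries:
    def test_minimum_matches_exhaustive_scan(self):
        film = FilmModelParams(deposition_flux=25.0, d50=30.0, noise_sd=0.4, seed=3)
        trace = simulate_trace(CyclingProtocol(duration=90.0), film)
        ranges = segment_cycles(trace)
        for cyc, (start, stop) in zip(summarize_cycles(trace, ranges), ranges):
            assert cyc.min_surface_tension == trace.surface_tension[start:stop].min()
            assert cyc.min_area <= cyc.area_at_min <= cyc.max_area
            assert 0 <= cyc.compression_ratio < 1

    def test_single_sample_range_rejected(self, functional_trace):
        with pytest.raises(InsufficientDataError):
            summarize_cycles(functional_trace, [(0, 1)])


class TestBaselineQC:
    def test_good_baseline_passes(self):
        qc = qc_baseline(make_summaries([1.5, 2.0, 1.8, 2.1, 1.9]))
        assert qc.passed and qc.reasons == ()

    @pytest.mark.parametrize(
        "minima, compression, should_pass",
        [
            ([5.0, 5.0, 5.0, 5.0, 5.0], 0.25, False),  # exactly at 5 mN/m: strict
            ([4.99, 4.99, 4.99, 4.99, 4.99], 0.25, True),
            ([2.0, 2.0, 2.0, 2.0, 2.0], 0.30, False),  # exactly 30%: strict
            ([2.0, 2.0, 2.0, 2.0, 2.0], 0.299, True),
        ],
    )
    def test_thresholds_are_strict(self, minima, compression, should_pass):
        qc = qc_baseline(make_summaries(minima, compression=compression))
        assert qc.passed is should_pass

    def test_too_few_cycles_rejected(self):
        with pytest.raises(InsufficientDataError):
            qc_baseline(make_summaries([2.0, 2.0]))

    def test_baseline_span_configurable(self):
        # over-compressed cycles after the third are outside a 3-cycle baseline
        summaries = make_summaries([2.0] * 3, compression=0.25) + make_summaries(
            [2.0] * 2, compression=0.45
        )
        assert qc_baseline(summaries, AssayCriteria(n_baseline_cycles=3)).passed
        assert not qc_baseline(summaries, AssayCriteria(n_baseline_cycles=5)).passed


class TestInhibitionDetection:
    @pytest.mark.parametrize(
        "minima, inhibited, onset",
        [
            ([2, 3, 2, 4, 3], False, None),
            ([3, 11, 12, 10.5, 4], True, 2),
            ([3, 11, 12, 4, 10, 11], False, None),  # longest run is 2
            ([10.0, 10.0, 10.0], True, 1),  # threshold inclusive
            ([9.999, 10.0, 10.0, 10.0], True, 2),
        ],
    )
    def test_rule_examples(self, minima, inhibited, onset):
        call = detect_inhibition(make_summaries(minima))
        assert call.inhibited is inhibited
        assert call.onset_cycle == onset

    def test_too_few_cycles_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_inhibition(make_summaries([12.0, 12.0]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        minima=st.lists(
            st.one_of(
                st.floats(0.5, 40.0, allow_nan=False),
                st.just(10.0),  # force boundary hits
            ),
            min_size=3,
            max_size=40,
        )
    )
    def test_equivalent_to_brute_force_window_scan(self, minima):
        call = detect_inhibition(make_summaries(minima))
        expected, onset = brute_force_inhibition(minima)
        assert call.inhibited == expected
        assert call.onset_cycle == onset

    def test_onset_time_is_minimum_gamma_sample_time(self, inhibited_trace):
        trace, film, protocol = inhibited_trace
        _, qc, call = analyze_trace(trace)
        assert qc.passed and call.inhibited
        # onset within one cycle of the analytic floor crossing
        assert abs(call.onset_time - film.floor_crossing_time(10.0)) <= protocol.cycle_period


class TestChemicalClassification:
    def test_unanimous_positive(self):
        calls = [InhibitionCall(True, 4, 10.5)] * 3
        out = classify_chemical(calls)
        assert out["inhibitory"] and out["agreement"] == 1.0 and not out["discordant"]

    def test_unanimous_negative(self):
        out = classify_chemical([InhibitionCall(False)] * 4)
        assert not out["inhibitory"] and out["agreement"] == 0.0

    def test_split_decides_by_majority_rule_and_flags_discordance(self):
        calls = [InhibitionCall(True, 2, 5.0), InhibitionCall(False)] * 2
        out = classify_chemical(calls)
        assert out["inhibitory"] and out["discordant"]

    def test_qc_failed_replicates_are_excluded(self):
        calls = [None, InhibitionCall(False), InhibitionCall(False), InhibitionCall(False)]
        out = classify_chemical(calls)
        assert out["n_replicates"] == 3 and not out["inhibitory"]

    def test_no_passing_replicates_is_an_error(self):
        with pytest.raises(NoCallError):
            classify_chemical([None, None])

    def test_replicate_count_outside_protocol_warns(self):
        with pytest.warns(UserWarning):
            classify_chemical([InhibitionCall(False)] * 2)


class TestInhibitoryDose:
    def test_dose_is_flux_times_onset_time(self):
        call = InhibitionCall(True, onset_cycle=100, onset_time=300.0)  # 5 min
        out = estimate_inhibitory_dose(10.0, call, mean_drop_area=50.0)
        assert out["dose_per_area_ng_cm2"] == pytest.approx(50.0)
        assert out["total_mass_ng"] == pytest.approx(50.0 * 0.50)

    def test_volatile_compound_not_estimable(self):
        call = InhibitionCall(True, onset_cycle=5, onset_time=15.0)
        out = estimate_inhibitory_dose(10.0, call, 50.0, volatile=True)
        assert not out["estimable"] and "volatile" in out["reason"]

    def test_negative_call_has_no_dose(self):
        with pytest.raises(DoseNotEstimableError):
            estimate_inhibitory_dose(10.0, InhibitionCall(False), 50.0)

    def test_zero_flux_rejected(self):
        call = InhibitionCall(True, onset_cycle=5, onset_time=15.0)
        with pytest.raises(ParameterError):
            estimate_inhibitory_dose(0.0, call, 50.0)


class TestEndToEnd:
    def test_functional_trace_never_called_inhibited(self, functional_trace):
        _, qc, call = analyze_trace(functional_trace)
        assert qc.passed and not call.inhibited

    def test_noisy_functional_trace_never_called_inhibited(self):
        for seed in range(5):
            trace = simulate_trace(CyclingProtocol(duration=120.0), FilmModelParams(noise_sd=0.3, seed=seed))
            _, qc, call = analyze_trace(trace)
            assert qc.passed and not call.inhibited

    def test_saturating_dose_always_called_inhibited(self, inhibited_trace):
        trace, film, _ = inhibited_trace
        _, qc, call = analyze_trace(trace)
        assert qc.passed and call.inhibited
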