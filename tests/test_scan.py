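"""Perturbation scan: smoothing, profiles, element calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgscan.engines import StubEngine
from dgscan.fixtures import generate_fixture_utr
from dgscan.scan import (
    PerturbationProfile,
    call_elements,
    perturbation_profile,
    scale_signal,
    smooth_profile,
)
from dgscan.sequences import UtrSequence


def make_profile(raw, window=3, seq_id="t"):
    raw = np.asarray(raw, dtype=float)
    signal = smooth_profile(raw, window)
    return PerturbationProfile(
        seq_id=seq_id,
        wild_type_dg=0.0,
        raw=raw,
        window=window,
        signal=signal,
        signal_scaled=scale_signal(signal),
    )


class TestSmoothProfile:
    @pytest.mark.parametrize(
        "raw,window,expected",
        [
            ([1, 1, 1, 1, 1, 1], 6, [1.0]),
            ([0, 0, 0, 6, 0, 0, 0], 3, [0, 2, 2, 2, 0]),
            ([3, 1], 2, [2.0]),
        ],
    )
    def test_hand_computed_means(self, raw, window, expected):
        assert smooth_profile(raw, window) == pytest.approx(expected)

    def test_empty_and_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile([], 1)
        with pytest.raises(ValueError):
            smooth_profile([1, 2], 3)

    @given(
        st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=40),
        st.data(),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_direct_window_means(self, raw, data):
        window = data.draw(st.integers(1, len(raw)))
        out = smooth_profile(raw, window)
        assert len(out) == len(raw) - window + 1
        for j, val in enumerate(out):
            assert val == pytest.approx(np.mean(raw[j : j + window]))


class TestScaleSignal:
    def test_minmax_spans_0_to_100(self):
        scaled = scale_signal(np.array([1.0, 3.0, 2.0]))
        assert scaled.min() == 0.0 and scaled.max() == 100.0

    def test_constant_signal_scales_to_zero(self):
        assert scale_signal(np.full(5, 7.0)).tolist() == [0.0] * 5

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            scale_signal(np.ones(3), "log")


class TestPerturbationProfile:
    def test_stub_engine_constant_raw_gives_constant_signal(self):
        # engine-independent plumbing: constant dG difference c at every mutant
        seq = UtrSequence("s", "AUGCAUGCAU")
        engine = StubEngine({seq.residues: -10.0}, default=-7.0)
        profile = perturbation_profile(seq, engine, window=4)
        assert profile.wild_type_dg == -10.0
        assert profile.raw == pytest.approx(np.full(10, 3.0))
        assert profile.signal == pytest.approx(np.full(7, 3.0))
        assert profile.signal_scaled.tolist() == [0.0] * 7  # constant convention

    def test_stub_engine_hand_computed_raw(self):
        # wild type AA: mutants at pos1 are CA, GA, UA; at pos2 AC, AG, AU
        table = {"AA": 0.0, "CA": -3.0, "GA": 0.0, "UA": 0.0,
                 "AC": -1.0, "AG": -2.0, "AU": -3.0}
        profile = perturbation_profile(
            UtrSequence("s", "AA"), StubEngine(table), window=1
        )
        assert profile.raw == pytest.approx([1.0, 2.0])

    def test_fold_count_capped_by_caching(self):
        seq = UtrSequence("s", "AUGC")
        engine = StubEngine()
        perturbation_profile(seq, engine, window=2)
        assert engine.calls <= 3 * len(seq) + 1

    def test_polyA_scans_flat_under_no_lone_pair_model(self, nn_engine):
        # no single substitution of poly-A can create a stackable helix
        profile = perturbation_profile(UtrSequence("pa", "A" * 30), nn_engine)
        assert profile.raw.max() == 0.0
        assert profile.signal.max() == 0.0

    def test_scan_is_deterministic(self, nn_engine):
        seq, _ = generate_fixture_utr(length=40, stem_len=6, loop_len=4, seed=2)
        p1 = perturbation_profile(seq, nn_engine)
        p2 = perturbation_profile(seq, nn_engine)
        assert np.array_equal(p1.raw, p2.raw)
        assert np.array_equal(p1.signal, p2.signal)

    def test_window_larger_than_sequence_rejected(self, nn_engine):
        with pytest.raises(ValueError):
            perturbation_profile(UtrSequence("s", "AUGC"), nn_engine, window=5)


class TestCallElements:
    def test_single_maximum_region_yields_one_element_containing_argmax(self):
        raw = np.zeros(30)
        raw[10:16] = 5.0
        profile = make_profile(raw, window=3)
        elements = call_elements(profile, max_elements=3)
        assert len(elements) == 1
        argmax_pos = int(np.argmax(profile.signal)) + 1
        assert elements[0].start <= argmax_pos <= elements[0].end
        assert elements[0].rank_label == "e1"

    def test_all_zero_signal_returns_empty(self):
        assert call_elements(make_profile(np.zeros(20))) == []

    def test_rank_labels_descend_with_peak_signal(self):
        raw = np.zeros(60)
        raw[5:10] = 9.0
        raw[30:35] = 4.0
        raw[50:55] = 6.0
        elements = call_elements(make_profile(raw), threshold_percentile=80, merge_gap=2)
        labels = [e.rank_label for e in elements]
        peaks = [e.peak_signal for e in elements]
        assert labels == [f"e{i}" for i in range(1, len(elements) + 1)]
        assert peaks == sorted(peaks, reverse=True)

    def test_elements_never_overlap(self):
        raw = np.zeros(50)
        raw[10:14] = 3.0
        raw[18:22] = 5.0
        elements = call_elements(make_profile(raw), threshold_percentile=70, merge_gap=0)
        for i in range(len(elements)):
            for j in range(i + 1, len(elements)):
                assert not elements[i].overlaps(elements[j])

    def test_boundary_windows_meet_threshold(self):
        # element ends are anchored on above-threshold windows
        raw = np.zeros(50)
        raw[12:20] = 4.0
        raw[33:37] = 2.5
        profile = make_profile(raw)
        threshold = np.percentile(profile.signal, 90)
        for e in call_elements(profile, threshold_percentile=90, merge_gap=0):
            first_window = profile.signal[e.start - 1]
            last_window = profile.signal[e.end - profile.window]
            assert first_window >= threshold
            assert last_window >= threshold

    def test_max_elements_truncates(self):
        raw = np.zeros(80)
        for start in (5, 25, 45, 65):
            raw[start : start + 5] = 5.0 + start / 100.0
        elements = call_elements(make_profile(raw), threshold_percentile=85,
                                 max_elements=2, merge_gap=0)
        assert len(elements) == 2


class TestEndToEndSmoke:
    def test_200nt_pairmax_pipeline_completes_consistently(self):
        """fixture -> scan -> elements -> design on a 200-nt UTR (PAIRMAX)."""
        from dgscan.energy import pairmax_model
        from dgscan.engines import BuiltinEngine
        from dgscan.oligo import design_oligos

        engine = BuiltinEngine(pairmax_model())
        seq, truth = generate_fixture_utr(length=200, stem_len=10, loop_len=6, seed=3)
        profile = perturbation_profile(seq, engine)
        assert profile.length == 200
        elements = call_elements(profile)
        assert elements
        for e in elements:
            assert 1 <= e.start <= e.end <= 200
        oligos = design_oligos(seq, elements[0],
                               categories=("SENSE", "ANTISENSE", "SCRAMBLED"),
                               scramble_seed=5)
        assert len(oligos) == 3
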