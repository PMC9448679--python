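"""Burst detection, coincidence, monomer brightness and event analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligofret.bursts import (
    EmptyTraceError,
    NoEventsError,
    NoMonomerEventsError,
    PhotonTrace,
    analyze_events,
    detect_events,
    fraction_of_coincidence,
    monomer_brightness,
    size_efficiency_table,
)
from oligofret.core import InstrumentParams
from oligofret.synthetic import (
    ScenarioPreset,
    SpeciesSpec,
    load_preset,
    simulate_burst_stream,
)


def _trace(donor, acceptor):
    return PhotonTrace(
        bin_width=0.001,
        donor_counts=np.asarray(donor),
        acceptor_counts=np.asarray(acceptor),
    )


class TestDetectEvents:
    def test_all_subthreshold_yields_no_events(self):
        ev = detect_events(_trace([3, 9, 5, 0], [9, 9, 2, 1]))
        assert ev.n_donor_events == 0
        with pytest.raises(NoEventsError):
            fraction_of_coincidence(ev)

    def test_single_bin_coincident_event(self):
        ev = detect_events(_trace([0, 12, 0], [0, 11, 0]))
        assert ev.n_donor_events == 1
        e = ev.events[0]
        assert e.coincident
        assert e.intensities.donor_raw == 12
        assert e.intensities.acceptor_raw == 11
        assert (e.start_bin, e.stop_bin) == (1, 2)

    def test_run_merging_spans_consecutive_bins(self):
        """D=[12,15,3], A=[4,11,2]: one donor event over bins 0-1, coincident
        because bin 1 passes threshold in both channels."""
        ev = detect_events(_trace([12, 15, 3], [4, 11, 2]))
        assert ev.n_donor_events == 1
        e = ev.events[0]
        assert (e.start_bin, e.stop_bin) == (0, 2)
        assert e.intensities.donor_raw == 27
        assert e.intensities.acceptor_raw == 15
        assert e.coincident
        assert e.touches_edge  # run starts at the trace boundary

    def test_empty_trace_raises(self):
        with pytest.raises(EmptyTraceError):
            detect_events(_trace([], []))

    def test_peak_intensity_mode(self):
        ev = detect_events(_trace([12, 15, 3], [4, 11, 2]), intensity_mode="peak")
        assert ev.events[0].intensities.donor_raw == 15
        assert ev.events[0].intensities.acceptor_raw == 11

    @given(st.data())
    @settings(derandomize=True, max_examples=300)
    def test_matches_brute_force_oracle(self, oracle, data):
        n = data.draw(st.integers(1, 100))
        donor = data.draw(st.lists(st.integers(0, 25), min_size=n, max_size=n))
        acceptor = data.draw(st.lists(st.integers(0, 25), min_size=n, max_size=n))
        thr = data.draw(st.integers(1, 15))
        ev = detect_events(_trace(donor, acceptor), threshold=thr)
        expected = oracle(donor, acceptor, thr)
        assert ev.n_donor_events == len(expected)
        for got, want in zip(ev.events, expected):
            assert (got.start_bin, got.stop_bin) == (want["start"], want["stop"])
            assert got.intensities.donor_raw == want["donor_sum"]
            assert got.intensities.acceptor_raw == want["acceptor_sum"]
            assert got.coincident == want["coincident"]

    def test_coincident_count_monotone_in_threshold(self, paper_mimic):
        trace, _ = simulate_burst_stream(paper_mimic, seed=11, n_events=500)
        counts = [detect_events(trace, threshold=t).n_coincident for t in (5, 10, 20, 40)]
        assert counts == sorted(counts, reverse=True)


class TestMonomerBrightness:
    def test_mean_of_non_coincident_donor_intensities(self):
        ev = detect_events(_trace([20, 0, 30, 0, 15], [0, 0, 0, 0, 12]))
        # bins 0 and 2 are non-coincident; bin 4 is coincident
        assert monomer_brightness(ev) == pytest.approx(25.0)

    def test_all_coincident_raises(self):
        ev = detect_events(_trace([20, 0, 30], [15, 0, 11]))
        with pytest.raises(NoMonomerEventsError):
            monomer_brightness(ev)

    def test_recovers_generative_brightness(self, default_params):
        preset = load_preset("monomer_only")
        trace, _ = simulate_burst_stream(preset, seed=21, n_events=2000)
        ev = detect_events(trace)
        est = monomer_brightness(ev, default_params)
        assert est == pytest.approx(50.0, rel=0.05)


class TestAnalyzeEvents:
    def test_symmetric_event_has_half_efficiency(self, clean_params):
        ev = detect_events(_trace([40, 0], [40, 0]))
        ev = analyze_events(ev, clean_params)
        assert ev.events[0].efficiency == pytest.approx(0.5)

    def test_negative_corrected_intensity_excluded_and_counted(self):
        params = InstrumentParams(autofluor_acceptor=20.0, monomer_brightness=50.0)
        ev = detect_events(_trace([40, 0], [12, 0]))
        ev = analyze_events(ev, params)
        assert ev.events[0].excluded
        assert ev.n_excluded == 1
        assert ev.efficiencies().size == 0

    def test_size_classes_assigned(self, clean_params):
        ev = detect_events(_trace([30, 0, 250, 0, 900], [30, 0, 250, 0, 900]))
        ev = analyze_events(ev, clean_params)  # I_monomer = 50
        assert [e.size_class for e in ev.events] == ["small", "medium", "large"]

    def test_size_recovery_for_synthetic_n_mers(self):
        """Mean apparent size converges to the true n-mer size at gamma=1."""
        for n_mer in (2, 6, 10):
            preset = ScenarioPreset(
                name="nmer",
                species=(
                    SpeciesSpec(size_true=n_mer, efficiency_true=0.3, weight=1.0,
                                brightness_per_monomer=100.0),
                ),
                instrument=InstrumentParams(),
                event_rate=20.0, duration=50.0,
            )
            trace, _ = simulate_burst_stream(preset, seed=n_mer, n_events=400)
            params = InstrumentParams(monomer_brightness=100.0)
            ev = analyze_events(detect_events(trace), params)
            sizes = np.array([e.apparent_size for e in ev.coincident_events()])
            assert sizes.mean() == pytest.approx(n_mer, rel=0.03)

    def test_size_efficiency_table_shape(self, mimic_events):
        events, _ = mimic_events
        table = size_efficiency_table(events)
        assert {"apparent_size", "efficiency"} <= set(table.columns)
        assert len(table) == len(events.coincident_events())


class TestFractionOfCoincidence:
    @pytest.mark.parametrize(
        "donor, acceptor, expected",
        [
            ([20, 0, 20, 0], [0, 0, 0, 0], 0.0),
            ([20, 0, 20, 0], [15, 0, 11, 0], 1.0),
        ],
    )
    def test_edge_fractions(self, donor, acceptor, expected):
        assert fraction_of_coincidence(detect_events(_trace(donor, acceptor))) == expected

    def test_count_arithmetic(self):
        donor = [0, 20] * 40
        acceptor = [0, 15] * 10 + [0, 0] * 30
        ev = detect_events(_trace(donor, acceptor))
        assert ev.n_donor_events == 40
        assert fraction_of_coincidence(ev) == pytest.approx(0.25)

    def test_monomer_stream_matches_background_chance(self):
        """With donor-only species and no cross-talk, coincidence is the
        Poisson chance that background alone crosses the threshold."""
        ins = InstrumentParams(autofluor_donor=2.0, autofluor_acceptor=4.0)
        preset = ScenarioPreset(
            name="monomer-nc",
            species=(SpeciesSpec(size_true=1, efficiency_true=0.0, weight=1.0,
                                 brightness_per_monomer=50.0),),
            instrument=ins,
            event_rate=50.0, duration=100.0,
        )
        trace, _ = simulate_burst_stream(preset, seed=17, n_events=5000)
        frac = fraction_of_coincidence(detect_events(trace))
        from scipy.stats import poisson

        chance = poisson.sf(9, 4.0)  # P(acceptor background >= 10)
        assert frac == pytest.approx(chance, abs=3 * np.sqrt(chance / 5000) + 1e-4)
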