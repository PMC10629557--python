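"""Release-pathway classification, second-event detection, summaries."""

import numpy as np
import pytest

from cosmofret import (SimConfig, classify_release, detect_second_events,
                       render_traces, simulate_timeline, summarize_condition)
from cosmofret.events import PathwayRecord, build_pathway_record
from cosmofret.fret import EfretTrace
from cosmofret.intervals import (CallParams, Interval, LinkedEpisode,
                                 call_intervals, normalize_trace)
from cosmofret.pipeline import call_location_intervals, occm_links


def _iv(channel, start, end, dt=1.0, censored_end=False, **kw):
    return Interval(0, channel, start, end, dt, censored_end=censored_end, **kw)


class TestClassifyRelease:
    def test_equal_ends_are_simultaneous(self):
        call = classify_release(_iv("Cdt1", 10, 50), _iv("Mcm2-7", 10, 50))
        assert call.klass == "simultaneous"

    def test_much_earlier_cdt1_end_is_productive(self):
        call = classify_release(_iv("Cdt1", 10, 50), _iv("Mcm2-7", 10, 150))
        assert call.klass == "cdt1_only"
        assert call.post_cdt1_dwell == pytest.approx(100.0)

    def test_censored_mcm_after_cdt1_is_productive_censored(self):
        call = classify_release(_iv("Cdt1", 10, 50),
                                _iv("Mcm2-7", 10, 200, censored_end=True))
        assert call.klass == "cdt1_only" and call.censored

    def test_censored_cdt1_unresolved(self):
        call = classify_release(_iv("Cdt1", 10, 200, censored_end=True),
                                _iv("Mcm2-7", 10, 200, censored_end=True))
        assert call.klass == "unresolved"

    def test_tolerance_frames_define_simultaneity(self):
        cdt1, mcm = _iv("Cdt1", 10, 50), _iv("Mcm2-7", 10, 51)
        assert classify_release(cdt1, mcm, 1).klass == "simultaneous"
        assert classify_release(cdt1, mcm, 0).klass == "cdt1_only"

    def test_mismatched_locations_rejected(self):
        other = Interval(1, "Mcm2-7", 10, 50, 1.0)
        with pytest.raises(ValueError):
            classify_release(_iv("Cdt1", 10, 50), other)

    def test_simulated_branch_fractions_recovered_through_analysis(self):
        # full simulate -> render -> call -> link -> classify chain
        cfg = SimConfig(n_locations=400, n_control_locations=0,
                        active_fraction=1.0, k_specific=0.01,
                        p_productive=0.47, seed=41)
        tl = simulate_timeline(cfg)
        traces = render_traces(tl)
        classes = []
        for loc in tl.dna_locations:
            ivs = call_location_intervals(traces[loc.location_id],
                                          params=CallParams(min_frames=2))
            for link in occm_links(ivs):
                c = classify_release(link.cdt1, link.mcm, 1)
                if c.klass != "unresolved":
                    classes.append(c.klass)
        frac = np.mean([c == "cdt1_only" for c in classes])
        se = np.sqrt(0.47 * 0.53 / len(classes))
        assert len(classes) > 250
        assert abs(frac - 0.47) < 3 * se


class TestSecondEvents:
    def _link(self, mcm_tags=None, cdc6=()):
        mcm = Interval(0, "Mcm2-7", 0, 200, 1.0,
                       tags=mcm_tags or {"stoich2_frames": []})
        return LinkedEpisode(0, mcm, cdc6=list(cdc6))

    def test_no_level2_epochs_means_none(self):
        assert detect_second_events(self._link()).second_mcm == "none"

    def test_ten_second_epoch_is_short(self):
        link = self._link({"stoich2_frames": [(50, 60)]})
        out = detect_second_events(link)
        assert out.second_mcm == "short"
        assert out.second_mcm_duration == pytest.approx(10.0)

    def test_longest_epoch_decides_class(self):
        link = self._link({"stoich2_frames": [(50, 60), (100, 130)]})
        assert detect_second_events(link).second_mcm == "long"

    def test_second_cdc6_needs_gap_after_first(self):
        first = _iv("Cdc6", 0, 40)
        second = _iv("Cdc6", 80, 120)
        link = self._link(cdc6=[first, second])
        assert detect_second_events(link).second_cdc6
        overlapping = _iv("Cdc6", 20, 120)
        link = self._link(cdc6=[first, overlapping])
        assert not detect_second_events(link).second_cdc6

    def test_disabled_second_recruitment_yields_no_detections(self):
        # background binding also off: a brief surface binder stacked on
        # the specific Mcm2-7 is indistinguishable from a second landing
        cfg = SimConfig(n_locations=1000, n_control_locations=0, p_mo=0.0,
                        k_background=0.0, noise_sd=0.0, efret_sd=0.0,
                        bleach_rate=0.0, seed=43)
        tl = simulate_timeline(cfg)
        traces = render_traces(tl)
        for loc in tl.dna_locations:
            ivs = call_location_intervals(traces[loc.location_id])
            for link in occm_links(ivs):
                out = detect_second_events(link)
                assert out.second_mcm == "none"


class TestSummaries:
    def test_mo_fraction_worked_example(self):
        recs = ([PathwayRecord(i, mo_positive=True) for i in range(46)]
                + [PathwayRecord(i, mo_positive=False) for i in range(177)])
        s = summarize_condition(recs, "unphos")
        b = s.fractions["mo_positive"]
        assert (b.k, b.n) == (46, 223)
        assert b.percent == pytest.approx(20.6, abs=0.05)
        assert b.sem_percent == pytest.approx(2.7, abs=0.05)

    def test_ring_closure_worked_example(self):
        recs = ([PathwayRecord(i, ring_closed=True) for i in range(62)]
                + [PathwayRecord(i, ring_closed=False) for i in range(109)])
        b = summarize_condition(recs).fractions["ring_closed"]
        assert (b.k, b.n) == (62, 171)
        assert b.percent == pytest.approx(36.3, abs=0.05)

    def test_empty_condition_all_zero(self):
        s = summarize_condition([], "empty")
        assert s.n_records == 0
        assert all(b.k == 0 for b in s.fractions.values())
        assert (s.table["percent"] == 0).all()

    def test_release_classes_partition_counts(self):
        recs = [PathwayRecord(0, release="cdt1_only"),
                PathwayRecord(1, release="simultaneous"),
                PathwayRecord(2, release="unresolved"),
                PathwayRecord(3, release="cdt1_only")]
        s = summarize_condition(recs)
        b = s.fractions["cdt1_only"]
        assert b.n == 3 and b.k == 2  # unresolved excluded from denominator

    def test_mo_disabled_simulation_reports_zero_fraction(self):
        cfg = SimConfig(n_locations=150, n_control_locations=0, p_mo=0.0,
                        fret_assay="mo", active_fraction=1.0, k_specific=0.01,
                        seed=44)
        from cosmofret.pipeline import analyze_condition
        res = analyze_condition(cfg, "phos-like", fit_arrival=False, n_boot=0)
        b = res.summary.fractions["mo_positive"]
        assert b.k == 0 and b.n > 30


class TestMoImpliesClosureCapable:
    def test_mo_positive_trace_always_passes_ring_rule(self, rng):
        # threshold ordering: 0.5-for-2-frames implies 0.3-for-2-frames
        from cosmofret.fret import call_state
        for _ in range(50):
            n = 40
            v = np.clip(rng.normal(0.35, 0.2, n), 0, 1)
            ef = EfretTrace(0, np.arange(n, dtype=float), v,
                            np.ones(n, bool), 1.0)
            if call_state(ef, 0.5, 2):
                assert call_state(ef, 0.3, 2)


def test_pathway_record_requires_known_assay():
    link = LinkedEpisode(0, Interval(0, "Mcm2-7", 0, 100, 1.0))
    ef = EfretTrace(0, np.arange(100, dtype=float), np.full(100, 0.4),
                    np.ones(100, bool), 1.0)
    with pytest.raises(ValueError, match="assay"):
        build_pathway_record(link, efret=ef, assay="bogus")
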