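"""E_FRET computation, state calling, mixture fitting, and heat maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosmofret import (SimConfig, compute_efret, call_state, efret_heatmap,
                       fit_mixture, mixture_pdf, render_traces,
                       simulate_timeline)
from cosmofret.fret import EfretTrace
from cosmofret.intervals import Interval
from cosmofret.render import Trace


def _pair(d_vals, a_vals, dt=1.0):
    d = Trace(0, "D_em", np.asarray(d_vals, float), dt)
    a = Trace(0, "A_em", np.asarray(a_vals, float), dt)
    return d, a


def _efret(values, valid=None, dt=1.0):
    v = np.asarray(values, float)
    mask = np.ones(len(v), bool) if valid is None else np.asarray(valid, bool)
    return EfretTrace(0, np.arange(len(v)) * dt, np.where(mask, v, np.nan),
                      mask, dt)


class TestComputeEfret:
    def test_zero_acceptor_gives_zero(self):
        d, a = _pair(np.full(20, 100.0), np.zeros(20))
        ef = compute_efret(d, a, [Interval(0, "pair", 0, 20, 1.0)])
        assert np.allclose(ef.efret[ef.valid], 0.0)

    def test_equal_emission_gives_half(self):
        d, a = _pair(np.full(20, 5.0), np.full(20, 5.0))
        ef = compute_efret(d, a, [Interval(0, "pair", 0, 20, 1.0)])
        assert np.allclose(ef.efret[ef.valid], 0.5)

    def test_first_and_last_episode_frames_discarded(self):
        d, a = _pair(np.ones(30), np.ones(30))
        ef = compute_efret(d, a, [Interval(0, "pair", 10, 20, 1.0)])
        assert not ef.valid[10] and not ef.valid[19]
        assert ef.valid[11:19].all()
        assert not ef.valid[:10].any() and not ef.valid[20:].any()

    def test_stops_at_second_mcm_arrival(self):
        d, a = _pair(np.ones(30), np.ones(30))
        ef = compute_efret(d, a, [Interval(0, "pair", 0, 30, 1.0)],
                           stop_time=15.0)
        assert not ef.valid[15:].any()

    def test_nonpositive_total_masked_and_counted(self):
        d, a = _pair(np.ones(20), np.ones(20))
        d.values[5] = a.values[5] = 0.0
        ef = compute_efret(d, a, [Interval(0, "pair", 0, 20, 1.0)])
        assert not ef.valid[5]
        assert ef.qc["n_masked_nonpositive_total"] == 1

    def test_noiseless_closed_state_reads_simulator_center(self):
        cfg = SimConfig(n_locations=30, n_control_locations=0, noise_sd=0.0,
                        efret_sd=0.0, bleach_rate=0.0, k_open_close=1e9,
                        k_close_open=0.0, active_fraction=1.0,
                        k_specific=0.01, k_background=0.0, p_mo=0.0, seed=17)
        tl = simulate_timeline(cfg)
        traces = render_traces(tl)
        hits = 0
        for loc in tl.dna_locations:
            ch = traces[loc.location_id]
            occupied = ch["D_em"].values + ch["A_em"].values > 0.5
            if occupied.sum() < 5:
                continue
            idx = np.nonzero(occupied)[0]
            ep = Interval(loc.location_id, "pair", int(idx[0]),
                          int(idx[-1] + 1), cfg.frame_interval)
            ef = compute_efret(ch["D_em"], ch["A_em"], [ep])
            # gate closes effectively instantly and stays closed
            vals = ef.efret[ef.valid][1:]
            if len(vals):
                np.testing.assert_allclose(vals, cfg.efret_closed_center,
                                           atol=1e-9)
                hits += 1
        assert hits >= 10

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        d, a = _pair([60.0, 40.0, 80.0], [40.0, 60.0, 20.0])
        d2, a2 = _pair(np.array([60.0, 40.0, 80.0]) * scale,
                       np.array([40.0, 60.0, 20.0]) * scale)
        ep = [Interval(0, "pair", 0, 3, 1.0)]
        e1 = compute_efret(d, a, ep)
        e2 = compute_efret(d2, a2, ep)
        np.testing.assert_allclose(e1.efret[e1.valid], e2.efret[e2.valid],
                                   rtol=1e-9)


class TestCallState:
    def test_sustained_level_gives_single_interval(self):
        (iv,) = call_state(_efret(np.full(10, 0.4)), 0.3, 2)
        assert (iv.start_frame, iv.end_frame) == (0, 10)

    def test_single_frame_excursion_not_called(self):
        v = np.full(10, 0.1)
        v[4] = 0.6
        assert call_state(_efret(v), 0.3, 2) == []
        assert len(call_state(_efret(v), 0.3, 1)) == 1

    def test_masked_frame_breaks_a_run(self):
        v = np.full(10, 0.5)
        valid = np.ones(10, bool)
        valid[5] = False
        ivs = call_state(_efret(v, valid), 0.3, 2)
        assert [(i.start_frame, i.end_frame) for i in ivs] == [(0, 5), (6, 10)]

    def test_idempotent_and_mask_outside_runs_irrelevant(self):
        v = np.array([0.1, 0.5, 0.5, 0.5, 0.1, 0.1, 0.6, 0.6, 0.1, 0.1])
        base = call_state(_efret(v), 0.3, 2)
        valid = np.ones(10, bool)
        valid[0] = valid[9] = False  # masked frames outside called runs
        again = call_state(_efret(v, valid), 0.3, 2)
        assert [(i.start_frame, i.end_frame) for i in base] == \
            [(i.start_frame, i.end_frame) for i in again]

    def test_closed_fraction_matches_markov_stationarity(self):
        # two-state occupancy oracle: k_oc / (k_oc + k_co)
        cfg = SimConfig(n_locations=300, n_control_locations=0, noise_sd=0.0,
                        efret_sd=0.02, bleach_rate=0.0, active_fraction=1.0,
                        k_specific=0.05, k_background=0.0, p_productive=1.0,
                        p_mo=0.0, closed_dwell_unstable_mean=2000.0,
                        cdt1_release_mean=5.0, seed=19)
        tl = simulate_timeline(cfg)
        total = 0.0
        closed = 0.0
        for loc in tl.dna_locations:
            for seg in loc.ring_segments:
                total += seg.end - seg.start
                if seg.state == "closed":
                    closed += seg.end - seg.start
        occ = cfg.k_open_close / (cfg.k_open_close + cfg.k_close_open)
        # conservative SE from the number of transitions simulated
        n_seg = sum(len(l.ring_segments) for l in tl.dna_locations)
        assert n_seg > 1000
        assert abs(closed / total - occ) < 3 * occ / math.sqrt(n_seg)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            call_state(_efret(np.ones(5)), threshold=1.5)
        with pytest.raises(ValueError):
            call_state(_efret(np.ones(5)), min_frames=0)


class TestMixture:
    def test_density_integrates_to_one(self):
        x = np.linspace(-1, 2, 20_000)
        for theta in [(0.6, 0.2, 0.37, 0.05, 0.05),
                      (0.1, 0.15, 0.5, 0.02, 0.2),
                      (0.9, 0.3, 0.31, 0.01, 0.01)]:
            area = np.trapezoid(mixture_pdf(x, *theta), x)
            assert area == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_within_three_bootstrap_se(self, rng):
        # truncated likelihood: the fit window clips ~2% of the low tail,
        # which would otherwise bias the component SDs
        truth = (0.6, 0.20, 0.37, 0.05, 0.05)
        n = 10_000
        comp = rng.random(n) < truth[0]
        x = np.where(comp, rng.normal(truth[1], truth[3], n),
                     rng.normal(truth[2], truth[4], n))
        fit = fit_mixture(x, n_boot=200, seed=1, truncated=True)
        for got, se, want in [
                (fit.p_low, fit.se_p_low, truth[0]),
                (fit.mu_low, fit.se_mu_low, truth[1]),
                (fit.mu_high, fit.se_mu_high, truth[2]),
                (fit.sigma_low, fit.se_sigma_low, truth[3]),
                (fit.sigma_high, fit.se_sigma_high, truth[4])]:
            assert abs(got - want) < 3 * se

    def test_single_component_input_flagged_degenerate(self, rng):
        x = rng.normal(0.2, 0.04, 2000)
        fit = fit_mixture(x, n_boot=0, seed=2)
        # either the mixture collapses onto 0.2 or one component vanishes
        collapsed = (abs(fit.mu_low - 0.2) < 0.02
                     and abs(fit.mu_high - 0.2) < 0.02)
        vanished = fit.p_low > 0.95 or fit.p_low < 0.05
        assert collapsed or vanished

    def test_symmetric_mixture_gives_half_weight(self, rng):
        n = 4000
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(0.28, 0.04, n),
                     rng.normal(0.42, 0.04, n))
        fit = fit_mixture(x, n_boot=0, seed=3)
        assert fit.p_low == pytest.approx(0.5, abs=0.05)
        assert fit.mu_low < fit.mu_high

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="50"):
            fit_mixture(rng.normal(0.3, 0.05, 30), n_boot=0)

    def test_truncated_and_plain_fits_agree_on_interior_mixture(self, rng):
        # window [0.1, 0.7] holds ~all the mass, so both modes agree
        n = 6000
        comp = rng.random(n) < 0.6
        x = np.where(comp, rng.normal(0.20, 0.05, n),
                     rng.normal(0.37, 0.05, n))
        plain = fit_mixture(x, n_boot=0, seed=4)
        trunc = fit_mixture(x, n_boot=0, seed=4, truncated=True)
        assert abs(plain.mu_low - trunc.mu_low) < 0.01
        assert abs(plain.mu_high - trunc.mu_high) < 0.01

    def test_paper_scale_mixture_mass_inside_window(self, rng):
        # >=97% of samples from the fitted state centers fall in [0.1, 0.7]
        n = 20_000
        comp = rng.random(n) < 0.6
        x = np.where(comp, rng.normal(0.20, 0.05, n),
                     rng.normal(0.37, 0.05, n))
        inside = np.mean((x >= 0.1) & (x <= 0.7))
        assert inside >= 0.97


class TestHeatMap:
    def test_each_time_slice_normalized(self, rng):
        traces = []
        for i in range(10):
            n = 60
            v = np.clip(rng.normal(0.3, 0.05, n), 0, 1)
            traces.append(_efret(v, dt=2.6))
        hm = efret_heatmap(traces)
        areas = np.trapezoid(hm.density, hm.e_grid, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-6)

    def test_single_constant_molecule_gives_kernel_at_center(self):
        hm = efret_heatmap([_efret(np.full(50, 0.2), dt=2.6)],
                           e_grid=np.linspace(0, 1, 2001))
        peak = hm.e_grid[np.argmax(hm.density[2])]
        assert peak == pytest.approx(0.2, abs=0.002)
        # kernel width equals the 0.005 E_FRET bandwidth
        half = hm.density[2] >= hm.density[2].max() / 2
        fwhm = hm.e_grid[half].max() - hm.e_grid[half].min()
        assert fwhm == pytest.approx(2.355 * 0.005, rel=0.1)

    def test_remaining_fraction_starts_at_one_and_decreases(self, rng):
        traces = []
        for i in range(20):
            n = int(rng.integers(10, 80))
            traces.append(_efret(np.full(n, 0.3), dt=2.6))
        hm = efret_heatmap(traces)
        assert hm.remaining[0] == 1.0
        assert np.all(np.diff(hm.remaining) <= 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            efret_heatmap([])
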