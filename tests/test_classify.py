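import numpy as np
import pytest
from scipy.stats import norm

import phasetrack as pt
from phasetrack.classify import H_STATE, L_STATE, eligible_tracks
from phasetrack.geometry import CONDENSED


@pytest.fixture(scope="module")
def anchored_two_state(acq):
    """Condensed-phase style tracks: confined jitter at 13.6 nm scatter,
    mobile diffusion at the reference mobile-state D, classification-scale
    switching (P_mc = 0.59, P_cm = 0.09 per frame)."""
    rates = pt.SwitchRates(P_cm=0.09, P_mc=0.59)
    gt, _ = pt.simulate_two_state(400, 60, 0.044, rates, psf_scatter=0.0136,
                                  acquisition=acq, seed=21)
    ts = pt.TrackSet(gt.tracks, acq)
    for tr in ts:
        tr.phase[:] = CONDENSED
    return ts, rates


class TestOvl:
    def test_identical_is_one(self):
        p = np.array([0.2, 0.5, 0.3]) / 0.1 / 10  # normalized on width-0.1 bins
        p = np.array([2.0, 5.0, 3.0])
        assert pt.ovl(p, p, 0.1) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        p = np.array([10.0, 0.0])
        q = np.array([0.0, 10.0])
        assert pt.ovl(p, q, 0.1) == 0.0

    def test_closed_form_shifted_gaussians(self):
        # two unit-variance Gaussians 2 sigma apart: OVL = 2 Phi(-1)
        x = np.arange(-10, 12, 0.01)
        centers = 0.5 * (x[:-1] + x[1:])
        p = norm.pdf(centers, loc=0.0)
        q = norm.pdf(centers, loc=2.0)
        assert pt.ovl(p, q, 0.01) == pytest.approx(2 * norm.cdf(-1), abs=1e-4)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = rng.random(50)
        p /= p.sum() * 0.1
        q /= q.sum() * 0.1
        assert pt.ovl(p, q, 0.1) == pytest.approx(pt.ovl(q, p, 0.1))
        assert 0 <= pt.ovl(p, q, 0.1) <= 1

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            pt.ovl(np.ones(3), np.ones(4), 0.1)


class TestConditionalDists:
    def test_pair_counting_single_track(self, acq):
        xy = np.cumsum(np.full((11, 2), 0.01), axis=0)
        tr = pt.Track(np.arange(11), xy)
        tr.phase[:] = CONDENSED
        cd = pt.conditional_dists(pt.TrackSet([tr], acq), d_b=0.05)
        # 10 steps -> 9 consecutive pairs
        assert cd.n_low + cd.n_high == 9

    def test_iid_steps_conditionals_converge(self, acq):
        # simple diffusion: consecutive steps independent -> OVL near 1
        rng = np.random.default_rng(1)
        tracks = []
        for _ in range(200):
            steps = rng.standard_normal((60, 2)) * np.sqrt(2 * 0.05 * 0.03)
            xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            tr = pt.Track(np.arange(61), xy)
            tr.phase[:] = CONDENSED
            tracks.append(tr)
        ts = pt.TrackSet(tracks, acq)
        cd = pt.conditional_dists(ts, d_b=0.05)
        w = 0.005
        assert pt.ovl(cd.p_low, cd.p_high, w) > 0.93

    def test_two_state_conditionals_distinct(self, anchored_two_state):
        ts, _ = anchored_two_state
        cd = pt.conditional_dists(ts, d_b=0.06)
        assert pt.ovl(cd.p_low, cd.p_high, 0.005) < 0.9

    def test_short_tracks_excluded(self, acq):
        tr = pt.Track(np.arange(5), np.random.default_rng(0).random((5, 2)))
        tr.phase[:] = CONDENSED
        with pytest.raises(ValueError):
            pt.conditional_dists(pt.TrackSet([tr], acq), d_b=0.05)


class TestScanDemarcation:
    def test_two_state_minimum_between_modes(self, anchored_two_state):
        ts, _ = anchored_two_state
        scan = pt.scan_demarcation(ts)
        assert not scan.flat
        # L displacement scale ~2*13.6 nm, H scale sqrt(2*0.044*0.03) ~ 51
        # nm per axis: the OVL minimum sits between the two modes
        assert 0.02 <= scan.d_b_star <= 0.12
        assert np.nanmin(scan.ovl_curve) == scan.ovl_curve[
            np.argmin(np.abs(scan.d_b_grid - scan.d_b_star))]

    def test_simple_diffusion_yields_null(self, acq):
        rng = np.random.default_rng(2)
        tracks = []
        for _ in range(150):
            steps = rng.standard_normal((60, 2)) * np.sqrt(2 * 0.05 * 0.03)
            xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            tr = pt.Track(np.arange(61), xy)
            tr.phase[:] = CONDENSED
            tracks.append(tr)
        scan = pt.scan_demarcation(pt.TrackSet(tracks, acq),
                                   d_b_grid=np.arange(0.03, 0.15, 0.01))
        assert scan.flat and scan.d_b_star is None


class TestClassifySteps:
    def test_all_below_demarcation(self, acq):
        xy = np.cumsum(np.full((12, 2), 0.001), axis=0)
        tr = pt.Track(np.arange(12), xy)
        tr.phase[:] = CONDENSED
        res = pt.classify_steps(pt.TrackSet([tr], acq), d_b=0.5)
        assert res.P_c == 1.0 and res.P_cm == 0.0

    def test_alternating_labels(self, acq):
        # alternate tiny and large steps -> every transition switches
        pos = [np.zeros(2)]
        for i in range(12):
            step = 0.001 if i % 2 == 0 else 0.2
            pos.append(pos[-1] + [step, 0.0])
        tr = pt.Track(np.arange(13), np.array(pos))
        tr.phase[:] = CONDENSED
        res = pt.classify_steps(pt.TrackSet([tr], acq), d_b=0.05)
        assert res.P_mc == 1.0 and res.P_cm == 1.0

    def test_switching_frequency_recovery(self, acq):
        # switching frequencies (P_mc = 0.59, P_cm = 0.09 per frame) are
        # recovered from label transitions when the state scales are well
        # separated relative to the demarcation; at marginal separation the
        # label process systematically differs from the state process
        rates = pt.SwitchRates(P_cm=0.09, P_mc=0.59)
        gt, _ = pt.simulate_two_state(500, 60, 0.3, rates, psf_scatter=0.0136,
                                      acquisition=acq, seed=31)
        ts = pt.TrackSet(gt.tracks, acq)
        for tr in ts:
            tr.phase[:] = CONDENSED
        res = pt.classify_steps(ts, d_b=0.06)
        assert res.P_mc == pytest.approx(rates.P_mc, rel=0.10)
        assert res.P_cm == pytest.approx(rates.P_cm, rel=0.10)
        assert res.P_m == pytest.approx(rates.mobile_ratio, rel=0.10)

    def test_agreement_with_hmm_ratios(self, acq):
        # well-separated scales: classification and HMM agree on P_c/P_m
        # within 10 percentage points
        rates = pt.SwitchRates(P_cm=0.09, P_mc=0.59)
        gt, _ = pt.simulate_two_state(600, 40, 0.1, rates, psf_scatter=0.01,
                                      acquisition=acq, seed=23)
        ts = pt.TrackSet(gt.tracks, acq)
        for tr in ts:
            tr.phase[:] = CONDENSED
        model = pt.hmm_fit(ts, max_iter=3000)
        res = pt.classify_steps(ts, d_b=0.05)
        assert abs(res.P_m - model.P_m) < 0.10


class TestFitComponents:
    def test_scale_recovery(self, anchored_two_state, acq):
        ts, _ = anchored_two_state
        res = pt.classify_steps(ts, d_b=0.06)
        fits = pt.fit_components(res, acq.frame_interval)
        assert fits["s_L_nm"] == pytest.approx(13.6, rel=0.10)
        assert fits["D_H"] == pytest.approx(0.044, rel=0.10)

    def test_brownian_H_not_heavy_tailed(self, anchored_two_state, acq):
        ts, _ = anchored_two_state
        res = pt.classify_steps(ts, d_b=0.06)
        fits = pt.fit_components(res, acq.frame_interval, heavy_tail=True)
        assert fits["aic_brownian"] < fits["aic_levy"]

    def test_tiny_component_rejected(self, acq):
        xy = np.cumsum(np.full((12, 2), 0.001), axis=0)
        tr = pt.Track(np.arange(12), xy)
        tr.phase[:] = CONDENSED
        res = pt.classify_steps(pt.TrackSet([tr], acq), d_b=0.5)
        with pytest.raises(ValueError):
            pt.fit_components(res, acq.frame_interval)


class TestEligibility:
    def test_condensed_only_and_min_steps(self, acq):
        long_cond = pt.Track(np.arange(12), np.random.default_rng(0).random((12, 2)))
        long_cond.phase[:] = CONDENSED
        short = pt.Track(np.arange(5), np.random.default_rng(1).random((5, 2)))
        short.phase[:] = CONDENSED
        mixed = pt.Track(np.arange(12), np.random.default_rng(2).random((12, 2)))
        mixed.phase[:] = CONDENSED
        mixed.phase[3] = "dilute"
        ts = pt.TrackSet([long_cond, short, mixed], acq)
        assert eligible_tracks(ts) == [long_cond]
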