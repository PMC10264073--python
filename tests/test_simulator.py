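import numpy as np
import pytest

import phasetrack as pt
from phasetrack.simulate import CONFINED, MOBILE


class TestBrownianStep:
    def test_frozen_at_zero_D(self):
        rng = np.random.default_rng(0)
        steps = pt.brownian_step(0.0, 0.03, rng, size=100)
        assert np.all(steps == 0)

    def test_step_variance_matches_law(self):
        rng = np.random.default_rng(1)
        D, dt = 0.5, 0.03
        steps = pt.brownian_step(D, dt, rng, size=100_000)
        # per-axis variance 2 D dt and mean square step 4 D dt
        assert np.var(steps[:, 0]) == pytest.approx(2 * D * dt, rel=0.02)
        msq = np.mean(steps[:, 0] ** 2 + steps[:, 1] ** 2)
        assert msq == pytest.approx(4 * D * dt, rel=0.02)


class TestSwitchRates:
    def test_detailed_balance_from_lifetime(self):
        r = pt.SwitchRates.from_mobile_lifetime(0.1, 0.1, 1e-4)
        assert r.P_mc == pytest.approx(1e-3)
        assert 0.1 * r.P_mc == pytest.approx(0.9 * r.P_cm)
        assert r.mobile_ratio == pytest.approx(0.1)

    def test_stationary_formula(self):
        r = pt.SwitchRates(P_cm=0.038, P_mc=0.828)
        assert r.mobile_ratio == pytest.approx(0.038 / (0.038 + 0.828))


class TestHomogeneousGenerator:
    def test_track_count_formula(self):
        gt, table = pt.simulate_homogeneous(0.3, 0.1, 1000, box=(10, 10), seed=0)
        expected = 0.3 * 100 * 1000 / 3.5
        assert len(gt.tracks) == round(expected)

    def test_mean_lifetime_near_poisson_mean(self):
        gt, _ = pt.simulate_homogeneous(0.35, 0.1, 1000, box=(10, 10), seed=1)
        assert len(gt.tracks) >= 10_000
        assert gt.mean_lifetime() == pytest.approx(3.5, rel=0.03)

    def test_zero_D_tracks_are_stationary(self):
        gt, _ = pt.simulate_homogeneous(0.05, 0.0, 50, box=(5, 5), seed=2)
        for tr in gt.tracks:
            assert np.allclose(tr.xy, tr.xy[0])

    def test_localizations_map_to_truth(self):
        gt, table = pt.simulate_homogeneous(0.1, 0.1, 100, box=(5, 5), seed=3)
        assert len(table) == sum(len(t.frames) for t in gt.tracks)


class TestTwoStateGenerator:
    def test_all_confined_when_no_escape(self):
        rates = pt.SwitchRates(P_cm=0.0, P_mc=1.0)
        gt, _ = pt.simulate_two_state(50, 20, 0.1, rates, seed=0)
        states = np.concatenate([t.state for t in gt.tracks])
        assert set(states) == {CONFINED}

    def test_stationary_mobile_fraction(self):
        rates = pt.SwitchRates(P_cm=0.1, P_mc=0.9)
        gt, _ = pt.simulate_two_state(200, 500, 0.1, rates, seed=1)
        states = np.concatenate([t.state for t in gt.tracks])
        assert np.mean(states == MOBILE) == pytest.approx(0.1, abs=0.01)

    def test_confined_scatter_scale(self, acq):
        # confined-state displacements: difference of two Gaussian(s)
        # scatters per axis -> E[d^2] = 4 s^2
        s = 0.0136
        rates = pt.SwitchRates(P_cm=0.0, P_mc=1.0)
        gt, _ = pt.simulate_two_state(300, 50, 0.1, rates, psf_scatter=s,
                                      acquisition=acq, seed=2)
        d = np.concatenate([t.displacements() for t in gt.tracks])
        s_hat = np.sqrt(np.mean(d**2) / 4)
        assert s_hat == pytest.approx(s, rel=0.05)


class TestEquilibriumEngine:
    @pytest.fixture(scope="class")
    def small_world(self):
        geom = pt.DiskRegions([[2.0, 2.0, 0.8], [5.5, 5.5, 0.8]])
        return pt.SimWorld(box=(8.0, 8.0), geometry=geom, D_d=0.6, D_m=0.2,
                           mobile_ratio=0.1, mobile_lifetime=0.1, dt=5e-4,
                           n_molecules=2000, T=5.0, seed=3)

    def test_no_contrast_gives_ef_one(self):
        geom = pt.DiskRegions([[2.0, 2.0, 1.0]])
        w = pt.SimWorld(box=(6.0, 6.0), geometry=geom, D_d=0.5, D_m=0.5,
                        mobile_ratio=1.0, mobile_lifetime=None, dt=5e-4,
                        n_molecules=5000, T=5.0, seed=0)
        trace, _ = pt.simulate_equilibrium(w, init="uniform")
        assert pt.steady_state_EF(trace, window=2.0) == pytest.approx(1.0, abs=0.1)

    def test_seed_reproducibility(self, small_world):
        t1, p1 = pt.simulate_equilibrium(small_world, init="enriched")
        t2, p2 = pt.simulate_equilibrium(small_world, init="enriched")
        np.testing.assert_array_equal(t1.ef, t2.ef)
        np.testing.assert_array_equal(p1, p2)

    def test_molecule_count_conserved_in_box(self, small_world):
        _, pos = pt.simulate_equilibrium(small_world, init="uniform")
        assert len(pos) == small_world.n_molecules
        assert np.all(pos >= 0) and np.all(pos[:, 0] < 8.0) and np.all(pos[:, 1] < 8.0)

    def test_mobile_fraction_detailed_balance(self, small_world):
        # long-run mobile fraction inside the condensed phase equals eta
        import phasetrack.simulate as sim
        rng = np.random.default_rng(9)
        raster = sim._raster_of(small_world)
        rates = small_world.switch_rates()
        pos = sim._init_positions(small_world, raster, rng, "enriched", None)
        cond = raster.contains(pos)
        confined = cond & (rng.random(len(pos)) >= small_world.mobile_ratio)
        x, y = pos[:, 0].copy(), pos[:, 1].copy()
        fracs = []

        def cb(k, xs, ys, c, conf):
            n_c = c.sum()
            if n_c:
                fracs.append(1.0 - conf.sum() / n_c)

        sim._run_steps(x, y, confined, cond, small_world, raster, rates, rng,
                       n_steps=10_000, callback=cb, callback_every=200)
        mean_frac = np.mean(fracs[10:])
        # binomial-ish noise bound, 3 sd with conservative n
        assert abs(mean_frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 500)

    def test_homogeneous_start_ef_rises_to_plateau(self, small_world):
        trace, _ = pt.simulate_equilibrium(small_world, init="uniform")
        third = len(trace.ef) // 3
        assert trace.ef[:third].mean() < trace.ef[-third:].mean()

    def test_eta_one_with_lifetime_rejected(self):
        geom = pt.DiskRegions([[1.0, 1.0, 0.5]])
        with pytest.raises(ValueError):
            pt.SimWorld(box=(4, 4), geometry=geom, mobile_ratio=1.0,
                        mobile_lifetime=0.1)


class TestSteadyStateEF:
    def test_constant_trace(self):
        from phasetrack.simulate import EFTrace
        tr = EFTrace(np.linspace(1, 30, 30), np.full(30, 60.0))
        assert pt.steady_state_EF(tr, window=10.0) == pytest.approx(60.0)

    def test_linear_ramp(self):
        from phasetrack.simulate import EFTrace
        times = np.arange(1.0, 101.0)
        tr = EFTrace(times, times)  # 0 -> 100 over 100 s
        assert pt.steady_state_EF(tr, window=10.0) == pytest.approx(95.5, abs=1.0)

    def test_replicates_mean_sd(self):
        from phasetrack.simulate import EFTrace
        times = np.linspace(1, 30, 30)
        traces = [EFTrace(times, np.full(30, v)) for v in (59.0, 60.0, 61.0)]
        mean, sd = pt.steady_state_EF(traces, window=10.0)
        assert mean == pytest.approx(60.0)
        assert sd == pytest.approx(1.0)

    def test_short_trace_rejected(self):
        from phasetrack.simulate import EFTrace
        tr = EFTrace(np.linspace(0, 5, 6), np.ones(6))
        with pytest.raises(ValueError):
            pt.steady_state_EF(tr, window=10.0)


class TestSwitchWalk:
    def test_apparent_D_scales_with_mobile_ratio(self, acq):
        out = pt.simulate_switch_walk(D_m=0.61, mobile_ratios=(0.25, 0.5, 1.0),
                                      n_particles=150, T=20.0,
                                      acquisition=acq, seed=0)
        Ds = [out[r][2] for r in (0.25, 0.5, 1.0)]
        assert Ds[0] < Ds[1] < Ds[2]
        # P_m = 1: apparent D equals the mobile-state input
        assert Ds[2] == pytest.approx(0.61, rel=0.1)
        # P_m = 0.5: time-average halves the apparent D
        assert Ds[1] == pytest.approx(0.5 * 0.61, rel=0.15)
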