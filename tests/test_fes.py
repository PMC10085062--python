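import numpy as np
import pytest

from lipidfes import fes as F
from lipidfes import synthetic as syn
from lipidfes.cv import CVSeries

KT310 = F.KB * 310.0


def _hill(t, c, s, h, w=0):
    return F.HillRecord(t, tuple(np.atleast_1d(c)), tuple(np.atleast_1d(s)), h, w)


class TestBiasPotential:
    def test_no_hills_is_zero(self):
        assert F.bias_potential([], np.array([0.3])) == 0.0

    def test_height_at_own_center(self):
        h = _hill(1.0, 0.4, 0.1, 2.5)
        assert F.bias_potential([h], np.array([0.4])) == pytest.approx(2.5)

    def test_truncated_sum_matches_untruncated_oracle(self):
        rng = np.random.default_rng(3)
        hills = [
            _hill(t, rng.uniform(-1, 1, 2), rng.uniform(0.05, 0.3, 2),
                  rng.uniform(0.5, 2.5))
            for t in range(100)
        ]
        pts = rng.uniform(-1, 1, size=(20, 2))
        got = F.bias_potential(hills, pts, truncate=6.0)
        want = np.zeros(20)
        for h in hills:
            c, s = np.array(h.center), np.array(h.sigma)
            want += h.height * np.exp(-0.5 * (((pts - c) / s) ** 2).sum(axis=1))
        total = sum(h.height for h in hills)
        assert np.abs(got - want).max() < 1e-6 * total

    def test_time_cutoff_excludes_later_hills(self):
        hills = [_hill(1.0, 0.0, 0.1, 1.0), _hill(2.0, 0.0, 0.1, 1.0)]
        assert F.bias_potential(hills, np.array([0.0]), time_cutoff=1.5) == pytest.approx(1.0)


class TestTemperedHeight:
    def test_zero_bias_gives_initial_height(self):
        p = F.WTMDParams()
        assert F.tempered_height(0.0, 2.5, p) == pytest.approx(2.5)

    def test_one_tempering_scale_gives_h0_over_e(self):
        p = F.WTMDParams()
        assert F.tempered_height(p.delta_t_energy, 2.5, p) == pytest.approx(2.5 / np.e)

    def test_heights_non_increasing_at_revisited_center(self):
        p = F.WTMDParams(sigmas=(0.1,), walls=(None,))
        grid = F.BiasGrid([np.linspace(-1, 1, 101)])
        heights = []
        for _ in range(30):
            v = grid.interpolate(np.array([[0.0]]))[0]
            h = F.tempered_height(v, 2.5, p)
            grid.add_hill([0.0], [0.1], h)
            heights.append(h)
        assert all(b <= a for a, b in zip(heights, heights[1:]))


class TestReweighting:
    def test_unbiased_limit_equals_plain_histogram(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 0.4, 4000)
        series = CVSeries(np.arange(len(x), dtype=float), {"x": x})
        edges = [np.linspace(-2, 2, 41)]
        p = F.WTMDParams(sigmas=(0.1,), walls=(None,))
        fes = F.reweight_tiwary_parrinello([series], [], p, edges, ["x"])
        hist, _ = np.histogram(x, bins=edges[0])
        want = -KT310 * np.log(hist, where=hist > 0, out=np.full(40, np.nan))
        want -= np.nanmin(want)
        ok = hist > 0
        assert np.allclose(fes.free_energy[ok], want[ok], atol=1e-9)

    def test_empty_after_burn_in_is_an_error(self):
        series = CVSeries(np.arange(4.0), {"x": np.zeros(4)})
        p = F.WTMDParams(sigmas=(0.1,), walls=(None,))
        with pytest.raises(ValueError):
            F.reweight_tiwary_parrinello([series], [], p, [np.linspace(-1, 1, 11)],
                                         ["x"], burn_in=100.0)

    def test_constant_energy_shift_leaves_fes_unchanged(self):
        # weights depend on V - c; adding a constant hill field everywhere
        # (sigma >> domain) must not change the normalized surface
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 0.4, 3000)
        series = CVSeries(np.arange(len(x), dtype=float), {"x": x})
        edges = [np.linspace(-2, 2, 41)]
        p = F.WTMDParams(sigmas=(0.1,), walls=(None,))
        base = F.reweight_tiwary_parrinello([series], [], p, edges, ["x"])
        flat = [_hill(0.5, 0.0, 500.0, 3.0)]  # essentially uniform over [-2, 2]
        shifted = F.reweight_tiwary_parrinello([series], flat, p, edges, ["x"])
        ok = np.isfinite(base.free_energy)
        assert np.allclose(shifted.free_energy[ok], base.free_energy[ok], atol=1e-3)


class TestWham:
    def test_single_harmonic_window_recovers_potential_curvature(self):
        # harmonic potential k_p plus harmonic bias k_b: exact Gaussian samples
        kp, kb, c = 5.0, 40.0, 0.3
        mu = c * kb / (kp + kb)
        sig = np.sqrt(KT310 / (kp + kb))
        rng = np.random.default_rng(5)
        samples = rng.normal(mu, sig, 200000)
        edges = np.linspace(mu - 3 * sig, mu + 3 * sig, 31)
        w = F.UmbrellaWindowData(c, kb, samples)
        fes = F.wham_1d([w], 310.0, edges, n_error_blocks=0)
        # Boltzmann-inversion oracle: bin-averaged Gaussian algebra
        from scipy.special import erf

        beta = 1.0 / KT310
        s_pot = np.sqrt(1.0 / (beta * kp))
        mass = 0.5 * (erf(edges[1:] / (s_pot * np.sqrt(2)))
                      - erf(edges[:-1] / (s_pot * np.sqrt(2))))
        want = -KT310 * np.log(mass)
        want -= want.min()
        counts, _ = np.histogram(samples, bins=edges)
        good = fes.defined & (counts > 2000)
        resid = fes.free_energy[good] - want[good]
        assert np.sqrt(np.mean(resid**2)) < 0.06

    def test_flat_potential_gives_flat_profile(self):
        rng = np.random.default_rng(6)
        sig = np.sqrt(KT310 / 40.0)
        ws = [
            F.UmbrellaWindowData(c, 40.0, rng.normal(c, sig, 100000))
            for c in (-0.2, 0.2)
        ]
        fes = F.wham_1d(ws, 310.0, np.linspace(-0.8, 0.8, 17), n_error_blocks=0)
        ok = fes.defined & (np.abs(fes.centers[0]) < 0.5)
        assert fes.free_energy[ok].max() < 0.15  # ~4x the per-bin noise

    def test_disjoint_windows_error_names_the_gap(self):
        rng = np.random.default_rng(7)
        ws = [
            F.UmbrellaWindowData(-3.0, 5000.0, rng.normal(-3.0, 0.02, 500)),
            F.UmbrellaWindowData(3.0, 5000.0, rng.normal(3.0, 0.02, 500)),
        ]
        with pytest.raises(ValueError, match="-3"):
            F.wham_1d(ws, 310.0, np.linspace(-4, 4, 81))

    def test_toy_double_well_matches_quadrature(self):
        pot = syn.ToyPotential(form="double_well_1d", barrier=8.0)
        lp = syn.LangevinParams(n_steps=30000, seed=2)
        windows = syn.run_toy_umbrella(pot, np.linspace(-1.9, 1.9, 20), 100.0, lp)
        edges = np.linspace(-2, 2, 101)
        fes = F.wham_1d(windows, 310.0, edges)
        truth = syn.analytic_fes(pot, edges, 310.0)
        ok = fes.defined & truth.defined & (truth.free_energy < 10 * KT310)
        rms = np.sqrt(np.mean((fes.free_energy[ok] - truth.free_energy[ok]) ** 2))
        assert rms < 0.3


class TestMarginalize:
    def _grid2d(self, fxy):
        ex = np.linspace(-1, 1, 21)
        ey = np.linspace(-2, 2, 31)
        cx = 0.5 * (ex[1:] + ex[:-1])
        cy = 0.5 * (ey[1:] + ey[:-1])
        Fv = fxy(cx[:, None], cy[None, :])
        return F.FESGrid(("x", "y"), [ex, ey], Fv - Fv.min())

    def test_constant_in_y_equals_any_slice(self):
        g = self._grid2d(lambda x, y: 3.0 * x**2 + 0.0 * y)
        m = F.marginalize_fes(g, "x", 310.0)
        want = 3.0 * m.centers[0] ** 2
        want -= want.min()
        assert np.allclose(m.free_energy, want, atol=1e-9)

    def test_separable_surface_marginalizes_to_f_of_x(self):
        g = self._grid2d(lambda x, y: 2.0 * x**4 + 1.5 * y**2)
        m = F.marginalize_fes(g, "x", 310.0)
        want = 2.0 * m.centers[0] ** 4
        want -= want.min()
        assert np.allclose(m.free_energy, want, atol=1e-9)

    def test_undefined_rows_stay_undefined(self):
        g = self._grid2d(lambda x, y: x**2 + y**2)
        g.free_energy[3, :] = np.nan
        m = F.marginalize_fes(g, "x", 310.0)
        assert np.isnan(m.free_energy[3])


class TestBarrier:
    def _profile(self, edges, values):
        return F.FESGrid(("r",), [edges], np.asarray(values, float)).normalize()

    def test_hand_profile_peak_inside_window(self):
        edges = np.linspace(-5, 15, 201)
        x = 0.5 * (edges[1:] + edges[:-1])
        vals = 10.0 * np.exp(-0.5 * (x / 1.0) ** 2) + 20.0 * np.exp(-0.5 * ((x - 11.8) / 0.5) ** 2) * 0
        vals[np.argmin(np.abs(x - 11.8))] = -0.0
        prof = self._profile(edges, vals)
        b = F.barrier_height(prof, window=(-2.0, 3.0))
        assert b.value_kj == pytest.approx(prof.free_energy[np.argmin(np.abs(x))], abs=1e-9)
        assert b.value_kcal == pytest.approx(b.value_kj / 4.184)

    def test_window_max_not_global_max(self):
        edges = np.linspace(-5, 15, 101)
        x = 0.5 * (edges[1:] + edges[:-1])
        vals = np.where(x > 5, 30.0, 4.0)  # global max outside the window
        vals[0] = 0.0
        b = F.barrier_height(self._profile(edges, vals), window=(-2.0, 3.0))
        assert b.value_kj == pytest.approx(4.0)

    def test_monotone_profile_reports_boundary_bin(self):
        edges = np.linspace(-3, 4, 71)
        x = 0.5 * (edges[1:] + edges[:-1])
        b = F.barrier_height(self._profile(edges, 2.0 * x), window=(-2.0, 3.0))
        assert b.location == pytest.approx(x[x < 3.0].max())

    def test_window_outside_grid_is_an_error(self):
        edges = np.linspace(10, 20, 11)
        prof = self._profile(edges, np.zeros(10))
        with pytest.raises(ValueError):
            F.barrier_height(prof, window=(-2.0, 3.0))


class TestBlockStatistics:
    def test_identical_blocks_give_zero(self):
        assert F.block_standard_error([2.0, 2.0, 2.0, 2.0], 2) == 0.0

    def test_two_point_hand_value(self):
        # block means {1, 3}: SE = |1-3|/2 = 1
        assert F.block_standard_error([1, 1, 3, 3], 2) == pytest.approx(1.0)

    def test_iid_gaussian_matches_analytic(self):
        rng = np.random.default_rng(1)
        ses = [
            F.block_standard_error(rng.normal(0, 1, 1024), 2) for _ in range(1000)
        ]
        # E[SE] approximates sigma/sqrt(n) (chi-correction ~0.8 for 1 dof)
        assert np.mean(ses) == pytest.approx(1 / np.sqrt(1024), rel=0.25)

    def test_too_short_series_is_an_error(self):
        with pytest.raises(ValueError):
            F.block_standard_error([1.0], 2)

    def test_blocking_iid_flat_curve(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2.0, 2**14)
        res = F.flyvbjerg_petersen(x)
        assert res.converged
        assert res.plateau_se == pytest.approx(2.0 / np.sqrt(2**14), rel=0.1)
        assert res.n_eff == pytest.approx(2**14, rel=0.2)

    def test_blocking_ar1_inflated_se(self):
        rng = np.random.default_rng(3)
        phi, n = 0.9, 2**14
        eps = rng.normal(0, 1.0, n)
        y = np.empty(n)
        y[0] = eps[0] / np.sqrt(1 - phi**2)
        for i in range(1, n):
            y[i] = phi * y[i - 1] + eps[i]
        want = (1.0 / np.sqrt(1 - phi**2)) / np.sqrt(n) * np.sqrt((1 + phi) / (1 - phi))
        res = F.flyvbjerg_petersen(y)
        assert res.plateau_se == pytest.approx(want, rel=0.2)
        assert res.n_eff < n / 5  # strong correlation shrinks the sample

    def test_blocking_constant_series_zero_se(self):
        res = F.flyvbjerg_petersen(np.full(64, 3.0))
        assert res.plateau_se == 0.0

    def test_blocking_short_series_is_an_error(self):
        with pytest.raises(ValueError):
            F.flyvbjerg_petersen(np.arange(5.0))

    def test_decorrelated_samples_reduce_to_plateau_blocks(self):
        rng = np.random.default_rng(4)
        x = np.repeat(rng.normal(size=256), 8)  # perfectly correlated in runs of 8
        dec = F.decorrelated_samples(x)
        assert len(dec) <= 512


class TestWelch:
    def test_identical_samples(self):
        t, dof, p = F.welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_unequal_means(self):
        t, _, p = F.welch_t_test([0.0, 0, 0, 0], [1.0, 1, 1, 1])
        assert p == 0.0 and np.isinf(t)

    def test_zero_variance_equal_means(self):
        t, _, p = F.welch_t_test([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_three_vs_three(self):
        a = np.array([2.1, 2.5, 2.3])
        b = np.array([3.1, 3.5, 3.0])
        t, dof, p = F.welch_t_test(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va / 3 + vb / 3)
        dof_hand = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert dof == pytest.approx(dof_hand, rel=1e-12)
        from scipy.stats import t as tdist
        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), dof_hand), rel=1e-9)


class TestScaledTime:
    def test_uniform_fill_history_approaches_gamma_minus_one(self):
        # one near-uniform hill per event (sigma >> domain), heights tempered
        # by the accumulated uniform level: c(t) = V(t), slope -> gamma - 1
        p = F.WTMDParams(sigmas=(50.0,), walls=(None,))
        kdt = p.delta_t_energy
        hills, V, h0, dt = [], 0.0, 5.0, 0.5
        for n in range(1, 3001):
            h = h0 * np.exp(-V / kdt)
            hills.append(_hill(n * dt, 2.0, 50.0, h))
            V += h
        res = F.scaled_time_diagnostic(hills, p, grid_edges=[np.linspace(0, 4, 101)],
                                       fit_start_fraction=0.5)
        assert res["slope"] == pytest.approx(p.bias_factor - 1.0, abs=1.5)
        assert res["reliable"]

    def test_short_history_is_an_error(self):
        p = F.WTMDParams(sigmas=(0.1,), walls=(None,))
        hills = [_hill(t, 0.0, 0.1, 1.0) for t in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError):
            F.scaled_time_diagnostic(hills, p)

    def test_unconverged_early_segment_flagged(self):
        # linear (untempered) growth: c ~ t, log-log slope drifts -> unreliable
        p = F.WTMDParams(sigmas=(50.0,), walls=(None,))
        hills = [_hill(n * 0.5, 2.0, 50.0, 5.0) for n in range(1, 1001)]
        res = F.scaled_time_diagnostic(hills, p, grid_edges=[np.linspace(0, 4, 101)])
        assert not res["reliable"]


class TestHillsIO:
    def test_roundtrip(self, tmp_path):
        hills = [
            _hill(1.0, (0.1, 0.9), (0.1, 0.01), 2.5, 0),
            _hill(1.0, (-0.4, 0.2), (0.1, 0.01), 2.1, 1),
        ]
        p = tmp_path / "HILLS"
        F.write_hills(hills, p, ["r_lxs", "q"])
        back = F.read_hills(p)
        assert len(back) == 2
        assert back[1].walker == 1
        assert back[0].center == pytest.approx(hills[0].center)
        assert back[0].sigma == pytest.approx(hills[0].sigma)

    def test_missing_header_is_an_error(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("1.0 0.1 0.1 2.5 0\n")
        with pytest.raises(ValueError):
            F.read_hills(p)


class TestFESGrid:
    def test_normalize_sets_min_to_zero(self):
        g = F.FESGrid(("x",), [np.linspace(0, 1, 6)], np.array([3.0, 2, 5, np.nan, 4]))
        g.normalize()
        assert np.nanmin(g.free_energy) == 0.0

    def test_kcal_conversion(self):
        g = F.FESGrid(("x",), [np.linspace(0, 1, 3)], np.array([0.0, 4.184]))
        assert g.free_energy_kcal[1] == pytest.approx(1.0)

    def test_text_output(self, tmp_path):
        g = F.FESGrid(("r",), [np.linspace(0, 1, 4)], np.array([0.0, 1.0, 2.0]),
                      error=np.array([0.1, 0.1, 0.2]))
        p = tmp_path / "fes.tsv"
        g.to_text(p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 3
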