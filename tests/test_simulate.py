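"""Binding model, fast-exchange shifts and spectrum rendering."""

from dataclasses import replace

import numpy as np
import pytest

from siapca import (
    PeakEntry,
    PeakList,
    PoolLabel,
    SimulationConfig,
    default_model,
    fraction_bound,
    render_spectrum,
    simulate_bound_peaklist,
    simulate_sia_experiment,
)
from siapca.errors import ConfigurationError, PlacementError
from siapca.simulate import BindingModel


def bisect_fraction_bound(P, R, K, lo=0.0, hi=1.0, iters=200):
    """Independent oracle: bisection on P·f² − (P+R+K)·f + R = 0."""
    g = lambda f: P * f * f - (P + R + K) * f + R
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(lo) * g(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestFractionBound:
    def test_limits(self):
        assert fraction_bound(100, 0, 5.0) == 0.0
        # saturation approaches 1 as sqrt(K/P): K = 1e-12 gives 1e-7 error
        assert fraction_bound(100, 100, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_case_against_closed_form(self):
        # P = R = K = 100: f = (3 - sqrt(5)) / 2 = 0.381966...
        assert fraction_bound(100, 100, 100) == pytest.approx(0.381966, abs=1e-6)

    def test_matches_bisection_oracle_on_random_triples(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            P = rng.uniform(1, 500)
            R = rng.uniform(0, 1000)
            K = 10 ** rng.uniform(-2, 3)
            assert fraction_bound(P, R, K) == pytest.approx(
                bisect_fraction_bound(P, R, K), abs=1e-9
            )

    def test_monotone_in_rna_and_kd(self):
        f = [fraction_bound(25, r, 10) for r in (0, 10, 25, 50, 100)]
        assert f == sorted(f)
        g = [fraction_bound(25, 25, k) for k in (1, 10, 100, 1000)]
        assert g == sorted(g, reverse=True)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fraction_bound(0, 10, 1)
        with pytest.raises(ValueError):
            fraction_bound(10, 10, 0)


def one_pool_model(kd, dmax=(0.03, -0.2)):
    return BindingModel(
        protein_conc=25.0,
        rna_ratio=1.0,
        kd_by_pool={(1, b): kd for b in "ACGU"},
        dmax_by_peak={"res1": dmax},
    )


class TestFastExchangeShifts:
    free = PeakList(
        [PeakEntry("res1", 8.0, 120.0, 1.0), PeakEntry("res2", 9.0, 115.0, 0.7)]
    )

    def test_no_binding_limit(self):
        out = simulate_bound_peaklist(self.free, one_pool_model(1e9), PoolLabel(1, "A"))
        for a, b in zip(out, self.free):
            assert a.delta_h == pytest.approx(b.delta_h, abs=1e-6)
            assert a.delta_n == pytest.approx(b.delta_n, abs=1e-6)

    def test_saturation_limit_lands_on_dmax(self):
        model = one_pool_model(1e-12)
        out = simulate_bound_peaklist(self.free, model, PoolLabel(1, "G"))
        moved = out.get("res1")
        assert moved.delta_h == pytest.approx(8.0 + 0.03, abs=1e-6)
        assert moved.delta_n == pytest.approx(120.0 - 0.2, abs=1e-6)
        # non-responsive peak untouched, intensities preserved
        assert out.get("res2") == self.free.get("res2")

    def test_displacement_ratio_equals_f_bound_ratio(self):
        m1, m2 = one_pool_model(10.0), one_pool_model(100.0)
        f1 = bisect_fraction_bound(25, 25, 10.0)
        f2 = bisect_fraction_bound(25, 25, 100.0)
        d1 = simulate_bound_peaklist(self.free, m1, PoolLabel(1, "A")).get("res1")
        d2 = simulate_bound_peaklist(self.free, m2, PoolLabel(1, "A")).get("res1")
        ratio = (d1.delta_h - 8.0) / (d2.delta_h - 8.0)
        assert ratio == pytest.approx(f1 / f2, rel=1e-9)
        assert abs(d1.delta_n - 120.0) > abs(d2.delta_n - 120.0)

    def test_fast_exchange_consistency(self):
        # observed displacement / dmax = f_bound exactly, per dimension
        model = one_pool_model(37.0)
        f = fraction_bound(25.0, 25.0, 37.0)
        out = simulate_bound_peaklist(self.free, model, PoolLabel(1, "C"))
        assert (out.get("res1").delta_h - 8.0) / 0.03 == pytest.approx(f, rel=1e-12)
        assert (out.get("res1").delta_n - 120.0) / -0.2 == pytest.approx(f, rel=1e-12)

    def test_missing_pool_kd_is_configuration_error(self):
        model = one_pool_model(10.0)
        with pytest.raises(ConfigurationError):
            simulate_bound_peaklist(self.free, model, PoolLabel(2, "A"))


class TestRendering:
    def test_single_peak_max_at_nearest_grid_point(self, small_config):
        cfg = replace(small_config, noise_sd=0.0)
        # sub-pixel offset: the maximum still lands on the nearest grid point
        h = cfg.axis_h.ppm_scale()[10] - 0.3 * cfg.axis_h.step
        n = cfg.axis_n.ppm_scale()[20] + 0.2 * cfg.axis_n.step
        spec = render_spectrum(PeakList([PeakEntry("p", h, n, 2.0)]), cfg)
        assert np.unravel_index(np.argmax(spec.intensities), spec.shape) == (10, 20)
        # exactly on-grid: the grid maximum equals the peak intensity
        on_grid = render_spectrum(
            PeakList([PeakEntry("p", cfg.axis_h.ppm_scale()[10], cfg.axis_n.ppm_scale()[20], 2.0)]),
            cfg,
        )
        assert on_grid.intensities[10, 20] == pytest.approx(2.0, rel=1e-12)

    def test_rendering_is_deterministic_given_seed(self, small_config):
        peaks = PeakList([PeakEntry("p", 8.0, 120.0, 1.0)])
        a = render_spectrum(peaks, small_config, seed=123)
        b = render_spectrum(peaks, small_config, seed=123)
        assert np.array_equal(a.intensities, b.intensities)
        c = render_spectrum(peaks, small_config, seed=124)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_linearity_in_scale_and_intensity(self, noiseless_small_config):
        cfg = noiseless_small_config
        peaks = PeakList([PeakEntry("p", 8.0, 120.0, 1.0), PeakEntry("q", 9.5, 112.0, 0.5)])
        full = render_spectrum(peaks, cfg, intensity_scale=1.0)
        scaled = render_spectrum(peaks, cfg, intensity_scale=0.8)
        assert np.allclose(scaled.intensities, 0.8 * full.intensities, rtol=0, atol=1e-14)
        double = PeakList(
            [PeakEntry("p", 8.0, 120.0, 2.0), PeakEntry("q", 9.5, 112.0, 1.0)]
        )
        assert np.allclose(
            render_spectrum(double, cfg).intensities, 2 * full.intensities, atol=1e-13
        )

    def test_off_grid_peak_names_the_peak(self, small_config):
        peaks = PeakList([PeakEntry("stray", 42.0, 120.0, 1.0)])
        with pytest.raises(PlacementError, match="stray"):
            render_spectrum(peaks, small_config)


class TestFullExperiment:
    def test_structure_and_grid(self, small_config):
        sim = simulate_sia_experiment(small_config)
        assert sorted(sim.stacks) == [1, 2]
        for stack in sim.stacks.values():
            assert len(stack.planes()) == 5
            assert stack.shape == (64, 48)

    def test_equal_kds_give_identical_bound_planes(self, noiseless_small_config):
        cfg = replace(
            noiseless_small_config,
            dilution_factor=1.0,
            kd_ladder=(10.0, 10.0, 10.0, 10.0),
            profile={1: ("A", "C", "G", "U")},
        )
        sim = simulate_sia_experiment(cfg)
        planes = [sim.stacks[1].bound[b].intensities for b in "ACGU"]
        for other in planes[1:]:
            assert np.array_equal(planes[0], other)

    def test_preferred_base_moves_plane_farthest(self, noiseless_small_config):
        cfg = replace(noiseless_small_config, dilution_factor=1.0)
        sim = simulate_sia_experiment(cfg)
        free = sim.stacks[1].reference.intensities
        dist = {
            b: np.linalg.norm(sim.stacks[1].bound[b].intensities - free) for b in "ACGU"
        }
        assert max(dist, key=dist.get) == "G"  # position-1 profile is G > U > C > A
        order = sorted(dist, key=dist.get, reverse=True)
        assert order == list(sim.true_ranking(1))

    def test_distinct_noise_per_plane_but_reproducible(self, small_config):
        sim1 = simulate_sia_experiment(small_config)
        sim2 = simulate_sia_experiment(small_config)
        a = sim1.stacks[1]
        assert not np.array_equal(a.bound["A"].intensities, a.bound["C"].intensities)
        for b in "ACGU":
            assert np.array_equal(
                sim1.stacks[1].bound[b].intensities, sim2.stacks[1].bound[b].intensities
            )

    def test_ground_truth_f_bound_matches_binding_oracle(self, small_config):
        sim = simulate_sia_experiment(small_config)
        for (pos, base), f in sim.f_bound.items():
            kd = small_config.kd_by_pool()[(pos, base)]
            assert f == pytest.approx(bisect_fraction_bound(25.0, 25.0, kd), abs=1e-9)

    def test_default_grid_is_290_by_256(self):
        cfg = SimulationConfig()
        assert cfg.grid == (290, 256)
        assert cfg.n_peaks == 100 and cfg.responsive_fraction == 0.3
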