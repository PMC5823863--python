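"""Generators: physical consistency, determinism, and stated-world defaults."""

import numpy as np
import pandas as pd
import pytest

from micropk import correlator, fcs_models
from micropk.quantify import AVOGADRO
from micropk.synthetic import (BindingGeneratorConfig, GradientGeneratorConfig,
                               MembraneSimConfig, SolutionSimConfig,
                               analytic_acf, generate_association_timecourses,
                               generate_gradient_dataset,
                               generate_saturation_dataset, gradient_true_mean,
                               simulate_membrane_trace, simulate_solution_trace)

from conftest import V_BOX_L, V_EFF_L, realized_n_eff_3d

SHORT = dict(duration=2.0, bin_width=1e-5)  # cheap traces for statistics


class TestConfigValidation:
    def test_box_scale_floor(self):
        with pytest.raises(ValueError, match="box_scale"):
            SolutionSimConfig(box_scale=2.0)

    def test_duration_must_span_bins(self):
        with pytest.raises(ValueError, match="1000 bins"):
            SolutionSimConfig(duration=1e-3, bin_width=1e-5)

    def test_gradient_ordering(self):
        with pytest.raises(ValueError, match="c_near"):
            GradientGeneratorConfig(c_near=1.0, c_bulk=2.0)

    def test_binding_positivity(self):
        with pytest.raises(ValueError):
            BindingGeneratorConfig(kd=-1.0)

    def test_resource_guard(self):
        cfg = SolutionSimConfig(concentration=5e4, duration=30.0, bin_width=1e-6)
        with pytest.raises(ValueError, match="resource guard"):
            simulate_solution_trace(cfg)


class TestSolutionTrace:
    def test_zero_brightness_gives_pure_background(self):
        cfg = SolutionSimConfig(brightness_eps=0.0, background_rate=5e3, **SHORT)
        trace = simulate_solution_trace(cfg)
        lam = 5e3 * cfg.bin_width
        assert trace.counts.mean() == pytest.approx(lam, rel=0.05)
        assert trace.counts.var() == pytest.approx(lam, rel=0.1)

    def test_deterministic_given_seed(self):
        cfg = SolutionSimConfig(seed=123, **SHORT)
        t1 = simulate_solution_trace(cfg)
        t2 = simulate_solution_trace(cfg)
        assert np.array_equal(t1.counts, t2.counts)
        t3 = simulate_solution_trace(SolutionSimConfig(seed=124, **SHORT))
        assert not np.array_equal(t1.counts, t3.counts)

    def test_mean_rate_matches_brightness_times_particle_number(self):
        """<rate> = cpm * N_eff + background, within 3 MC SDs over 20 seeds."""
        rates, n_effs = [], []
        for seed in range(20):
            cfg = SolutionSimConfig(concentration=20.0, seed=seed,
                                    background_rate=1e3, **SHORT)
            tr = simulate_solution_trace(cfg)
            rates.append(tr.mean_rate)
            n_effs.append(realized_n_eff_3d(tr))
        expected = 30e3 * np.asarray(n_effs) + 1e3
        resid = np.asarray(rates) / expected - 1
        assert abs(resid.mean()) < 3 * resid.std(ddof=1) / np.sqrt(len(resid))

    def test_intensity_linear_in_concentration(self):
        """Doubling concentration doubles the mean rate (MC-averaged)."""
        r1 = np.mean([simulate_solution_trace(
            SolutionSimConfig(concentration=10.0, seed=s, **SHORT)).mean_rate
            for s in range(12)])
        r2 = np.mean([simulate_solution_trace(
            SolutionSimConfig(concentration=20.0, seed=100 + s, **SHORT)).mean_rate
            for s in range(12)])
        assert r2 / r1 == pytest.approx(2.0, rel=0.12)

    def test_acf_matches_analytic_model(self):
        """Simulated single-species ACF tracks the 3D diffusion law:
        max |dG|/G(0) <= 0.1 (8-s trace; scaled down from a 20-s read)."""
        cfg = SolutionSimConfig(concentration=20.0, duration=8.0, seed=5)
        tr = simulate_solution_trace(cfg)
        acf = correlator.multitau_autocorrelate(tr, n_segments=0)
        n_eff = realized_n_eff_3d(tr)
        tau_d = (0.2e-6) ** 2 / (4 * cfg.diffusion_coeff)
        model = fcs_models.FCSModelSpec.single_3d(n_eff, tau_d, 5.0)
        g_true = fcs_models.eval_model(model, acf.lags)
        keep = acf.lags <= 0.1  # sampling noise dominates the deep tail
        dev = np.abs(acf.g_values[keep] - g_true[keep]) / (1.0 / n_eff)
        assert dev.max() <= 0.1


class TestMembraneTrace:
    def test_zero_surface_density_reduces_to_solution(self):
        cfg = MembraneSimConfig(surface_density=0.0, seed=7, **SHORT)
        trace = simulate_membrane_trace(cfg)
        assert trace.metadata["n_particles_2d"] == 0
        sol = simulate_solution_trace(SolutionSimConfig(seed=7, **SHORT))
        assert trace.counts.mean() == pytest.approx(sol.counts.mean(), rel=0.25)

    def test_pure_2d_dwell_time_recovered(self):
        """2D-only trace fits the planar diffusion law with tauD = w0^2/4D
        within 20%."""
        cfg = MembraneSimConfig(concentration=1e-12, duration=20.0,
                                bin_width=2e-5, seed=3, surface_density=2e12,
                                brightness_ratio=1.0)
        tr = simulate_membrane_trace(cfg)
        assert tr.metadata["n_particles_3d"] == 0
        acf = correlator.multitau_autocorrelate(tr)
        res = fcs_models.fit_acf(acf, fcs_models.FCSModelSpec.single_2d(1.0, 1e-3))
        tau_true = (0.2e-6) ** 2 / (4 * cfg.diffusion_coeff_2d)
        assert res.model.components[0].tau_d == pytest.approx(tau_true, rel=0.2)


class TestAnalyticACF:
    def test_zero_lag_amplitude(self):
        m = fcs_models.FCSModelSpec.single_3d(4.0, 1e-4, 5.0)
        acf = analytic_acf(m, [1e-9, 1e-4])
        assert acf.g_values[0] == pytest.approx(0.25, rel=1e-4)

    def test_values_match_eval_model(self):
        m = fcs_models.FCSModelSpec.membrane(1.0, 1e-4, [1e-2], [0.5])
        lags = np.geomspace(1e-6, 1.0, 30)
        np.testing.assert_array_equal(analytic_acf(m, lags).g_values,
                                      fcs_models.eval_model(m, lags))


class TestGradientGenerator:
    def test_noise_free_reference_point(self):
        cfg = GradientGeneratorConfig(noise_cv=0.0, d_cv=0.0, n_cells=2, seed=0)
        df = generate_gradient_dataset(cfg)
        at_ref = df[(df.condition == "receptor_high") & (df.distance_um == 2)
                    & (df.time_min == 120)]
        assert np.allclose(at_ref.conc_nM, 45.7)

    def test_far_field_approaches_bulk(self):
        cfg = GradientGeneratorConfig(noise_cv=0.0, d_cv=0.0, n_cells=1)
        assert gradient_true_mean(cfg, "receptor_high", 2000.0, 120.0) \
            == pytest.approx(1.5, rel=1e-4)

    def test_monotone_in_distance_and_time(self):
        cfg = GradientGeneratorConfig(n_cells=1)
        for condition in ("receptor_high", "receptor_none"):
            means_z = [gradient_true_mean(cfg, condition, z, 120.0)
                       for z in cfg.distances]
            assert np.all(np.diff(means_z) <= 0)
            means_t = [gradient_true_mean(cfg, condition, 2.0, t)
                       for t in cfg.timepoints]
            assert np.all(np.diff(means_t) >= -1e-12)

    def test_printed_near_and_far_values_within_two_sem(self):
        """Defaults reproduce the receptor-expressing profile endpoints:
        2-um mean near 45.7 nM and 200-um mean near 1.5 nM (n = 13)."""
        df = generate_gradient_dataset(GradientGeneratorConfig(seed=2))
        final = df[(df.condition == "receptor_high") & (df.time_min == 120)]
        for dist, printed in ((2.0, 45.7), (200.0, 1.5)):
            vals = final[final.distance_um == dist].conc_nM
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert len(vals) == 13
            assert abs(vals.mean() - printed) <= 2 * sem

    def test_seed_reproducibility_and_cell_stream_stability(self):
        base = GradientGeneratorConfig(n_cells=4, seed=9)
        df1 = generate_gradient_dataset(base)
        df2 = generate_gradient_dataset(base)
        pd.testing.assert_frame_equal(df1, df2)
        bigger = generate_gradient_dataset(
            base.model_copy(update={"n_cells": 6}))
        for cond in base.conditions:
            old = df1[df1.condition == cond].reset_index(drop=True)
            new = bigger[(bigger.condition == cond)
                         & bigger.cell_id.isin(old.cell_id.unique())]
            pd.testing.assert_frame_equal(old, new.reset_index(drop=True))


class TestBindingGenerators:
    def test_half_saturation_at_kd(self):
        cfg = BindingGeneratorConfig(noise_sd=0.0, ligand_concs=(1.8, 18.0),
                                     times=tuple(np.arange(0, 2000.0, 10.0)))
        courses = generate_association_timecourses(cfg)
        at_kd = courses[0]
        assert at_kd.specific[-1] == pytest.approx(cfg.bmax_signal / 2, rel=1e-3)

    def test_observed_rate_doubles_koff_at_kd(self):
        cfg = BindingGeneratorConfig()
        assert cfg.kon_per_nm * cfg.kd + cfg.koff == pytest.approx(2 * cfg.koff)

    def test_implied_kon_matches_printed_rates(self):
        # koff 0.04 /min over Kd 1.8 nM -> kon = 2.22e7 /M/min
        cfg = BindingGeneratorConfig()
        assert cfg.kon_per_nm * 1e9 == pytest.approx(2.22e7, rel=1e-2)

    def test_nsb_series_is_linear_offset(self):
        cfg = BindingGeneratorConfig(noise_sd=0.0)
        for c in generate_association_timecourses(cfg):
            assert np.allclose(c.ratio_nsb,
                               cfg.baseline + cfg.ns_slope * c.ligand_conc)

    def test_saturation_half_point_and_range_check(self):
        cfg = BindingGeneratorConfig(noise_sd=0.0)
        data = generate_saturation_dataset(cfg, concs=[0.01, 0.1, 0.6, 1.8, 6, 30, 300])
        at_kd = np.searchsorted(data.ligand_concs, 1.8)
        assert data.specific[at_kd] == pytest.approx(cfg.bmax_signal / 2, rel=1e-6)
        with pytest.raises(ValueError, match="span Kd"):
            generate_saturation_dataset(cfg, concs=[10, 30, 100])

    def test_generators_deterministic(self):
        cfg = BindingGeneratorConfig(seed=4)
        a = generate_association_timecourses(cfg)
        b = generate_association_timecourses(cfg)
        assert all(np.array_equal(x.ratio_total, y.ratio_total)
                   for x, y in zip(a, b))
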