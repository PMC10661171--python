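"""Rate-network model tests (reduced problem sizes; directions at scale
are exercised by the acceptance suite)."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from timescales import (
    DivergenceError,
    ModelConfig,
    StimulusSpec,
    hierarchy_to_fln,
    region_wilcoxon_summary,
    run_condition_set,
    simulate,
)
from timescales.model import REGIONS, acw0_from_rates, default_hierarchy


def single_region_config(**kwargs):
    base = dict(
        h=np.array([0.0]), fln=np.zeros((1, 1)), duration=4.0, discard=3.0,
        noise_sd_input=0.0, noise_sd_other=0.0,
    )
    base.update(kwargs)
    return ModelConfig(**base)


class TestHierarchyToFln:
    def test_equal_hierarchy_gives_logistic_offset(self):
        h = np.full(3, 0.5)
        fln = hierarchy_to_fln(h, logistic_slope=3.0, logistic_offset=0.4, scale=2.0)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(fln[off], 2.0 * expit(0.4))

    def test_asymptotes_bracketed(self):
        fln = hierarchy_to_fln(np.array([0.0, 1.0]), logistic_slope=20.0, scale=1.0)
        assert fln[1, 0] > 0.99  # feedforward (low -> high) saturates high
        assert fln[0, 1] < 0.01

    def test_matches_elementwise_closed_form(self, rng):
        h = rng.uniform(size=5)
        slope, offset, scale = 1.7, -0.3, 0.08
        fln = hierarchy_to_fln(h, slope, offset, scale)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else scale / (
                    1 + np.exp(-(slope * (h[i] - h[j]) + offset))
                )
                assert fln[i, j] == pytest.approx(expected, abs=1e-14)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            hierarchy_to_fln(np.array([0.0, 1.0]), logistic_slope=np.inf)


class TestSimulate:
    def test_zero_input_fixed_point_is_zero(self):
        run = simulate(single_region_config(), seed=0)
        assert np.abs(run.rates_E).max() == 0.0

    def test_single_region_matches_linear_fixed_point(self):
        cfg = single_region_config(background_E=10.0, background_I=5.0)
        run = simulate(cfg, seed=0)
        # solve the 2x2 linear system (rectification inactive at the root)
        a_mat = np.array(
            [
                [1 - cfg.beta_E * cfg.w_EE, cfg.beta_E * cfg.w_EI],
                [-cfg.beta_I * cfg.w_IE, 1 + cfg.beta_I * cfg.w_II],
            ]
        )
        rhs = np.array([cfg.beta_E * cfg.background_E, cfg.beta_I * cfg.background_I])
        v_fix = np.linalg.solve(a_mat, rhs)
        assert abs(run.rates_E[-1, 0] - v_fix[0]) < 1e-8

    def test_same_seed_bitwise_identical(self):
        cfg = ModelConfig(duration=2.0, discard=1.0)
        r1 = simulate(cfg, seed=11)
        r2 = simulate(cfg, seed=11)
        assert np.array_equal(r1.rates_E, r2.rates_E)

    def test_divergence_detected(self):
        # pathological self-excitation must raise, not silently overflow
        cfg = single_region_config(w_EE=1e4, background_E=10.0, duration=2.0, discard=1.0)
        with pytest.raises(DivergenceError):
            simulate(cfg, seed=0)

    def test_hierarchy_of_timescales(self):
        # V1 (bottom) decorrelates faster than the top of the hierarchy
        wins = 0
        for seed in range(5):
            run = simulate(ModelConfig(duration=40.0, discard=5.0), seed=seed)
            wins += run.acw0_ms[0] < np.nanmean(run.acw0_ms[-3:])
        assert wins >= 4


class TestStimulusSpec:
    def test_waveform_kinds(self):
        t = np.linspace(0, 1, 1001)
        assert np.allclose(StimulusSpec("none").waveform(t, 0.0, 1.0), 0.0)
        sine = StimulusSpec("sine", freqs=(25.0,)).waveform(t, 0.0, 1.0)
        assert np.max(sine) <= 1.0 and np.ptp(sine) > 1.9
        multi = StimulusSpec("multisine", freqs=(25.0, 50.0, 75.0)).waveform(t, 0.0, 1.0)
        assert np.ptp(multi) > np.ptp(sine)

    def test_chirp_sweeps_range(self):
        spec = StimulusSpec("chirp", chirp_range=(20.0, 100.0))
        dt = 1e-4
        t = np.arange(0, 10.0, dt)
        w = spec.waveform(t, discard=2.0, duration=10.0)
        # crude instantaneous-frequency check via zero crossings
        early = w[(t > 2.0) & (t < 3.0)]
        late = w[(t > 9.0) & (t < 10.0)]
        f_early = np.sum(np.diff(np.sign(early)) != 0) / 2
        f_late = np.sum(np.diff(np.sign(late)) != 0) / 2
        assert 15 < f_early < 40
        assert 80 < f_late < 110

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec("sine", freqs=())
        with pytest.raises(ValueError):
            StimulusSpec("chirp", chirp_range=(100.0, 20.0))
        with pytest.raises(ValueError):
            StimulusSpec("square")


@pytest.fixture(scope="module")
def short_tables():
    cfg = ModelConfig(duration=30.0, discard=5.0)
    return run_condition_set(cfg, scenario="sine25", n_runs=4, seed=3)


class TestRunConditionSet:
    def test_deterministic_tables(self, short_tables):
        cfg = ModelConfig(duration=30.0, discard=5.0)
        again = run_condition_set(cfg, scenario="sine25", n_runs=4, seed=3)
        for cond in short_tables:
            pd.testing.assert_frame_equal(short_tables[cond], again[cond])

    def test_shapes_and_names(self, short_tables):
        for table in short_tables.values():
            assert table.shape == (4, 29)
            assert list(table.columns) == list(REGIONS)

    def test_sleep_slows_every_region(self, short_tables):
        med_awake = short_tables["awake"].median(axis=0)
        med_sleep = short_tables["sleep_rest"].median(axis=0)
        assert (med_sleep > med_awake).all()

    def test_stimulus_shortens_v1(self, short_tables):
        med_rest = short_tables["sleep_rest"].median(axis=0)
        med_stim = short_tables["sleep_stim"].median(axis=0)
        assert med_stim["V1"] < med_rest["V1"]
        assert (med_stim < med_rest).sum() > 0

    def test_dt_robustness_on_coupled_noise_paths(self):
        # halving the integration step barely moves the timescale estimates
        # when both resolutions are driven by the same continuous noise path
        # (the coarse step injects the average of its two fine-step currents)
        from timescales.model import _integrate_batch

        rng = np.random.default_rng(77)
        cfg_fine = ModelConfig(duration=60.0, discard=10.0, dt=5e-4)
        cfg_coarse = ModelConfig(duration=60.0, discard=10.0, dt=1e-3)
        n = cfg_fine.n_regions
        n_runs = 10
        steps_fine = int(round(cfg_fine.duration / cfg_fine.dt))
        sd = np.full(n, cfg_fine.noise_sd_other)
        sd[0] = cfg_fine.noise_sd_input
        fine_noise = rng.standard_normal((steps_fine, n_runs, n)) * sd
        coarse_noise = 0.5 * (fine_noise[0::2] + fine_noise[1::2])
        fine = _integrate_batch(cfg_fine, None, list(range(n_runs)), noise_array=fine_noise)
        coarse = _integrate_batch(cfg_coarse, None, list(range(n_runs)), noise_array=coarse_noise)
        acw_fine = np.median(
            [acw0_from_rates(fine[:, j, :], cfg_fine.dt) for j in range(n_runs)], axis=0
        )
        acw_coarse = np.median(
            [acw0_from_rates(coarse[:, j, :], cfg_coarse.dt) for j in range(n_runs)], axis=0
        )
        rel = np.abs(acw_fine - acw_coarse) / acw_coarse
        # bulk of the regions' median windows move by well under 10%; a few
        # regions whose autocorrelation grazes zero flip their first
        # crossing between distant lags, so an all-region bound would test
        # the discontinuity of the statistic, not the integrator
        assert np.median(rel) < 0.10
        # the coupled trajectories themselves stay close in every region
        for j in range(n_runs):
            for r in range(0, cfg_fine.n_regions, 7):
                c = np.corrcoef(
                    fine[::2, j, r].astype(float), coarse[:, j, r].astype(float)
                )[0, 1]
                assert c > 0.85


class TestRegionWilcoxon:
    def test_no_change_no_significance(self, rng):
        rest = pd.DataFrame(rng.standard_normal((30, 5)) + 100, columns=list("abcde"))
        out = region_wilcoxon_summary(rest, rest.copy())
        assert out.attrs["n_significant_decrease"] == 0

    def test_designated_decreases_detected(self, rng):
        rest = pd.DataFrame(rng.standard_normal((30, 10)) + 100,
                            columns=[f"r{i}" for i in range(10)])
        stim = rest.copy()
        for col in list(stim.columns[:6]):
            stim[col] = stim[col] - 5.0
        out = region_wilcoxon_summary(rest, stim)
        assert out.attrs["n_significant_decrease"] == 6
        sig = out[out["significant"] & (out["direction"] == "decrease")]["region"]
        assert sorted(sig) == [f"r{i}" for i in range(6)]

    def test_shape_mismatch(self, rng):
        rest = pd.DataFrame(rng.standard_normal((10, 3)))
        stim = pd.DataFrame(rng.standard_normal((9, 3)))
        with pytest.raises(ValueError):
            region_wilcoxon_summary(rest, stim)


class TestAcw0FromRates:
    def test_agrees_with_scalar_estimator(self, rng):
        from timescales import acf_with_acw

        x = rng.standard_normal((500, 3)).cumsum(axis=0)  # slow random walks
        got = acw0_from_rates(x, dt=1e-3)
        for j in range(3):
            expected = acf_with_acw(x[:, j], dt=1e-3).acw0
            if np.isnan(expected):
                assert np.isnan(got[j])
            else:
                assert got[j] == pytest.approx(expected * 1e3)
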