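"""Reference-frame analysis: kernel fits, PRESS selection, tuning test."""

import numpy as np
import pandas as pd
import pytest

from alloego import Canvas
from alloego.datasets import NeuroConfig, TrialDataset
from alloego.units import (CANONICAL_MODELS, DEFAULT_KW_GRID,
                           ResponseFieldSample, continuum_positions,
                           ego_allo_correlation, fit_canonical,
                           fit_continuum, loo_kernel_fit,
                           map_response_fields, model_positions,
                           population_summary, press_statistic,
                           spatial_tuning_test)


def brute_force_loo(positions, activities, kw):
    n = len(positions)
    out = np.empty(n)
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            if j == i:
                continue
            w = np.exp(-np.sum((positions[i] - positions[j]) ** 2) / kw)
            num += activities[j] * w
            den += w
        out[i] = num / den
    return out


def make_dataset(rng, n=120, zero_shift=False):
    """Protocol-like trial table for planting synthetic units."""
    target = rng.uniform(-30, 30, (n, 2))
    offs = np.array([[7.78, 7.78], [-7.78, 7.78],
                     [-7.78, -7.78], [7.78, -7.78]])
    landmark = target + offs[rng.integers(4, size=n)]
    ang = rng.integers(8, size=n) * np.pi / 4
    shift = np.zeros((n, 2)) if zero_shift else \
        8.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    gaze0 = rng.uniform(-10, 10, (n, 2))
    gaze_final = target + 0.33 * shift + rng.normal(0, 2.0, (n, 2))
    return TrialDataset(target=target, landmark=landmark, shift=shift,
                        gaze0=gaze0, gaze_final=gaze_final,
                        split=np.zeros(n, dtype=np.int8),
                        canvas=Canvas(64, 100.0))


def plant_unit(rng, positions, width=12.0, noise=0.0):
    c = rng.uniform(-20, 20, 2)
    act = np.exp(-np.sum((positions - c) ** 2, axis=1) / (2 * width ** 2))
    return act + noise * rng.normal(size=len(positions))


class TestKernelFit:
    def test_matches_brute_force_to_1e12(self, rng):
        pos = rng.uniform(-20, 20, (50, 2))
        act = rng.uniform(0, 1, 50)
        for kw in (4.0, 36.0, 400.0):
            fast = loo_kernel_fit(pos, act, kw)
            slow = brute_force_loo(pos, act, kw)
            assert np.allclose(fast, slow, atol=1e-12)

    def test_constant_activity_predicted_exactly(self, rng):
        pos = rng.uniform(-20, 20, (30, 2))
        act = np.full(30, 0.42)
        assert np.allclose(loo_kernel_fit(pos, act, 16.0), 0.42)

    def test_infinite_bandwidth_gives_loo_mean(self, rng):
        pos = rng.uniform(-5, 5, (20, 2))
        act = rng.uniform(0, 1, 20)
        pred = loo_kernel_fit(pos, act, 1e12)
        loo_mean = (act.sum() - act) / 19.0
        assert np.allclose(pred, loo_mean, atol=1e-8)

    def test_multi_unit_matches_per_unit(self, rng):
        pos = rng.uniform(-20, 20, (25, 2))
        A = rng.uniform(0, 1, (25, 3))
        joint = loo_kernel_fit(pos, A, 36.0)
        for u in range(3):
            assert np.allclose(joint[:, u],
                               loo_kernel_fit(pos, A[:, u], 36.0))

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            loo_kernel_fit(np.zeros((1, 2)), np.zeros(1), 4.0)
        with pytest.raises(ValueError):
            loo_kernel_fit(np.zeros((5, 2)), np.zeros(5), 0.0)


class TestModelPositions:
    def test_eye_frame_identity(self, rng):
        ds = make_dataset(rng)
        assert np.allclose(model_positions(ds, "Te"),
                           model_positions(ds, "Ts") - ds.gaze0)
        assert np.allclose(model_positions(ds, "L'e"),
                           model_positions(ds, "L's") - ds.gaze0)

    def test_zero_shift_merges_primed_models(self, rng):
        ds = make_dataset(rng, zero_shift=True)
        assert np.allclose(model_positions(ds, "Te"),
                           model_positions(ds, "T'e"))
        assert np.allclose(continuum_positions(ds, "TTp", 0),
                           continuum_positions(ds, "TTp", 10))

    def test_continuum_endpoints(self, rng):
        ds = make_dataset(rng)
        assert np.allclose(continuum_positions(ds, "TG", 0),
                           model_positions(ds, "Te"))
        assert np.allclose(continuum_positions(ds, "TG", 10),
                           model_positions(ds, "Gfe"))
        assert np.allclose(continuum_positions(ds, "TTp", 10),
                           model_positions(ds, "T'e"))

    def test_unknown_model_rejected(self, rng):
        ds = make_dataset(rng)
        with pytest.raises(KeyError):
            model_positions(ds, "Xx")


class TestPressSelection:
    def test_planted_canonical_model_recovered(self, rng):
        ds = make_dataset(rng, n=150)
        pos = model_positions(ds, "Te")
        A = np.column_stack([plant_unit(rng, pos, noise=0.02)
                             for _ in range(40)])
        sample = ResponseFieldSample(ds, A)
        fits, _ = fit_canonical(sample)
        assert (fits["best_model"] == "Te").mean() >= 0.95

    def test_planted_gaze_model_recovered(self, rng):
        ds = make_dataset(rng, n=150)
        pos = model_positions(ds, "Gfe")
        A = np.column_stack([plant_unit(rng, pos, noise=0.02)
                             for _ in range(20)])
        fits, _ = fit_canonical(ResponseFieldSample(ds, A))
        assert (fits["best_model"] == "Gfe").mean() >= 0.95

    def test_planted_continuum_step_recovered(self, rng):
        ds = make_dataset(rng, n=200)
        pos = continuum_positions(ds, "TTp", 3)
        A = np.column_stack([plant_unit(rng, pos, noise=0.01)
                             for _ in range(25)])
        fits, _ = fit_continuum(ResponseFieldSample(ds, A), "TTp")
        steps = fits["best_step"].astype(int).to_numpy()
        assert np.all(np.abs(steps - 3) <= 1)
        assert np.median(steps) == 3

    def test_duplicate_trials_leave_argmin_unchanged(self, rng):
        ds = make_dataset(rng, n=80)
        pos = model_positions(ds, "Te")
        A = plant_unit(rng, pos, noise=0.02)[:, None]
        base, _ = fit_canonical(ResponseFieldSample(ds, A))

        dup = TrialDataset(
            target=np.concatenate([ds.target, ds.target]),
            landmark=np.concatenate([ds.landmark, ds.landmark]),
            shift=np.concatenate([ds.shift, ds.shift]),
            gaze0=np.concatenate([ds.gaze0, ds.gaze0]),
            gaze_final=np.concatenate([ds.gaze_final, ds.gaze_final]),
            split=np.zeros(160, dtype=np.int8), canvas=ds.canvas)
        dupfit, _ = fit_canonical(
            ResponseFieldSample(dup, np.concatenate([A, A])))
        assert dupfit["best_model"][0] == base["best_model"][0]


class TestSpatialTuning:
    def test_planted_unit_is_tuned_noise_unit_is_not(self, rng):
        ds = make_dataset(rng, n=120)
        pos = model_positions(ds, "Te")
        tuned_act = plant_unit(rng, pos, noise=0.02)
        noise_act = rng.uniform(0, 1, 120)
        A = np.column_stack([tuned_act, noise_act])
        sample = ResponseFieldSample(ds, A)
        fits, _ = fit_canonical(sample)
        sets = [model_positions(ds, m) for m in CANONICAL_MODELS]
        out = spatial_tuning_test(sample, fits, sets,
                                  rng=np.random.default_rng(0))
        assert bool(out.loc[0, "tuned"]) is True
        assert bool(out.loc[1, "tuned"]) is False

    def test_verdict_deterministic_given_seed(self, rng):
        ds = make_dataset(rng, n=80)
        pos = model_positions(ds, "Te")
        A = np.column_stack([plant_unit(rng, pos, noise=0.3)
                             for _ in range(5)])
        sample = ResponseFieldSample(ds, A)
        fits, _ = fit_canonical(sample)
        sets = [model_positions(ds, m) for m in CANONICAL_MODELS]
        runs = [spatial_tuning_test(sample, fits, sets,
                                    rng=np.random.default_rng(9))["tuned"]
                for _ in range(2)]
        assert runs[0].equals(runs[1])


class TestPopulationStats:
    def test_identical_units_degenerate_summary(self, rng):
        press = pd.DataFrame({"Te": [0.1, 0.1, 0.1], "Ts": [0.1, 0.1, 0.1]})
        best = pd.Series(["Te", "Te", "Te"])
        out = population_summary(press, best)
        assert (out["p"] == 1.0).all()

    def test_worse_model_flagged(self, rng):
        n = 30
        press = pd.DataFrame({"Te": rng.uniform(0.01, 0.02, n)})
        press["Ts"] = press["Te"] + rng.uniform(0.05, 0.06, n)
        out = population_summary(press, pd.Series(["Te"] * n))
        row = out.set_index("model")
        assert row.loc["Ts", "p"] < 1e-6
        assert row.loc["Te", "n_best"] == n


class TestEgoAlloCorrelation:
    def test_collinear_fractions_give_unit_r2(self):
        x = np.linspace(0, 100, 20)
        out = ego_allo_correlation(x, 0.5 * x + 3)
        assert out["r2"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(0.5)

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0, 100, 10)
        y = rng.uniform(0, 100, 10)
        out = ego_allo_correlation(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        assert out["slope"] == pytest.approx(slope)
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(np.sum(resid ** 2) / 8.0 / sxx)
        assert out["slope_se"] == pytest.approx(se)

    def test_null_calibration(self):
        # independent fractions: slope near zero, mostly non-significant
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            out = ego_allo_correlation(r.uniform(0, 100, 50),
                                       r.uniform(0, 100, 50))
            hits += out["pvalue"] > 0.05
        assert hits >= 18

    def test_degenerate_regressor(self):
        out = ego_allo_correlation(np.full(10, 100.0),
                                   np.linspace(0, 30, 10))
        assert np.isnan(out["slope"]) and out["pvalue"] == 1.0


class _StubNet:
    """Minimal network stand-in: random motor rates, zero decoder."""

    def __init__(self, n_units=6):
        from alloego.codes import DecoderWeights, MotorCodeSpec
        self.n_units = n_units
        self.decoder_ = DecoderWeights(
            W=np.zeros((n_units, 2)), sigma_n2=0.01,
            spec=MotorCodeSpec(n_units=n_units))

    def motor_activity(self, ds):
        rng = np.random.default_rng(0)
        return rng.uniform(0.5, 1.0, (len(ds), self.n_units))


class TestResponseFieldMapping:
    def test_grid_probe_structure(self, canvas64):
        cfg = NeuroConfig(n_trials=200, seed=3, canvas=canvas64,
                          noise="none")
        sample = map_response_fields(_StubNet(), cfg, n_trials=200, seed=5)
        assert sample.activities.shape == (200, 6)
        ds = sample.dataset
        # eye-frame identity holds on the probe
        assert np.allclose(model_positions(ds, "Te"),
                           ds.target - ds.gaze0)
        # with a zero decoder, the model's gaze sits at fixation
        assert np.allclose(ds.gaze_final, ds.gaze0)

    def test_zero_shift_probe(self, canvas64):
        cfg = NeuroConfig(n_trials=100, seed=3, canvas=canvas64,
                          noise="none")
        sample = map_response_fields(_StubNet(), cfg, n_trials=100,
                                     seed=5, zero_shift=True)
        assert np.all(sample.dataset.shift == 0.0)
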