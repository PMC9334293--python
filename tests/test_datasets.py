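"""Synthetic dataset generators: weighting, noise, splits, determinism."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import curve_fit

from alloego import Canvas, NeuroConfig, ScenarioConfig, TrialDataset
from alloego.behavior import allocentric_weight
from alloego.datasets import (NoiseConfig, apply_image_noise,
                              generate_neuro_dataset,
                              generate_protocol_dataset, generate_scenario)


@pytest.fixture
def small_cfg(canvas64):
    return ScenarioConfig(allocentric_weight=0.3, n_trials=400, seed=7,
                          canvas=canvas64)


class TestScenarioWeighting:
    @pytest.mark.parametrize("w,expect", [(0.0, "target"), (1.0, "virtual")])
    def test_extreme_weights_land_exactly(self, canvas64, w, expect):
        ds = generate_scenario(ScenarioConfig(
            allocentric_weight=w, n_trials=200, seed=1, canvas=canvas64))
        ref = ds.target if expect == "target" else ds.target + ds.shift
        assert np.allclose(ds.gaze_final, ref)

    def test_intermediate_weight_recovered_exactly(self, small_cfg):
        # the AW projection of a noiseless w=0.3 dataset is 0.3 per trial
        ds = generate_scenario(small_cfg)
        aw = allocentric_weight(ds.gaze_final, ds.target, ds.shift)
        assert np.allclose(aw.values, 0.3)
        assert aw.mean == pytest.approx(0.3)

    def test_invalid_weight_rejected(self, canvas64):
        with pytest.raises(ValueError):
            ScenarioConfig(allocentric_weight=1.5, canvas=canvas64)

    def test_ranges_respected(self, small_cfg):
        ds = generate_scenario(replace(small_cfg, n_trials=2000))
        assert np.abs(ds.target).max() <= 50.0
        assert np.abs(ds.landmark).max() <= 40.0
        assert np.abs(ds.shift).max() <= 10.0
        assert np.abs(ds.gaze0).max() <= 10.0


class TestSplits:
    def test_proportions_and_disjointness(self, small_cfg):
        ds = generate_scenario(replace(small_cfg, n_trials=1000))
        tr, va, te = (ds.indices(s) for s in ("train", "val", "test"))
        assert len(tr) == 900 and len(va) == 50 and len(te) == 50
        assert len(np.intersect1d(tr, va)) == 0
        assert len(np.intersect1d(tr, te)) == 0

    def test_split_determinism(self, small_cfg):
        a = generate_scenario(small_cfg)
        b = generate_scenario(small_cfg)
        assert np.array_equal(a.split, b.split)
        assert np.allclose(a.gaze_final, b.gaze_final)


class TestImageNoise:
    def test_blur_preserves_mass_and_peak_location(self, rng):
        img = np.zeros((1, 64, 64), dtype=np.float32)
        img[0, 32, 30] = 1.0
        out = apply_image_noise(img, NoiseConfig(blur_sd=6.0), 3.125, rng)
        assert np.unravel_index(np.argmax(out[0]), (64, 64)) == (32, 30)
        assert out.sum() == pytest.approx(img.sum(), rel=0.05)

    def test_blurred_line_profile_sd(self, rng):
        # fit a Gaussian to a blurred 1-px line; SD should match the
        # configured blur in pixels
        canvas = Canvas(200, 100.0)
        img = np.zeros((1, 200, 200), dtype=np.float32)
        img[0, :, 100] = 1.0
        noise = NoiseConfig(blur_sd=10.0)
        out = apply_image_noise(img, noise, canvas.resolution, rng)
        profile = out[0, 100, :]
        x = np.arange(200.0)

        def gauss(x, a, mu, sd):
            return a * np.exp(-(x - mu) ** 2 / (2 * sd ** 2))

        (a, mu, sd), _ = curve_fit(gauss, x, profile, p0=[0.05, 100, 8])
        assert abs(sd) == pytest.approx(10.0, rel=0.05)

    def test_poisson_images_flag(self, rng):
        img = np.full((1, 32, 32), 0.5, dtype=np.float32)
        clean = apply_image_noise(img, NoiseConfig(blur_sd=1.0), 1.0, rng)
        noisy = apply_image_noise(
            img, NoiseConfig(blur_sd=1.0, poisson_images=True), 1.0, rng)
        assert np.std(noisy - clean) > 0.01  # Poisson branch engaged
        assert np.all(noisy >= 0.0)

    def test_noisy_rendering_deterministic(self, canvas64):
        cfg = ScenarioConfig(allocentric_weight=0.3, noise="high",
                             n_trials=64, seed=3, canvas=canvas64)
        a = generate_scenario(cfg)
        b = generate_scenario(cfg)
        for (ia, ea, da), (ib, eb, db) in zip(a.iter_images(32),
                                              b.iter_images(32)):
            assert np.array_equal(ea, eb) and np.array_equal(da, db)

    def test_gaze_noise_mean_preserving(self, canvas64):
        cfg = ScenarioConfig(allocentric_weight=0.0, noise="high",
                             n_trials=10_000, seed=5, canvas=canvas64)
        ds = generate_scenario(cfg)
        err = ds.gaze_final - ds.target
        mc_sem = cfg.noise_params.gaze_sd / np.sqrt(len(ds))
        assert np.all(np.abs(err.mean(axis=0)) < 5 * mc_sem)


class TestNeuroDataset:
    def test_grid_coverage(self, canvas64):
        cfg = NeuroConfig(n_trials=300, seed=2, canvas=canvas64)
        ds = generate_neuro_dataset(cfg)
        cells = {tuple(t) for t in ds.target}
        assert len(cells) == 49  # every 7x7 grid cell sampled

    def test_sampled_gaze_mean_matches_weighting(self, canvas64):
        cfg = NeuroConfig(n_trials=20_000, seed=2, canvas=canvas64,
                          zero_shift_fraction=0.0)
        ds = generate_neuro_dataset(cfg)
        expected = ds.target + 0.33 * ds.shift
        err = (ds.gaze_final - expected).mean(axis=0)
        tol = 5 * cfg.cue_sd / np.sqrt(len(ds))
        # gaze endpoint noise also contributes to the spread
        assert np.all(np.abs(err) < tol + 0.1)

    def test_zero_variance_limit_reduces_to_scenario_rule(self, canvas64):
        cfg = NeuroConfig(n_trials=500, seed=2, canvas=canvas64,
                          sigma_ego=1e-9, sigma_allo=1e-9, noise="none",
                          zero_shift_fraction=0.0)
        ds = generate_neuro_dataset(cfg)
        assert np.allclose(ds.gaze_final, ds.target + 0.33 * ds.shift,
                           atol=1e-6)

    def test_zero_shift_trials_present(self, canvas64):
        cfg = NeuroConfig(n_trials=2000, seed=2, canvas=canvas64)
        ds = generate_neuro_dataset(cfg)
        zero = np.linalg.norm(ds.shift, axis=1) == 0
        assert 0.05 < zero.mean() < 0.20


class TestProtocolDataset:
    def test_geometry_constraints(self, canvas64):
        ds = generate_protocol_dataset(500, seed=4, canvas=canvas64)
        d = np.linalg.norm(ds.landmark - ds.target, axis=1)
        assert np.allclose(d, 11.0)
        r = np.linalg.norm(ds.gaze0, axis=1)
        assert r.min() >= 7.0 and r.max() <= 12.0
        s = np.linalg.norm(ds.shift, axis=1)
        assert set(np.round(s, 6)) <= {0.0, 8.0}


class TestIO:
    def test_hdf5_round_trip(self, small_cfg, tmp_path):
        ds = generate_scenario(small_cfg)
        path = tmp_path / "ds.h5"
        ds.to_hdf5(path)
        back = TrialDataset.from_hdf5(path)
        assert np.allclose(back.target, ds.target)
        assert np.array_equal(back.split, ds.split)
        assert back.canvas == ds.canvas

    def test_csv_columns(self, small_cfg, tmp_path):
        ds = generate_scenario(small_cfg)
        path = tmp_path / "trials.csv"
        ds.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "tx,ty,lx,ly,sx,sy,g0x,g0y,gfx,gfy,split"
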