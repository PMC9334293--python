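"""Synthetic trial datasets with controlled allocentric-egocentric weighting.

Three generators are provided:

``generate_scenario``
    Idealised training scenarios: target, landmark, shift and initial gaze
    drawn from uniform ranges, final gaze placed deterministically at
    ``T + w * shift`` for a configured allocentric weight ``w`` (0 = purely
    egocentric, 1 = purely allocentric), optionally corrupted by noise.

``generate_neuro_dataset``
    The dataset used for the reference-frame (unit) analysis: targets on a
    uniform grid, protocol landmark geometry, and final gaze sampled from a
    reliability-weighted Gaussian combination of the egocentric (T) and
    allocentric (T') cues at a configured weight (default 33%).

``generate_protocol_dataset``
    Trials drawn under the monkey protocol geometry (4 oblique landmarks at
    11 deg, 8 shift directions at 8 deg, 7-12 deg gaze jitter).

The "high" noise model follows the training-noise description: Gaussian
image blur of 10 deg standard deviation, Poisson sampling of the
eye-position population code, and an isotropic Gaussian perturbation of
the gaze endpoint (pixel-wise Poisson corruption of the images is
available as a config flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .stimuli import Canvas, ProtocolConfig, TrialSpec, TARGET_BLOCK

__all__ = [
    "NoiseConfig",
    "ScenarioConfig",
    "NeuroConfig",
    "TrialDataset",
    "generate_scenario",
    "generate_neuro_dataset",
    "generate_protocol_dataset",
    "apply_image_noise",
    "split_labels",
]

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class NoiseConfig:
    """Parameters of the "high" noise condition.

    blur_sd is in degrees (converted to pixels by the canvas resolution).
    Poisson corruption maps a pixel value p to Poisson(s*p)/s with
    s = poisson_scale photons per intensity unit.  gaze_sd (degrees) is the
    SD of the isotropic Gaussian added to the final gaze endpoint.
    """

    blur_sd: float = 10.0
    poisson_scale: float = 50.0
    poisson_images: bool = False
    gaze_sd: float = 2.0
    poisson_eye_code: bool = True


@dataclass
class ScenarioConfig:
    """Uniform-range scenario with a fixed allocentric weight."""

    allocentric_weight: float = 0.0
    noise: str = "none"  # {"none", "high"}
    n_trials: int = 10_000
    seed: int = 0
    target_range: float = 50.0
    landmark_range: float = 40.0
    shift_range: float = 10.0
    gaze_range: float = 10.0
    split_fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
    canvas: Canvas = field(default_factory=Canvas)
    noise_params: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.allocentric_weight <= 1.0:
            raise ValueError("allocentric_weight must be in [0, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.noise not in ("none", "high"):
            raise ValueError("noise must be 'none' or 'high'")


@dataclass
class NeuroConfig:
    """Grid-target dataset for the reference-frame analysis."""

    allocentric_weight: float = 0.33
    noise: str = "high"
    n_trials: int = 10_000
    seed: int = 0
    grid_shape: tuple[int, int] = (7, 7)
    grid_spacing: float = 10.0
    zero_shift_fraction: float = 1.0 / 9.0
    sigma_ego: float = 3.0  # SD of the egocentric (target) cue, deg
    sigma_allo: float = 6.0  # SD of the allocentric (T') cue, deg
    split_fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
    canvas: Canvas = field(default_factory=Canvas)
    noise_params: NoiseConfig = field(default_factory=NoiseConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    @property
    def cue_sd(self) -> float:
        """SD of the combined-cue gaze distribution (deg)."""
        va, ve = self.sigma_allo ** 2, self.sigma_ego ** 2
        return float(np.sqrt(va * ve / (va + ve)))


def split_labels(n: int, fractions: tuple[float, float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Random disjoint train/val/test labels (0/1/2) in given proportions."""
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    labels = np.full(n, 2, dtype=np.int8)
    labels[:n_train] = 0
    labels[n_train:n_train + n_val] = 1
    return labels[rng.permutation(n)]


@dataclass
class TrialDataset:
    """Column-oriented trial table with stimulus rendering attached.

    All geometric columns are (n, 2) float arrays in degrees, screen frame.
    Images are rendered on demand (in deterministic chunk order) rather
    than stored, to keep memory bounded for large datasets.
    """

    target: np.ndarray
    landmark: np.ndarray
    shift: np.ndarray
    gaze0: np.ndarray
    gaze_final: np.ndarray
    split: np.ndarray
    canvas: Canvas
    noise: str = "none"
    noise_params: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.target)

    @property
    def virtual_target(self) -> np.ndarray:
        return self.target + self.shift

    @property
    def motor_error(self) -> np.ndarray:
        """Required gaze displacement: final gaze in eye coordinates."""
        return self.gaze_final - self.gaze0

    def indices(self, split: str | None = None) -> np.ndarray:
        if split is None:
            return np.arange(len(self))
        return np.flatnonzero(self.split == SPLIT_NAMES.index(split))

    def trial(self, i: int) -> TrialSpec:
        return TrialSpec(self.target[i], self.landmark[i], self.shift[i],
                         self.gaze0[i], self.gaze_final[i])

    # ---- rendering -------------------------------------------------------

    def render(self, idx: np.ndarray, rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
        """Retinal encoding/decoding image stacks for the given trials.

        With noise enabled a generator must be supplied; the caller is
        responsible for seeding it reproducibly (see ``iter_images``).
        """
        idx = np.asarray(idx)
        n = self.canvas.n_pixels
        res = self.canvas.resolution
        enc = np.zeros((len(idx), n, n), dtype=np.float32)
        dec = np.zeros((len(idx), n, n), dtype=np.float32)

        half = n // 2
        # integer pixel coordinates of all geometry, retinal frame
        def rc(points: np.ndarray, gaze: np.ndarray) -> tuple:
            p = points - gaze
            col = np.rint(p[:, 0] / res).astype(int) + half
            row = half - np.rint(p[:, 1] / res).astype(int)
            return row, col

        g0 = self.gaze0[idx]
        lm_r, lm_c = rc(self.landmark[idx], g0)
        sl_r, sl_c = rc(self.landmark[idx] + self.shift[idx], g0)
        tgt = self.target[idx] - g0
        t_c = np.floor(tgt[:, 0] / res).astype(int) + half
        t_r = half - np.floor(tgt[:, 1] / res).astype(int)

        for k in range(len(idx)):
            if 0 <= lm_r[k] < n:
                enc[k, lm_r[k], :] = 1.0
            if 0 <= lm_c[k] < n:
                enc[k, :, lm_c[k]] = 1.0
            if 0 <= sl_r[k] < n:
                dec[k, sl_r[k], :] = 1.0
            if 0 <= sl_c[k] < n:
                dec[k, :, sl_c[k]] = 1.0
            r1, c0 = t_r[k], t_c[k]
            r0, c1 = r1 - (TARGET_BLOCK - 1), c0 + TARGET_BLOCK
            rr0, rr1 = max(r0, 0), min(r1 + 1, n)
            cc0, cc1 = max(c0, 0), min(c1, n)
            if rr0 < rr1 and cc0 < cc1:
                enc[k, rr0:rr1, cc0:cc1] = 1.0

        if self.noise == "high":
            if rng is None:
                raise ValueError("rng required to render a noisy dataset")
            enc = apply_image_noise(enc, self.noise_params, res, rng)
            dec = apply_image_noise(dec, self.noise_params, res, rng)
        return enc, dec

    def iter_images(self, chunk_size: int = 512, split: str | None = None):
        """Yield (indices, enc, dec) chunks in deterministic order.

        Image noise is drawn from a generator seeded from the dataset seed,
        so iterating the same dataset twice yields identical images.
        """
        idx = self.indices(split)
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 7)))
        for start in range(0, len(idx), chunk_size):
            sl = idx[start:start + chunk_size]
            enc, dec = self.render(sl, rng)
            yield sl, enc, dec

    # ---- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tx": self.target[:, 0], "ty": self.target[:, 1],
            "lx": self.landmark[:, 0], "ly": self.landmark[:, 1],
            "sx": self.shift[:, 0], "sy": self.shift[:, 1],
            "g0x": self.gaze0[:, 0], "g0y": self.gaze0[:, 1],
            "gfx": self.gaze_final[:, 0], "gfy": self.gaze_final[:, 1],
            "split": [SPLIT_NAMES[s] for s in self.split],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("trials")
            for name in ("target", "landmark", "shift", "gaze0",
                         "gaze_final", "split"):
                g.create_dataset(name, data=getattr(self, name))
            f.attrs["n_pixels"] = self.canvas.n_pixels
            f.attrs["field_halfwidth"] = self.canvas.field_halfwidth
            f.attrs["noise"] = self.noise
            f.attrs["seed"] = self.seed
            for k, v in asdict(self.noise_params).items():
                f.attrs[f"noise_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "TrialDataset":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["trials"]
            cols = {name: g[name][...] for name in
                    ("target", "landmark", "shift", "gaze0", "gaze_final",
                     "split")}
            canvas = Canvas(int(f.attrs["n_pixels"]),
                            float(f.attrs["field_halfwidth"]))
            noise = str(f.attrs["noise"])
            np_ = NoiseConfig(
                blur_sd=float(f.attrs["noise_blur_sd"]),
                poisson_scale=float(f.attrs["noise_poisson_scale"]),
                gaze_sd=float(f.attrs["noise_gaze_sd"]),
                poisson_eye_code=bool(f.attrs["noise_poisson_eye_code"]))
            seed = int(f.attrs["seed"])
        return cls(canvas=canvas, noise=noise, noise_params=np_,
                   seed=seed, split=cols.pop("split"), **cols)


def apply_image_noise(images: np.ndarray, noise: NoiseConfig,
                      resolution: float, rng: np.random.Generator
                      ) -> np.ndarray:
    """Gaussian blur (SD in degrees), optionally Poisson pixel corruption.

    Pixel-wise Poisson corruption (p -> Poisson(s*p)/s) is off by default:
    the "high" training-noise condition blurs the images and puts the
    Poisson noise on the eye-position signal instead, with the gaze
    endpoints perturbed separately.  Set ``poisson_images`` to corrupt the
    stimulus pixels as well.
    """
    sd_px = noise.blur_sd / resolution
    out = np.ascontiguousarray(images, dtype=np.float32)
    out = ndimage.gaussian_filter1d(out, sd_px, axis=-1, mode="constant")
    out = ndimage.gaussian_filter1d(out, sd_px, axis=-2, mode="constant")
    if noise.poisson_images:
        s = noise.poisson_scale
        out = rng.poisson(np.clip(out, 0.0, None) * s).astype(np.float32) / s
    return out


def _finish(cfg, target, landmark, shift, gaze0, gaze_final, rng,
            kind: str) -> TrialDataset:
    if cfg.noise == "high":
        gaze_final = gaze_final + rng.normal(
            0.0, cfg.noise_params.gaze_sd, size=gaze_final.shape)
    split = split_labels(len(target), cfg.split_fractions, rng)
    meta = {"kind": kind, "config": repr(cfg)}
    return TrialDataset(target=target, landmark=landmark, shift=shift,
                        gaze0=gaze0, gaze_final=gaze_final, split=split,
                        canvas=cfg.canvas, noise=cfg.noise,
                        noise_params=cfg.noise_params, seed=cfg.seed,
                        meta=meta)


def generate_scenario(cfg: ScenarioConfig) -> TrialDataset:
    """Uniform-range dataset with final gaze = T + w * shift (+ noise)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    target = rng.uniform(-cfg.target_range, cfg.target_range, (n, 2))
    landmark = rng.uniform(-cfg.landmark_range, cfg.landmark_range, (n, 2))
    shift = rng.uniform(-cfg.shift_range, cfg.shift_range, (n, 2))
    gaze0 = rng.uniform(-cfg.gaze_range, cfg.gaze_range, (n, 2))
    gaze_final = target + cfg.allocentric_weight * shift
    return _finish(cfg, target, landmark, shift, gaze0, gaze_final, rng,
                   "scenario")


def generate_neuro_dataset(cfg: NeuroConfig) -> TrialDataset:
    """Grid-target dataset with Gaussian cue-combination gaze endpoints.

    Final gaze is drawn around the reliability-weighted mean
    ``(1-w) T + w T'`` with the combined-cue SD; zero-shift trials are
    interleaved at ``zero_shift_fraction`` so the behavioural normalisation
    has a per-target no-shift reference.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    gy, gx = cfg.grid_shape
    xs = (np.arange(gx) - (gx - 1) / 2.0) * cfg.grid_spacing
    ys = (np.arange(gy) - (gy - 1) / 2.0) * cfg.grid_spacing
    cells = np.array([(x, y) for y in ys for x in xs])
    # every grid cell covered, remainder sampled uniformly over cells
    reps = int(np.ceil(n / len(cells)))
    target = np.tile(cells, (reps, 1))[:n]
    rng.shuffle(target, axis=0)

    p = cfg.protocol
    landmark = target + p.landmark_offsets[rng.integers(4, size=n)]
    shift = p.shift_offsets[rng.integers(p.n_shift_directions, size=n)]
    zero = rng.random(n) < cfg.zero_shift_fraction
    shift[zero] = 0.0
    r = rng.uniform(*p.gaze_annulus, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    gaze0 = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    w = cfg.allocentric_weight
    mean = target + w * shift
    gaze_final = mean + rng.normal(0.0, cfg.cue_sd, size=(n, 2))
    return _finish(cfg, target, landmark, shift, gaze0, gaze_final, rng,
                   "neuro")


def generate_protocol_dataset(n_trials: int, seed: int,
                              canvas: Canvas | None = None,
                              protocol: ProtocolConfig | None = None,
                              noise: str = "none",
                              noise_params: NoiseConfig | None = None,
                              zero_shift_fraction: float = 1.0 / 9.0,
                              ) -> TrialDataset:
    """Trials under the monkey protocol geometry (continuous targets)."""
    rng = np.random.default_rng(seed)
    canvas = canvas or Canvas()
    p = protocol or ProtocolConfig()
    n = n_trials
    target = rng.uniform(-p.target_range, p.target_range, (n, 2))
    landmark = target + p.landmark_offsets[rng.integers(4, size=n)]
    shift = p.shift_offsets[rng.integers(p.n_shift_directions, size=n)]
    zero = rng.random(n) < zero_shift_fraction
    shift[zero] = 0.0
    r = rng.uniform(*p.gaze_annulus, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    gaze0 = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    gaze_final = target + p.allocentric_weight * shift

    class _Cfg:
        pass

    cfg = _Cfg()
    cfg.noise = noise
    cfg.noise_params = noise_params or NoiseConfig()
    cfg.split_fractions = (0.90, 0.05, 0.05)
    cfg.canvas = canvas
    cfg.seed = seed
    return _finish(cfg, target, landmark, shift, gaze0, gaze_final, rng,
                   "protocol")
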