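"""Physiological input/output population codes and the fixed linear decoder.

Eye position is encoded by a small population (default 44 units) with
Gaussian receptive fields scattered around the orbit whose amplitude is
gain-modulated by gaze eccentricity, mimicking eye-position coding in
somatosensory cortex.  The required movement is encoded by a cosine-tuned
motor population (default 250 units) whose tuning is restricted to the
first quarter of the cosine (activity never drops below the 0.5 baseline),
reconciling open-ended motor response fields with cosine tuning.  A fixed
optimal-linear-estimator (OLE) read-out maps the motor population to the
2-D saccade vector; its weights are computed in closed form and never
trained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EyePositionCode",
    "MotorCodeSpec",
    "motor_code",
    "DecoderWeights",
    "build_ole_decoder",
    "decode_saccade",
]


class EyePositionCode(BaseEstimator, TransformerMixin):
    """Gain-modulated Gaussian eye-position population code.

    Unit i responds to gaze g with

        a_i = (b_i + alpha_i * ||g||) * exp(-||g - c_i||^2 / (2 sigma^2))

    with baseline b_i ~ U(0, max_baseline), gain slope
    alpha_i ~ U(0, max_gain) and receptive-field centres c_i uniform in
    [-center_range, center_range]^2.  ``mode="linear"`` drops the Gaussian
    receptive field and uses the pure gain term b_i + alpha_i * ||g||.
    Optional Poisson sampling models rate noise.

    Parameters follow sklearn conventions; ``fit`` draws the population
    (no data needed), ``transform`` maps (n, 2) gaze to (n, n_units) rates.
    """

    def __init__(self, n_units: int = 44, rf_sigma: float = 10.0,
                 max_baseline: float = 1.0, max_gain: float = 0.05,
                 center_range: float = 15.0, mode: str = "gain_gaussian",
                 poisson_scale: float = 0.0, random_state: int = 0):
        self.n_units = n_units
        self.rf_sigma = rf_sigma
        self.max_baseline = max_baseline
        self.max_gain = max_gain
        self.center_range = center_range
        self.mode = mode
        self.poisson_scale = poisson_scale
        self.random_state = random_state

    def fit(self, X=None, y=None) -> "EyePositionCode":
        rng = np.random.default_rng(self.random_state)
        self.baseline_ = rng.uniform(0.0, self.max_baseline, self.n_units)
        self.gain_ = rng.uniform(0.0, self.max_gain, self.n_units)
        self.centers_ = rng.uniform(-self.center_range, self.center_range,
                                    (self.n_units, 2))
        return self

    def transform(self, X: np.ndarray,
                  rng: np.random.Generator | None = None) -> np.ndarray:
        gaze = np.atleast_2d(np.asarray(X, dtype=float))
        amp = np.linalg.norm(gaze, axis=1)
        rates = self.baseline_[None, :] + self.gain_[None, :] * amp[:, None]
        if self.mode == "gain_gaussian":
            d2 = ((gaze[:, None, :] - self.centers_[None, :, :]) ** 2
                  ).sum(axis=2)
            rates = rates * np.exp(-d2 / (2.0 * self.rf_sigma ** 2))
        elif self.mode != "linear":
            raise ValueError(f"unknown mode {self.mode!r}")
        rates = np.clip(rates, 0.0, None)
        if self.poisson_scale > 0.0 and rng is not None:
            # rng is None -> noiseless mean rates even for a noisy code
            s = self.poisson_scale
            rates = rng.poisson(rates * s) / s
        return rates


@dataclass(frozen=True)
class MotorCodeSpec:
    """Quarter-cosine motor population: a = a0 + a1 * cos(theta) clipped.

    Preferred directions are unit vectors evenly spaced over 360 degrees;
    a0 = 0.5 is the baseline and a1 = 0.5 ||M|| / m_max scales with
    movement amplitude, so activities live in [0.5, 1.0].  Angles beyond
    90 degrees from the preferred direction stay at baseline.
    """

    n_units: int = 250
    m_max: float = 150.0
    a0: float = 0.5

    @property
    def preferred_directions(self) -> np.ndarray:
        ang = 2.0 * np.pi * np.arange(self.n_units) / self.n_units
        return np.column_stack([np.cos(ang), np.sin(ang)])


def motor_code(M: np.ndarray, spec: MotorCodeSpec | None = None
               ) -> np.ndarray:
    """Population activity for movement(s) M; shape (n_units,) or (n, units)."""
    spec = spec or MotorCodeSpec()
    M = np.asarray(M, dtype=float)
    single = M.ndim == 1
    M = np.atleast_2d(M)
    amp = np.linalg.norm(M, axis=1)
    if np.any(amp > spec.m_max * (1.0 + 1e-12)):
        raise ValueError(f"movement amplitude exceeds m_max={spec.m_max}")
    pd_ = spec.preferred_directions
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (M @ pd_.T) / amp[:, None]
    cos = np.where(amp[:, None] > 0.0, cos, 0.0)
    a1 = 0.5 * amp / spec.m_max
    act = spec.a0 + a1[:, None] * np.clip(cos, 0.0, None)
    return act[0] if single else act


@dataclass
class DecoderWeights:
    """Fixed OLE read-out: saccade = activity @ W."""

    W: np.ndarray
    sigma_n2: float
    spec: MotorCodeSpec

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.W)):
            raise ValueError("decoder weights must be finite")


def build_ole_decoder(spec: MotorCodeSpec | None = None,
                      sigma_n2: float = 0.01,
                      n_radii: int = 64, n_angles: int = 128
                      ) -> DecoderWeights:
    """Closed-form optimal linear estimator over the movement disk.

    Q = sigma_n^2 I + \\int a(M) a(M)^T dM and C = \\int M a(M) dM are
    integrated on a polar grid over ||M|| <= m_max; W solves Q W = C.
    The weights are fixed; they are never updated during training.
    """
    spec = spec or MotorCodeSpec()
    if sigma_n2 < 0.0:
        raise ValueError("sigma_n2 must be nonnegative")
    # midpoint polar quadrature: dM = r dr dphi
    r = (np.arange(n_radii) + 0.5) * spec.m_max / n_radii
    phi = (np.arange(n_angles) + 0.5) * 2.0 * np.pi / n_angles
    R, P = np.meshgrid(r, phi, indexing="ij")
    M = np.column_stack([(R * np.cos(P)).ravel(), (R * np.sin(P)).ravel()])
    wq = (R.ravel() * (spec.m_max / n_radii) * (2.0 * np.pi / n_angles))
    A = motor_code(M, spec)  # (G, n_units)
    Aw = A * wq[:, None]
    Q = sigma_n2 * np.eye(spec.n_units) + A.T @ Aw
    C = Aw.T @ M  # (n_units, 2)
    try:
        W = np.linalg.solve(Q, C)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular correlation matrix; increase sigma_n2") from err
    return DecoderWeights(W=W, sigma_n2=sigma_n2, spec=spec)


def decode_saccade(activity: np.ndarray, decoder: DecoderWeights
                   ) -> np.ndarray:
    """Linear read-out of the 2-D saccade vector from population activity."""
    act = np.asarray(activity, dtype=float)
    if act.shape[-1] != decoder.W.shape[0]:
        raise ValueError("activity length does not match decoder")
    return act @ decoder.W
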