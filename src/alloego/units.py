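"""Reference-frame analysis of motor-layer units.

Each motor unit's response field (activity as a function of a candidate
spatial variable) is fit nonparametrically with a Gaussian kernel in
leave-one-out form,

    A_fit(x_i; kw) = sum_{j != i} A_j exp(-|x_i - x_j|^2 / kw)
                     / sum_{j != i} exp(-|x_i - x_j|^2 / kw),

and scored by PRESS (predicted error sum of squares): the mean squared
leave-one-out residual.  The candidate spatial model and kernel bandwidth
with the lowest PRESS is the unit's intrinsic coordinate frame.

Candidate models comprise canonical frames — target, landmark, shifted
target/landmark, target-relative-to-landmark, and future gaze, each in
screen ("space") or eye coordinates (eye frame = screen position minus
initial gaze) — and two continua of intermediate eye-frame models:
target-to-gaze (T-G) and target-to-virtually-shifted-target (T-T'), each
sampled at 30 steps (10 between the reference points and 10 beyond each
end).  Spatial tuning is established by comparing the best-fit PRESS
against 200 random shuffles of the activities over the positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import NeuroConfig, TrialDataset, generate_neuro_dataset
from .pipeline import GazeNetwork

__all__ = [
    "CANONICAL_MODELS",
    "EXTENDED_MODELS",
    "DEFAULT_KW_GRID",
    "ResponseFieldSample",
    "map_response_fields",
    "model_positions",
    "continuum_positions",
    "loo_kernel_fit",
    "press_statistic",
    "fit_canonical",
    "fit_continuum",
    "spatial_tuning_test",
    "population_summary",
    "ego_allo_correlation",
    "ReferenceFrameAnalyzer",
]

# canonical model pool without / with landmark-shift frames
CANONICAL_MODELS = ("Ts", "Te", "Ls", "Le", "TL", "Gfe")
EXTENDED_MODELS = CANONICAL_MODELS + ("T's", "T'e", "L's", "L'e", "TL'")

# kernel bandwidths kw (deg^2), entering as the divisor of |dx|^2
DEFAULT_KW_GRID = tuple((2.0 * k) ** 2 for k in range(1, 11))

CONTINUUM_STEPS = tuple(range(-10, 21))  # 30 intervals spanning [-100%, 200%]


@dataclass
class ResponseFieldSample:
    """Trials used to map response fields plus the recorded activities."""

    dataset: TrialDataset
    activities: np.ndarray  # (n_trials, n_units)

    def __post_init__(self) -> None:
        if len(self.dataset) != len(self.activities):
            raise ValueError("dataset/activity length mismatch")

    @property
    def n_units(self) -> int:
        return self.activities.shape[1]


def model_positions(ds: TrialDataset, model: str) -> np.ndarray:
    """Per-trial candidate position (deg) under a canonical spatial model."""
    screen = {
        "Ts": ds.target,
        "T's": ds.target + ds.shift,
        "Ls": ds.landmark,
        "L's": ds.landmark + ds.shift,
        "FGs": ds.gaze_final,
    }
    if model in screen:
        return screen[model]
    eye = {
        "Te": ds.target - ds.gaze0,
        "T'e": ds.target + ds.shift - ds.gaze0,
        "Le": ds.landmark - ds.gaze0,
        "L'e": ds.landmark + ds.shift - ds.gaze0,
        "Gfe": ds.gaze_final - ds.gaze0,
        "TL": ds.target - ds.landmark,
        "TL'": ds.target - (ds.landmark + ds.shift),
    }
    if model in eye:
        return eye[model]
    raise KeyError(f"unknown spatial model {model!r}")


def continuum_positions(ds: TrialDataset, kind: str, step: int) -> np.ndarray:
    """Eye-frame position at continuum step k: T + (k/10)(X - T).

    kind "TG" interpolates target to final gaze, "TTp" target to virtually
    shifted target; k in [-10, 20] extrapolates 100% beyond each end.
    """
    t = ds.target - ds.gaze0
    if kind == "TG":
        x = ds.gaze_final - ds.gaze0
    elif kind == "TTp":
        x = ds.target + ds.shift - ds.gaze0
    else:
        raise KeyError(f"unknown continuum {kind!r}")
    return t + (step / 10.0) * (x - t)


def map_response_fields(net: GazeNetwork, cfg: NeuroConfig, n_trials: int,
                        seed: int, zero_shift: bool = False
                        ) -> ResponseFieldSample:
    """Probe the trained network on a grid-target dataset.

    Targets step across a uniform grid with protocol landmark geometry and
    gaze jitter.  The "final gaze" entered into the spatial models is the
    network's own decoded saccade on each trial — the model's produced
    behavior, the analogue of the recorded gaze endpoint in the
    physiological analysis — so gaze-coding units align with what the
    motor population actually drives.
    """
    from dataclasses import replace

    probe_cfg = replace(
        cfg, n_trials=n_trials, seed=seed,
        zero_shift_fraction=1.0 if zero_shift else 0.0,
        split_fractions=(1.0, 0.0, 0.0))
    ds = generate_neuro_dataset(probe_cfg)
    acts = net.motor_activity(ds)
    ds.gaze_final = ds.gaze0 + acts @ net.decoder_.W
    return ResponseFieldSample(dataset=ds, activities=acts)


# ---- kernel regression / PRESS ------------------------------------------


def _loo_weights(positions: np.ndarray, kw: float) -> np.ndarray:
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / kw)
    np.fill_diagonal(k, 0.0)
    return k


def loo_kernel_fit(positions: np.ndarray, activities: np.ndarray,
                   kw: float) -> np.ndarray:
    """Leave-one-out Gaussian-kernel prediction of each trial's activity.

    ``activities`` may be (n,) or (n, n_units); predictions have the same
    shape.  Trials with zero total kernel weight (isolated points under a
    tiny bandwidth) fall back to the mean of the other activities.
    """
    pos = np.asarray(positions, dtype=float)
    A = np.asarray(activities, dtype=float)
    single = A.ndim == 1
    A = A[:, None] if single else A
    if len(pos) != len(A) or len(pos) < 2:
        raise ValueError("need >= 2 trials with matching positions")
    if kw <= 0.0:
        raise ValueError("kw must be positive")
    k = _loo_weights(pos, kw)
    denom = k.sum(axis=1)
    n = len(A)
    loo_mean = (A.sum(axis=0)[None, :] - A) / (n - 1)
    with np.errstate(invalid="ignore"):
        pred = (k @ A) / denom[:, None]
    pred = np.where(denom[:, None] > 0.0, pred, loo_mean)
    return pred[:, 0] if single else pred


def press_statistic(positions: np.ndarray, activities: np.ndarray,
                    kw: float) -> np.ndarray:
    """Mean squared leave-one-out residual per unit."""
    A = np.asarray(activities, dtype=float)
    pred = loo_kernel_fit(positions, A, kw)
    return np.mean((pred - A) ** 2, axis=0)


def _press_table(sample: ResponseFieldSample, positions: dict,
                 kw_grid: tuple) -> np.ndarray:
    """(n_models, n_kw, n_units) PRESS array for a model-position dict."""
    names = list(positions)
    out = np.empty((len(names), len(kw_grid), sample.n_units))
    for i, name in enumerate(names):
        for j, kw in enumerate(kw_grid):
            out[i, j] = press_statistic(positions[name], sample.activities,
                                        kw)
    return out


def _best_fit_frame(sample: ResponseFieldSample, positions: dict,
                    kw_grid: tuple, tie_order: np.ndarray | None = None
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    names = list(positions)
    press = _press_table(sample, positions, kw_grid)
    # per unit: min over kw for each model, then argmin over models
    press_by_model = press.min(axis=1)  # (models, units)
    kw_idx = press.argmin(axis=1)
    if tie_order is None:
        best_model = press_by_model.argmin(axis=0)
    else:
        # resolve exact ties toward the preferred (egocentric) end
        reordered = press_by_model[tie_order]
        best_model = tie_order[reordered.argmin(axis=0)]
    units = np.arange(sample.n_units)
    best_kw_idx = kw_idx[best_model, units]
    rows = pd.DataFrame({
        "unit": units,
        "best_model": [names[m] for m in best_model],
        "best_kw": [kw_grid[j] for j in best_kw_idx],
        "press": press_by_model[best_model, units],
    })
    return rows, press_by_model


def fit_canonical(sample: ResponseFieldSample,
                  models: tuple = CANONICAL_MODELS,
                  kw_grid: tuple = DEFAULT_KW_GRID
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best canonical spatial model per unit.

    Returns (per-unit table, per-model PRESS table indexed by model name).
    """
    positions = {m: model_positions(sample.dataset, m) for m in models}
    rows, press_by_model = _best_fit_frame(sample, positions, kw_grid)
    press_df = pd.DataFrame(press_by_model.T, columns=list(models))
    return rows, press_df


def fit_continuum(sample: ResponseFieldSample, kind: str,
                  kw_grid: tuple = DEFAULT_KW_GRID,
                  steps: tuple = CONTINUUM_STEPS
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best intermediate frame along a continuum, per unit.

    The reported ``fraction_pct`` is the best step as a percentage of the
    T -> X distance (0% = target, 100% = gaze or shifted target).  Exact
    PRESS ties resolve toward the egocentric end (step nearest the
    target).
    """
    positions = {k: continuum_positions(sample.dataset, kind, k)
                 for k in steps}
    tie_order = np.argsort(np.abs(np.asarray(steps)), kind="stable")
    rows, press_by_step = _best_fit_frame(sample, positions, kw_grid,
                                          tie_order=tie_order)
    rows = rows.rename(columns={"best_model": "best_step"})
    rows["fraction_pct"] = rows["best_step"].astype(float) * 10.0
    press_df = pd.DataFrame(press_by_step.T,
                            columns=[str(k) for k in steps])
    return rows, press_df


# ---- spatial tuning ------------------------------------------------------


def _stacked_smoothers(position_sets: list[np.ndarray],
                       kw_grid: tuple) -> np.ndarray:
    """Row-normalized LOO smoother matrices for every (positions, kw) pair,
    stacked into one (n_combos * n, n) float32 matrix for fast matmuls.

    Rows with zero kernel mass (isolated points under a tiny bandwidth)
    fall back to the uniform leave-one-out mean.
    """
    mats = []
    for pos in position_sets:
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
        n = len(pos)
        for kw in kw_grid:
            k = np.exp(-d2 / kw)
            np.fill_diagonal(k, 0.0)
            denom = k.sum(axis=1)
            dead = denom <= 0.0
            if np.any(dead):
                k[dead] = 1.0 / (n - 1)
                np.fill_diagonal(k, 0.0)
                denom[dead] = k[dead].sum(axis=1)
            mats.append((k / denom[:, None]).astype(np.float32))
    return np.concatenate(mats, axis=0)


def spatial_tuning_test(sample: ResponseFieldSample, fits: pd.DataFrame,
                        position_sets: list[np.ndarray],
                        kw_grid: tuple = DEFAULT_KW_GRID,
                        n_shuffles: int = 200,
                        rng: np.random.Generator | None = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Shuffle test of spatial tuning against the best-fit PRESS.

    The activities are randomly permuted over the position data
    ``n_shuffles`` times and each shuffled response field is refit with
    the same model/bandwidth selection as the observed data (the PRESS is
    minimized over every candidate position set and kernel bandwidth).
    A unit is spatially tuned iff the rank-based p-value
    (1 + #{null <= best}) / (n_shuffles + 1) is at most alpha — by
    exchangeability the test has type-I error at most alpha for untuned
    units.
    """
    rng = rng or np.random.default_rng(0)
    n = len(sample.dataset)
    A = np.asarray(sample.activities, dtype=np.float32)
    stacked = _stacked_smoothers(position_sets, kw_grid)
    n_combos = stacked.shape[0] // n
    null = np.empty((n_shuffles, A.shape[1]))
    for s in range(n_shuffles):
        ash = rng.permuted(A, axis=0)
        pred = (stacked @ ash).reshape(n_combos, n, A.shape[1])
        press = ((pred - ash[None]) ** 2).mean(axis=1)
        null[s] = press.min(axis=0)
    units = fits["unit"].to_numpy()
    best = fits["press"].to_numpy()
    pval = (1.0 + (null[:, units] <= best[None, :]).sum(axis=0))         / (n_shuffles + 1.0)
    out = fits.copy()
    out["tuned"] = pval <= alpha
    out["tuning_pvalue"] = pval
    return out


def responsive_units(sample: ResponseFieldSample, min_trials: int = 16,
                     margin: float = 0.05) -> np.ndarray:
    """Units responding above their own floor on enough trials.

    A trial counts as a response if the unit's activity exceeds its
    minimum over the mapping set by ``margin``; units with fewer than
    ``min_trials`` responses are excluded before fitting (spatially
    irrelevant units).
    """
    A = sample.activities
    above = A > (A.min(axis=0) + margin)
    return np.flatnonzero(above.sum(axis=0) >= min_trials)


# ---- population statistics ----------------------------------------------


def population_summary(press_by_model: pd.DataFrame,
                       best_models: pd.Series) -> pd.DataFrame:
    """Paired t-test of each model's PRESS against the per-unit best.

    For each candidate model, the mean residual across units is compared
    with the residuals of each unit's best model; a significant positive
    difference marks the model as worse than the best at the population
    level.
    """
    best = press_by_model.to_numpy().min(axis=1)
    rows = []
    for m in press_by_model.columns:
        diff = press_by_model[m].to_numpy() - best
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(press_by_model[m].to_numpy(), best)
        rows.append({"model": m, "mean_press": press_by_model[m].mean(),
                     "t": float(t), "p": float(p),
                     "n_best": int((best_models == m).sum())})
    return pd.DataFrame(rows)


def continuum_shift_test(fractions_pct: np.ndarray) -> dict:
    """Wilcoxon signed-rank test of continuum fractions against zero."""
    x = np.asarray(fractions_pct, dtype=float)
    if np.allclose(x, 0.0):
        return {"statistic": 0.0, "pvalue": 1.0, "mean": 0.0, "median": 0.0}
    res = stats.wilcoxon(x)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "mean": float(np.mean(x)), "median": float(np.median(x))}


def ego_allo_correlation(tg_fraction_pct: np.ndarray,
                         ttp_fraction_pct: np.ndarray) -> dict:
    """OLS of the allocentric (T-T') on the egocentric (T-G) fraction."""
    import statsmodels.api as sm

    x = np.asarray(tg_fraction_pct, dtype=float)
    y = np.asarray(ttp_fraction_pct, dtype=float)
    if np.ptp(x) == 0.0:
        # degenerate regressor (all units at the same egocentric
        # position): the slope is unidentifiable
        return {"slope": np.nan, "slope_se": np.nan,
                "intercept": float(np.mean(y)), "r2": 0.0,
                "pvalue": 1.0, "n": len(x)}
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "slope_se": float(model.bse[1]),
        "intercept": float(model.params[0]),
        "r2": float(model.rsquared),
        "pvalue": float(model.pvalues[1]),
        "n": int(model.nobs),
    }


# ---- orchestration -------------------------------------------------------


@dataclass
class ReferenceFrameAnalyzer:
    """Full unit-level analysis of a trained network.

    Maps motor-unit response fields on grid-target probe datasets (one
    zero-shift, one shifted), runs the canonical-model comparison in each
    condition, fits the T-G and T-T' continua on the shifted condition,
    applies the shuffle tuning test throughout, and summarises the
    population (best-model fractions, continuum shift tests, ego-allo
    regression).
    """

    kw_grid: tuple = DEFAULT_KW_GRID
    n_shuffles: int = 200
    n_trials: int = 400
    min_trials: int = 16
    seed: int = 0

    def _analyze_condition(self, sample: ResponseFieldSample,
                           models: tuple, rng: np.random.Generator
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
        keep = responsive_units(sample, self.min_trials)
        sub = ResponseFieldSample(sample.dataset,
                                  sample.activities[:, keep])
        fits, press_df = fit_canonical(sub, models, self.kw_grid)
        fits["unit_id"] = keep[fits["unit"]]
        sets = [model_positions(sub.dataset, m) for m in models]
        fits = spatial_tuning_test(sub, fits, sets, self.kw_grid,
                                   self.n_shuffles, rng)
        return fits, press_df

    def analyze(self, net: GazeNetwork, cfg: NeuroConfig) -> dict:
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 3)))
        noshift = map_response_fields(net, cfg, self.n_trials,
                                      seed=self.seed + 101, zero_shift=True)
        shifted = map_response_fields(net, cfg, self.n_trials,
                                      seed=self.seed + 202, zero_shift=False)

        can0, press0 = self._analyze_condition(noshift, CANONICAL_MODELS,
                                               rng)
        can1, press1 = self._analyze_condition(shifted, EXTENDED_MODELS,
                                               rng)

        # continua are fit on the units spatially tuned in the shift
        # condition (tuning established once, on the canonical fits)
        tuned_ids = can1.loc[can1["tuned"], "unit_id"].to_numpy()
        sub = ResponseFieldSample(shifted.dataset,
                                  shifted.activities[:, tuned_ids])
        ttp, _ = fit_continuum(sub, "TTp", self.kw_grid)
        tg, _ = fit_continuum(sub, "TG", self.kw_grid)
        for frame in (ttp, tg):
            frame["unit_id"] = tuned_ids[frame["unit"]]

        tuned0 = can0[can0["tuned"]]
        tuned1 = can1[can1["tuned"]]
        ttp_frac = ttp["fraction_pct"].to_numpy()
        tg_frac = tg["fraction_pct"].to_numpy()

        out = {
            "canonical_noshift": can0,
            "canonical_shift": can1,
            "continuum_ttp": ttp,
            "continuum_tg": tg,
            "gfe_pct_noshift": 100.0 * np.mean(
                tuned0["best_model"] == "Gfe") if len(tuned0) else np.nan,
            "gfe_pct_shift": 100.0 * np.mean(
                tuned1["best_model"] == "Gfe") if len(tuned1) else np.nan,
            "population_noshift": population_summary(
                press0.loc[tuned0["unit"]], tuned0["best_model"]),
            "population_shift": population_summary(
                press1.loc[tuned1["unit"]], tuned1["best_model"]),
            "ttp_mean_pct": float(np.mean(ttp_frac)) if len(ttp_frac)
            else np.nan,
            "ttp_median_pct": float(np.median(ttp_frac)) if len(ttp_frac)
            else np.nan,
            "ttp_shift_test": continuum_shift_test(ttp_frac),
            "tg_mean_pct": float(np.mean(tg_frac)) if len(tg_frac)
            else np.nan,
            "tg_median_pct": float(np.median(tg_frac)) if len(tg_frac)
            else np.nan,
            "ego_allo": ego_allo_correlation(tg_frac, ttp_frac)
            if len(tg_frac) >= 3 else None,
            "n_tuned_noshift": int(len(tuned0)),
            "n_tuned_shift": int(len(tuned1)),
            "n_tuned_continuum": int(len(tuned_ids)),
        }
        return out
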