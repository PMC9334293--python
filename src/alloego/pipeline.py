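"""End-to-end gaze network: stimuli -> CNN features -> MLP -> decoded gaze.

``GazeNetwork`` wires the fixed Gabor front-end, the eye-position
population code and the trainable sensorimotor MLP into a single
fit/predict object operating on :class:`~alloego.datasets.TrialDataset`
instances.  The trained network predicts the gaze displacement (final
gaze in eye coordinates) for each trial; behavioral and unit-level
analyses consume its predictions and motor-layer activities.
"""

from __future__ import annotations

import numpy as np

from .codes import DecoderWeights, EyePositionCode, MotorCodeSpec
from .datasets import TrialDataset
from .frontend import GaborBank, GaborFrontend
from .network import SaccadeMLPRegressor, evaluate_predictions

__all__ = ["GazeNetwork"]


class GazeNetwork:
    """CNN + MLP saccade model with physiological input/output codes.

    Parameters mirror the component estimators; ``random_state`` seeds the
    eye-code population, MLP initialisation and batch order, so two fits
    on the same dataset are bit-identical.

    ``n_fit_images`` bounds how many training encoding/decoding images are
    used to fit the feature-pooling weights of the front-end.
    """

    def __init__(self, n_hidden: int = 100, n_motor: int = 250,
                 m_max: float = 150.0, sigma_n2: float = 0.01,
                 n_eye_units: int = 44, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 50,
                 early_stop_tol: float = 1e-3, patience: int = 12,
                 motor_init_scale: float = 0.4, n_fit_images: int = 128,
                 bank: GaborBank | None = None, random_state: int = 0):
        self.n_hidden = n_hidden
        self.n_motor = n_motor
        self.m_max = m_max
        self.sigma_n2 = sigma_n2
        self.n_eye_units = n_eye_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_tol = early_stop_tol
        self.patience = patience
        self.motor_init_scale = motor_init_scale
        self.n_fit_images = n_fit_images
        self.bank = bank
        self.random_state = random_state

    # ---- feature assembly ------------------------------------------------

    def features(self, dataset: TrialDataset) -> np.ndarray:
        """Flattened CNN features + eye code for every trial of a dataset.

        Deterministic given the dataset seed (image and eye-code noise are
        drawn from generators derived from it).
        """
        n = len(dataset)
        d = self.frontend_.output_dim(dataset.canvas.n_pixels)
        X = np.empty((n, 2 * d + self.n_eye_units))
        eye_rng = np.random.default_rng(
            np.random.SeedSequence((dataset.seed, 11)))
        noisy_eye = (dataset.noise == "high"
                     and dataset.noise_params.poisson_eye_code)
        for sl, enc, dec in dataset.iter_images():
            X[sl, :d] = self.frontend_.transform(enc)
            X[sl, d:2 * d] = self.frontend_.transform(dec)
        eye = self.eye_code_.transform(
            dataset.gaze0,
            rng=eye_rng if noisy_eye else None)
        X[:, 2 * d:] = eye
        return X

    # ---- fit / predict ---------------------------------------------------

    def fit(self, dataset: TrialDataset) -> "GazeNetwork":
        self.frontend_ = GaborFrontend(bank=self.bank)
        train_idx = dataset.indices("train")
        fit_idx = train_idx[:max(1, self.n_fit_images // 2)]
        fit_rng = np.random.default_rng(
            np.random.SeedSequence((dataset.seed, 13)))
        enc, dec = dataset.render(
            fit_idx, fit_rng if dataset.noise == "high" else None)
        self.frontend_.fit(np.concatenate([enc, dec]))

        poisson = 50.0 if (dataset.noise == "high"
                           and dataset.noise_params.poisson_eye_code) else 0.0
        self.eye_code_ = EyePositionCode(
            n_units=self.n_eye_units, poisson_scale=poisson,
            random_state=self.random_state).fit()

        X = self.features(dataset)
        y = dataset.motor_error
        tr = dataset.indices("train")
        va = dataset.indices("val")
        # standardize inputs to the MLP by training-set statistics (the
        # pooled feature maps have tiny magnitudes; sigmoid units train
        # poorly on unscaled inputs)
        self.feature_mean_ = X[tr].mean(axis=0)
        self.feature_scale_ = X[tr].std(axis=0) + 1e-8
        Xs = (X - self.feature_mean_) / self.feature_scale_
        mlp = SaccadeMLPRegressor(
            n_hidden=self.n_hidden, n_motor=self.n_motor, m_max=self.m_max,
            sigma_n2=self.sigma_n2, learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            early_stop_tol=self.early_stop_tol, patience=self.patience,
            motor_init_scale=self.motor_init_scale,
            random_state=self.random_state)
        mlp.fit(Xs[tr], y[tr], Xs[va] if len(va) else None,
                y[va] if len(va) else None)
        self.mlp_ = mlp
        self.decoder_: DecoderWeights = mlp.decoder_
        self._train_dataset = dataset
        self._train_features = Xs
        return self

    def _features_for(self, dataset: TrialDataset) -> np.ndarray:
        if dataset is getattr(self, "_train_dataset", None):
            return self._train_features
        X = self.features(dataset)
        return (X - self.feature_mean_) / self.feature_scale_

    def predict_displacement(self, dataset: TrialDataset,
                             split: str | None = None) -> np.ndarray:
        """Decoded gaze displacement (final gaze in eye coordinates)."""
        X = self._features_for(dataset)
        idx = dataset.indices(split)
        return self.mlp_.predict(X[idx])

    def predict_gaze(self, dataset: TrialDataset,
                     split: str | None = None) -> np.ndarray:
        """Predicted final gaze in screen coordinates."""
        idx = dataset.indices(split)
        return dataset.gaze0[idx] + self.predict_displacement(dataset, split)

    def motor_activity(self, dataset: TrialDataset,
                       split: str | None = None) -> np.ndarray:
        """Motor population rates for each trial (for unit analysis)."""
        X = self._features_for(dataset)
        return self.mlp_.motor_activity(X[dataset.indices(split)])

    def evaluate(self, dataset: TrialDataset, split: str = "test") -> dict:
        """R^2 / MSE of decoded vs. true gaze displacement on a split."""
        idx = dataset.indices(split)
        pred = self.predict_displacement(dataset, split)
        out = evaluate_predictions(dataset.motor_error[idx], pred)
        out["n"] = len(idx)
        return out

    # ---- persistence -----------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("mlp")
            for name in ("W1_", "b1_", "W2_", "b2_"):
                g.create_dataset(name, data=getattr(self.mlp_, name))
            f.create_group("decoder").create_dataset(
                "W", data=self.decoder_.W)
            e = f.create_group("eyecode")
            e.create_dataset("baseline", data=self.eye_code_.baseline_)
            e.create_dataset("gain", data=self.eye_code_.gain_)
            e.create_dataset("centers", data=self.eye_code_.centers_)
            f.create_group("frontend").create_dataset(
                "pooling_weights", data=self.frontend_.pooling_weights_)
            sc = f.create_group("scaling")
            sc.create_dataset("mean", data=self.feature_mean_)
            sc.create_dataset("scale", data=self.feature_scale_)
            for k in ("n_hidden", "n_motor", "m_max", "sigma_n2",
                      "n_eye_units", "learning_rate", "batch_size",
                      "max_epochs", "early_stop_tol", "patience",
                      "motor_init_scale", "n_fit_images", "random_state"):
                f.attrs[k] = getattr(self, k)
            f.attrs["eye_poisson_scale"] = self.eye_code_.poisson_scale

    @classmethod
    def from_hdf5(cls, path) -> "GazeNetwork":
        import h5py

        with h5py.File(path, "r") as f:
            kwargs = {k: f.attrs[k].item() if hasattr(f.attrs[k], "item")
                      else f.attrs[k]
                      for k in ("n_hidden", "n_motor", "m_max", "sigma_n2",
                                "n_eye_units", "learning_rate", "batch_size",
                                "max_epochs", "early_stop_tol", "patience",
                                "motor_init_scale", "n_fit_images",
                                "random_state")}
            for k in ("n_hidden", "n_motor", "n_eye_units", "batch_size",
                      "max_epochs", "patience", "n_fit_images",
                      "random_state"):
                kwargs[k] = int(kwargs[k])
            net = cls(**kwargs)
            net.eye_code_ = EyePositionCode(
                n_units=kwargs["n_eye_units"],
                poisson_scale=float(f.attrs["eye_poisson_scale"]),
                random_state=kwargs["random_state"])
            net.eye_code_.baseline_ = f["eyecode/baseline"][...]
            net.eye_code_.gain_ = f["eyecode/gain"][...]
            net.eye_code_.centers_ = f["eyecode/centers"][...]
            net.frontend_ = GaborFrontend()
            net.frontend_.pooling_weights_ = f["frontend/pooling_weights"][...]
            net.frontend_.n_channels_ = len(net.frontend_.pooling_weights_)
            net.feature_mean_ = f["scaling/mean"][...]
            net.feature_scale_ = f["scaling/scale"][...]
            mlp = SaccadeMLPRegressor(
                n_hidden=kwargs["n_hidden"], n_motor=kwargs["n_motor"],
                m_max=kwargs["m_max"], sigma_n2=kwargs["sigma_n2"],
                random_state=kwargs["random_state"])
            spec = MotorCodeSpec(n_units=kwargs["n_motor"],
                                 m_max=kwargs["m_max"])
            mlp.decoder_ = DecoderWeights(W=f["decoder/W"][...],
                                          sigma_n2=kwargs["sigma_n2"],
                                          spec=spec)
            for name in ("W1_", "b1_", "W2_", "b2_"):
                setattr(mlp, name, f[f"mlp/{name}"][...])
            net.mlp_ = mlp
            net.decoder_ = mlp.decoder_
        return net
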