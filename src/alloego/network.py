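"""Sensorimotor multilayer perceptron with a fixed linear read-out.

The MLP maps the concatenated visual features and eye-position code
through one sigmoid hidden layer to a sigmoid motor population layer; a
fixed optimal-linear-estimator decoder (never updated by training) turns
the motor population activity into the 2-D saccade vector.  Training
minimises the mean squared error between decoded and ground-truth gaze
displacement with the Adam optimiser (learning rate 0.001, batch size 32),
stopping after 50 epochs or once the validation RMSE has stopped dropping
(no improvement beyond 0.001 for `patience` consecutive epochs, with the
best-epoch weights restored).

Implemented directly in NumPy with hand-written backpropagation: the
network is small enough that this is fast, exactly reproducible given the
seed, and keeps the fixed-decoder constraint explicit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .codes import DecoderWeights, MotorCodeSpec, build_ole_decoder

__all__ = ["SaccadeMLPRegressor", "evaluate_predictions", "r_squared"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Joint coefficient of determination over both gaze components."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - y_true.mean(axis=0)) ** 2)
    return float(1.0 - ss_res / ss_tot)


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """R^2 (joint and per axis), MSE of the summed squared error, residuals."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    res = y_pred - y_true
    per_axis = [r_squared(y_true[:, j:j + 1], y_pred[:, j:j + 1])
                for j in range(y_true.shape[1])]
    return {
        "r2": r_squared(y_true, y_pred),
        "r2_x": per_axis[0],
        "r2_y": per_axis[1],
        "mse": float(np.mean(np.sum(res ** 2, axis=1))),
        "residuals": res,
    }


class SaccadeMLPRegressor(BaseEstimator, RegressorMixin):
    """Sigmoid MLP -> cosine-tuned motor population -> fixed OLE decoder.

    Parameters
    ----------
    n_hidden : hidden-layer size (100 at full scale, 50 reduced).
    n_motor : motor population size (250 by default).
    m_max : movement amplitude bound of the motor code / decoder.
    sigma_n2 : expected neural noise variance used by the OLE decoder.
    learning_rate, batch_size, max_epochs, early_stop_tol : training
        protocol (Adam; validation-RMSE plateau stopping).
    random_state : seeds weight initialisation and batch shuffling.

    Fitted attributes carry trailing underscores; ``decoder_`` holds the
    fixed read-out weights, which training never modifies.
    """

    def __init__(self, n_hidden: int = 100, n_motor: int = 250,
                 m_max: float = 150.0, sigma_n2: float = 0.01,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 50, early_stop_tol: float = 1e-3,
                 patience: int = 12,
                 motor_init_scale: float = 0.4, random_state: int = 0):
        self.n_hidden = n_hidden
        self.n_motor = n_motor
        self.m_max = m_max
        self.sigma_n2 = sigma_n2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_tol = early_stop_tol
        self.patience = patience
        self.motor_init_scale = motor_init_scale
        self.random_state = random_state

    # ---- forward pass ----------------------------------------------------

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
        h = _sigmoid(X @ self.W1_ + self.b1_)
        m = _sigmoid(h @ self.W2_ + self.b2_)
        return h, m, m @ self.decoder_.W

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Decoded 2-D gaze displacement for each input row."""
        check_is_fitted(self, "W1_")
        return self._forward(np.asarray(X, dtype=float))[2]

    def motor_activity(self, X: np.ndarray) -> np.ndarray:
        """Motor population rates (the model's recordable units)."""
        check_is_fitted(self, "W1_")
        return self._forward(np.asarray(X, dtype=float))[1]

    # ---- training --------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> "SaccadeMLPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("X must be (n, d) and y (n, 2)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)
        d = X.shape[1]
        spec = MotorCodeSpec(n_units=self.n_motor, m_max=self.m_max)
        self.decoder_ = build_ole_decoder(spec, self.sigma_n2)

        def init(fan_in: int, fan_out: int) -> np.ndarray:
            lim = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-lim, lim, (fan_in, fan_out))

        self.W1_ = init(d, self.n_hidden)
        # the motor layer starts near zero so its tuning is inherited
        # through the fixed decoder rather than from initialisation noise
        self.W2_ = self.motor_init_scale * init(self.n_hidden, self.n_motor)
        self.b1_ = np.zeros(self.n_hidden)
        self.b2_ = np.zeros(self.n_motor)

        params = [self.W1_, self.b1_, self.W2_, self.b2_]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        Wd = self.decoder_.W

        self.loss_curve_ = []
        self.val_rmse_curve_ = []
        best_rmse = np.inf
        best_weights = None
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            for start in range(0, len(X), self.batch_size):
                b = order[start:start + self.batch_size]
                xb, yb = X[b], y[b]
                h, mo, pred = self._forward(xb)
                err = pred - yb
                loss = np.sum(err ** 2)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                epoch_loss += loss
                # backprop; loss = sum of squared errors over the batch
                g_mo = (2.0 * err @ Wd.T) * mo * (1.0 - mo)
                g_W2 = h.T @ g_mo
                g_b2 = g_mo.sum(axis=0)
                g_h = (g_mo @ self.W2_.T) * h * (1.0 - h)
                g_W1 = xb.T @ g_h
                g_b1 = g_h.sum(axis=0)
                grads = [g_W1 / len(b), g_b1 / len(b),
                         g_W2 / len(b), g_b2 / len(b)]
                step += 1
                for p, g, m_, v_ in zip(params, grads, m_t, v_t):
                    m_ *= beta1
                    m_ += (1.0 - beta1) * g
                    v_ *= beta2
                    v_ += (1.0 - beta2) * g * g
                    mh = m_ / (1.0 - beta1 ** step)
                    vh = v_ / (1.0 - beta2 ** step)
                    p -= self.learning_rate * mh / (np.sqrt(vh) + eps)
            self.loss_curve_.append(epoch_loss / len(X))
            if X_val is not None and len(X_val):
                val_pred = self.predict(X_val)
                rmse = float(np.sqrt(np.mean(
                    np.sum((val_pred - y_val) ** 2, axis=1))))
                self.val_rmse_curve_.append(rmse)
                # validation RMSE stopped dropping significantly: no epoch
                # has beaten the best by early_stop_tol for `patience`
                # consecutive epochs
                if rmse < best_rmse - self.early_stop_tol:
                    best_rmse = rmse
                    best_weights = [p.copy() for p in params]
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_weights is not None:
            for p, b in zip(params, best_weights):
                p[...] = b
            self.best_val_rmse_ = best_rmse
        self.n_epochs_ = len(self.loss_curve_)
        self.n_parameters_ = int(sum(p.size for p in params))
        return self

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return r_squared(np.asarray(y, dtype=float), self.predict(X))

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> dict:
        return evaluate_predictions(np.asarray(y, dtype=float),
                                    self.predict(X))
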