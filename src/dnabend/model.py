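"""The cyclizability predictor: a scikit-learn-style estimator around the
IR+LSTM network.

A fitted :class:`IRLSTMRegressor` maps any 50-bp DNA sequence to its
predicted intrinsic cyclizability (C-score).  Prediction follows the
two-pass contract: the sequence and its reverse complement are encoded and
evaluated independently, the two raw network outputs are averaged, and the
average is linearly detrended::

    C(s) = a + b * (f(s) + f(rc(s))) / 2

which makes the C-score exactly reverse-complement symmetric by
construction.  The detrend coefficients ``(a, b)`` correct the mean drift
and variance shrinkage that raw deep-regression outputs exhibit; they are
calibrated by regressing held-out labels on raw averaged outputs.

Training uses RMSprop on the mean-squared error of standardized labels,
with an early-stopping checkpoint: the weights returned are those with the
lowest validation MSE seen during training, not the final epoch's.
"""

from __future__ import annotations

import json
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn import ArchitectureConfig, IRLSTMNetwork, RMSprop
from .sequence import one_hot_encode_batch

CHANNEL_ORDER = "ACGT"


class DegenerateLabelsError(ValueError):
    """Labels (or raw outputs) have zero variance where variance is required."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def _as_onehot(X) -> np.ndarray:
    """Accept a list of equal-length sequences or an (n, L, 4) one-hot array."""
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return np.asarray(X, dtype=float)
    if isinstance(X, np.ndarray):
        X = X.tolist()
    if not isinstance(X, (list, tuple)):
        raise TypeError("X must be a list of sequences or an (n, L, 4) array")
    return one_hot_encode_batch(list(X))


def _rc_onehot(x: np.ndarray) -> np.ndarray:
    """Reverse complement in one-hot space: reverse the position axis and
    the (A,C,G,T) channel axis (A<->T, C<->G)."""
    return x[:, ::-1, ::-1]


class IRLSTMRegressor(RegressorMixin, BaseEstimator):
    """Inception-residual + LSTM regressor for DNA cyclizability.

    Parameters
    ----------
    input_length : int, default 50
        Window width in bp; the C-score is defined for 50-bp fragments.
    stem_filters, filters_per_branch, lstm_units, dropout_rate
        Architecture knobs; the defaults are the deployed configuration
        (64 stem filters, 32 per inception branch so the concatenation
        matches the residual shortcut, 20 LSTM units, dropout 0.2).
    learning_rate, rho, epsilon
        RMSprop settings.
    batch_size, max_epochs, patience
        Optimization schedule.  ``patience`` counts non-improving epochs
        after the best checkpoint before stopping; the checkpointed (best
        validation MSE) weights are always restored.
    validation_fraction : float
        Fraction of the training data carved out (seeded) for early
        stopping and detrend calibration when no explicit validation set
        is passed to :meth:`fit`.
    standardize : bool
        Standardize labels to zero mean / unit variance inside ``fit``
        (constants stored as ``label_mean_`` / ``label_std_``).  The
        C-score scale is the standardized scale.
    detrend : bool
        Calibrate the linear detrend on the validation split after
        training.  With ``False`` the identity calibration (0, 1) is used.

    Attributes
    ----------
    network_ : IRLSTMNetwork
        The fitted network (evaluation mode for prediction).
    detrend_a_, detrend_b_ : float
        Linear recalibration applied to raw averaged outputs.
    label_mean_, label_std_ : float
        Standardization constants of the training labels.
    history_ : dict
        Per-epoch train/validation MSE.
    best_epoch_, n_epochs_ : int
    """

    def __init__(
        self,
        input_length: int = 50,
        stem_filters: int = 64,
        filters_per_branch: int = 32,
        lstm_units: int = 20,
        dropout_rate: float = 0.2,
        learning_rate: float = 1e-3,
        rho: float = 0.9,
        epsilon: float = 1e-7,
        batch_size: int = 128,
        max_epochs: int = 100,
        patience: int = 5,
        validation_fraction: float = 0.1,
        standardize: bool = True,
        detrend: bool = True,
        random_state: int | None = None,
        verbose: int = 0,
    ) -> None:
        self.input_length = input_length
        self.stem_filters = stem_filters
        self.filters_per_branch = filters_per_branch
        self.lstm_units = lstm_units
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.rho = rho
        self.epsilon = epsilon
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.detrend = detrend
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ utils
    def _config(self) -> ArchitectureConfig:
        return ArchitectureConfig(
            input_length=self.input_length,
            stem_filters=self.stem_filters,
            filters_per_branch=self.filters_per_branch,
            lstm_units=self.lstm_units,
            dropout_rate=self.dropout_rate,
        )

    def _forward_batched(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        out = np.empty(len(x))
        for i in range(0, len(x), batch):
            out[i : i + batch] = self.network_.forward(x[i : i + batch], training=False)
        return out

    def raw_scores(self, X) -> np.ndarray:
        """Reverse-complement-averaged raw network outputs (no detrend)."""
        check_is_fitted(self, "network_")
        x = _as_onehot(X)
        if x.shape[1] != self.input_length:
            raise ValueError(
                f"sequences are {x.shape[1]} bp; the C-score is defined for "
                f"{self.input_length}-bp fragments — use dnabend.genome."
                "predict_track for sliding-window prediction of longer input"
            )
        fwd = self._forward_batched(x)
        rev = self._forward_batched(_rc_onehot(x))
        return 0.5 * (fwd + rev)

    # ------------------------------------------------------------------- fit
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on sequences ``X`` with cyclizability labels ``y``.

        If no explicit validation set is passed, ``validation_fraction`` of
        the data is held out (seeded) for the early-stopping checkpoint and
        for detrend calibration.
        """
        x = _as_onehot(X)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("X and y length mismatch")
        if x.shape[1] != self.input_length:
            raise ValueError(
                f"training sequences must be {self.input_length} bp, got {x.shape[1]}"
            )

        rng = np.random.default_rng(self.random_state)
        init_seed = int(rng.integers(2**31))

        if self.standardize:
            std = float(y.std())
            if std == 0.0:
                raise DegenerateLabelsError(
                    "labels have zero variance; cannot standardize"
                )
            self.label_mean_, self.label_std_ = float(y.mean()), std
        else:
            self.label_mean_, self.label_std_ = 0.0, 1.0
        ys = (y - self.label_mean_) / self.label_std_

        if X_val is not None:
            if y_val is None:
                raise ValueError("X_val given without y_val")
            xv = _as_onehot(X_val)
            yv = (np.asarray(y_val, dtype=float) - self.label_mean_) / self.label_std_
            xt, yt = x, ys
        else:
            n_val = int(round(self.validation_fraction * len(x)))
            if n_val < 1:
                raise ValueError(
                    "empty validation set: provide X_val/y_val or more data"
                )
            perm = rng.permutation(len(x))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            xt, yt = x[tr_idx], ys[tr_idx]
            xv, yv = x[val_idx], ys[val_idx]
        if len(xv) == 0:
            raise ValueError("empty validation set")
        if len(xt) == 0:
            raise ValueError("empty training set")

        net = IRLSTMNetwork(self._config(), seed=init_seed)
        net.set_dropout_rng(np.random.default_rng(int(rng.integers(2**31))))
        opt = RMSprop(self.learning_rate, self.rho, self.epsilon)
        self.network_ = net

        best_mse = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        history = {"train_mse": [], "val_mse": []}
        since_best = 0

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(xt))
            train_loss = 0.0
            for i in range(0, len(order), self.batch_size):
                idx = order[i : i + self.batch_size]
                xb, yb = xt[idx], yt[idx]
                pred = net.forward(xb, training=True)
                err = pred - yb
                loss = float(np.mean(err * err))
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite training loss at epoch {epoch}")
                train_loss += loss * len(idx)
                net.backward(2.0 * err / len(idx))
                opt.step(net.parameters())
            train_loss /= len(xt)

            val_pred = self._forward_batched(xv)
            val_mse = float(np.mean((val_pred - yv) ** 2))
            if not np.isfinite(val_mse):
                raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
            history["train_mse"].append(train_loss)
            history["val_mse"].append(val_mse)
            if self.verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_mse:.4f}")

            if val_mse < best_mse:
                best_mse, best_epoch, since_best = val_mse, epoch, 0
                best_weights = net.get_weights()
            else:
                since_best += 1
                if since_best > self.patience:
                    break

        net.set_weights(best_weights)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(history["val_mse"])

        if self.detrend:
            raw = self.raw_scores(xv)
            self.detrend_a_, self.detrend_b_ = fit_detrend_values(raw, yv)
        else:
            self.detrend_a_, self.detrend_b_ = 0.0, 1.0
        return self

    # --------------------------------------------------------------- predict
    def predict(self, X) -> np.ndarray:
        """Predicted C-score for each 50-bp sequence in ``X``."""
        check_is_fitted(self, "network_")
        return self.detrend_a_ + self.detrend_b_ * self.raw_scores(X)

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Serialize architecture, weights, detrend and label constants.

        The archive round-trips to bit-identical predictions.
        """
        check_is_fitted(self, "network_")
        meta = {
            "config": json.loads(self.network_.config.to_json()),
            "init_seed": self.network_.seed,
            "detrend_a": self.detrend_a_,
            "detrend_b": self.detrend_b_,
            "label_mean": self.label_mean_,
            "label_std": self.label_std_,
            "channel_order": CHANNEL_ORDER,
            "params": self.get_params(),
        }
        weights = self.network_.get_weights()
        arrays = {f"w{i}": w for i, w in enumerate(weights)}
        np.savez(path, meta=np.array(json.dumps(meta)), n_weights=len(weights), **arrays)

    @classmethod
    def load(cls, path) -> "IRLSTMRegressor":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            weights = [archive[f"w{i}"] for i in range(int(archive["n_weights"]))]
        est = cls(**meta["params"])
        config = ArchitectureConfig.from_json(json.dumps(meta["config"]))
        est.network_ = IRLSTMNetwork(config, seed=meta["init_seed"])
        est.network_.set_weights(weights)
        est.detrend_a_ = float(meta["detrend_a"])
        est.detrend_b_ = float(meta["detrend_b"])
        est.label_mean_ = float(meta["label_mean"])
        est.label_std_ = float(meta["label_std"])
        if meta["channel_order"] != CHANNEL_ORDER:
            raise ValueError("incompatible one-hot channel order in archive")
        return est


def fit_detrend_values(raw: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``labels ~ a + b * raw``.

    This is the recalibration direction: applying ``a + b*raw`` afterwards
    makes the corrected predictions match the calibration labels in mean
    exactly, and gives OLS slope 1 of labels on corrected predictions.
    """
    raw = np.asarray(raw, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if raw.shape != labels.shape:
        raise ValueError("raw and labels must have equal length")
    if np.var(raw) == 0.0:
        raise DegenerateLabelsError("raw outputs have zero variance; cannot detrend")
    b, a = np.polyfit(raw, labels, 1)
    return float(a), float(b)


def predict_cscore(model: IRLSTMRegressor, seq: str) -> float:
    """C-score of a single sequence of exactly the model's input length."""
    if len(seq) != model.input_length:
        raise ValueError(
            f"sequence is {len(seq)} bp but the C-score is defined for "
            f"{model.input_length}-bp fragments; use dnabend.genome.predict_track "
            "for sliding-window prediction"
        )
    return float(model.predict([seq])[0])
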