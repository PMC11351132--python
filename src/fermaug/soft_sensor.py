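"""The ethanol soft sensor: a 4-80-60-1 feedforward regression network.

Maps the four online probe signals (pH, redox, capacitance, temperature) at
one timestep to the ethanol concentration at that timestep.  The map is
pointwise in time — no information leaks across timesteps — which is what
lets whole experiments be stacked row-wise for training.

The network itself is scikit-learn's multilayer perceptron regressor with
the fixed (80, 60) hidden architecture; training minimizes mean squared
error with Adam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .preprocess import Normalizer

__all__ = ["FNNConfig", "SoftSensorModel", "train_soft_sensor", "predict_ethanol"]

#: Fixed layer widths: input-hidden-hidden-output.
LAYER_WIDTHS = (4, 80, 60, 1)


@dataclass
class FNNConfig:
    """Training hyperparameters; the 4-80-60-1 architecture is fixed."""

    activation: str = "relu"
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int | str = "auto"   # "auto" = min(200, n); "full" = all rows
    seed: int = 0
    #: clamp prediction inputs to the training-feature range per channel.
    #: A ReLU net's behaviour outside its training domain is undefined;
    #: deployed soft sensors clamp inputs to the calibrated sensor range
    clip_inputs: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def hidden_layer_sizes(self) -> tuple:
        return LAYER_WIDTHS[1:-1]


@dataclass
class SoftSensorModel:
    """Trained regressor plus the normalizer it expects inputs in."""

    net: MLPRegressor
    config: FNNConfig
    normalizer: Optional[Normalizer] = None
    #: per-feature (min, max) of the training data, for input clamping
    feature_range: Optional[tuple] = None


def train_soft_sensor(
    features: np.ndarray,
    targets: np.ndarray,
    config: FNNConfig | None = None,
    normalizer: Normalizer | None = None,
) -> SoftSensorModel:
    """Fit the soft sensor on stacked (rows, 4) features and (rows, 1) targets.

    Inputs are expected already normalized; the normalizer used to produce
    them can be attached for bookkeeping.  Deterministic for a fixed seed.
    """
    config = config or FNNConfig()
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if features.ndim != 2 or features.shape[1] != LAYER_WIDTHS[0]:
        raise ValueError(f"features must be (rows, {LAYER_WIDTHS[0]}), got {features.shape}")
    if targets.ndim == 2 and targets.shape[1] == 1:
        y = targets[:, 0]
    elif targets.ndim == 1:
        y = targets
    else:
        raise ValueError(f"targets must be (rows,) or (rows, 1), got {targets.shape}")
    if features.shape[0] != y.shape[0]:
        raise ValueError("features and targets disagree on row count")
    if not (np.all(np.isfinite(features)) and np.all(np.isfinite(y))):
        raise ValueError("NaN/inf in training data; impute and normalize first")

    batch = features.shape[0] if config.batch_size == "full" else config.batch_size
    net = MLPRegressor(
        hidden_layer_sizes=config.hidden_layer_sizes,
        activation=config.activation,
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=batch,
        max_iter=config.epochs,
        n_iter_no_change=config.epochs,   # run all epochs; no early stop
        random_state=config.seed,
        shuffle=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(features, y)
    if not np.isfinite(net.loss_):
        raise RuntimeError("soft-sensor training diverged (non-finite loss)")
    return SoftSensorModel(
        net=net, config=config, normalizer=normalizer,
        feature_range=(features.min(axis=0), features.max(axis=0)),
    )


def predict_ethanol(model: SoftSensorModel, features: np.ndarray) -> np.ndarray:
    """Predict ethanol for (rows, 4) normalized features; returns (rows, 1).

    Inputs outside the model's training-feature range are clamped to it
    (unless the model was configured otherwise): the network's behaviour
    beyond its training domain is undefined extrapolation.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != LAYER_WIDTHS[0]:
        raise ValueError(f"features must be (rows, {LAYER_WIDTHS[0]}), got {features.shape}")
    feature_range = getattr(model, "feature_range", None)
    config = getattr(model, "config", None)
    if feature_range is not None and (config is None or config.clip_inputs):
        lo, hi = feature_range
        features = np.clip(features, lo, hi)
    pred = model.net.predict(features)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("non-finite predictions")
    return pred.reshape(-1, 1)
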