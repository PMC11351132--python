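"""Imputation, normalization, regridding and tensor assembly.

Bridges raw experiment collections (which may contain missing channels and
uneven grids) to the fixed-shape arrays the generative model and the soft
sensor consume: a ``(n_sets, n_points, 7)`` tensor for the VAE and stacked
``(n_sets * n_points, 4)`` feature / ``(n_sets * n_points, 1)`` target
arrays for the regression network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.impute import KNNImputer

from .core import (
    CHANNELS,
    INPUT_CHANNELS,
    TARGET_CHANNEL,
    ExperimentCollection,
    ExperimentSeries,
    channel_index,
)

__all__ = [
    "Normalizer",
    "SeriesTensor",
    "impute_missing_channel",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
    "regrid",
    "to_vae_tensor",
    "to_regression_arrays",
    "collection_from_tensor",
]


@dataclass
class Normalizer:
    """Per-channel affine normalizer (min-max to [0, 1] or z-score).

    ``transform`` maps raw values to normalized space as
    ``(x - shift) / scale``; ``inverse`` undoes it.  Statistics come from a
    fitting collection only, so a normalizer fit on training experiments can
    be reused leak-free on held-out ones.
    """

    scheme: str
    shift: np.ndarray   # per-channel, length 7
    scale: np.ndarray   # per-channel, length 7
    channels: tuple = CHANNELS

    def transform_values(self, values: np.ndarray) -> np.ndarray:
        if values.shape[-1] != len(self.channels):
            raise ValueError("channel count mismatch")
        return (values - self.shift) / self.scale

    def inverse_values(self, values: np.ndarray) -> np.ndarray:
        if values.shape[-1] != len(self.channels):
            raise ValueError("channel count mismatch")
        return values * self.scale + self.shift

    def transform_channel(self, x: np.ndarray, name: str) -> np.ndarray:
        i = channel_index(name)
        return (x - self.shift[i]) / self.scale[i]

    def inverse_channel(self, x: np.ndarray, name: str) -> np.ndarray:
        i = channel_index(name)
        return x * self.scale[i] + self.shift[i]


def impute_missing_channel(collection: ExperimentCollection, k: int = 5) -> ExperimentCollection:
    """KNN-impute missing sensor values.

    Samples (time points) from all experiments are pooled into one
    ``(n_sets * n_points, 7)`` matrix; each missing entry is replaced by the
    mean of its channel over the ``k`` nearest samples that observed it,
    with Euclidean distance over the mutually observed channels (scikit-learn's
    nan-aware KNN imputer).  Observed entries are returned bit-identical.
    """
    stacked = collection.stacked_values()
    n_sets, n_points, n_chan = stacked.shape
    flat = stacked.reshape(n_sets * n_points, n_chan)
    mask = np.isnan(flat)
    if not mask.any():
        return collection.copy()
    for ci, name in enumerate(CHANNELS):
        if mask[:, ci].all():
            raise ValueError(f"channel {name!r} has no observed values to impute from")
    n_complete = int((~mask.any(axis=1)).sum())
    if k > n_complete:
        raise ValueError(f"k={k} exceeds the {n_complete} fully observed samples")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(flat)
    filled[~mask] = flat[~mask]   # keep observed entries bit-identical
    filled = filled.reshape(n_sets, n_points, n_chan)
    out = []
    for i, s in enumerate(collection):
        c = s.copy()
        c.values = filled[i]
        out.append(c)
    return ExperimentCollection(out)


def fit_normalizer(collection: ExperimentCollection, scheme: str = "minmax") -> Normalizer:
    """Fit per-channel statistics over every experiment in ``collection``.

    min-max is the default (pairs with a bounded decoder output); z-score is
    available for diagnostics.  A constant channel cannot be normalized and
    raises, naming the channel.
    """
    if scheme not in ("minmax", "zscore"):
        raise ValueError(f"unknown scheme {scheme!r}")
    flat = collection.stacked_values().reshape(-1, len(CHANNELS))
    if np.isnan(flat).any():
        raise ValueError("collection must be imputed before fitting a normalizer")
    if scheme == "minmax":
        lo, hi = flat.min(axis=0), flat.max(axis=0)
        bad = hi <= lo
        shift, scale = lo, hi - lo
    else:
        mean, sd = flat.mean(axis=0), flat.std(axis=0, ddof=0)
        bad = sd <= 0
        shift, scale = mean, sd
    if bad.any():
        names = [CHANNELS[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"constant channel(s) cannot be normalized: {names}")
    return Normalizer(scheme=scheme, shift=shift.astype(float), scale=scale.astype(float))


def _map_collection(collection: ExperimentCollection, fn) -> ExperimentCollection:
    out = []
    for s in collection:
        c = s.copy()
        c.values = fn(c.values)
        out.append(c)
    return ExperimentCollection(out)


def apply_normalizer(collection: ExperimentCollection, normalizer: Normalizer) -> ExperimentCollection:
    """Elementwise per-channel affine transform; shape preserved."""
    return _map_collection(collection, normalizer.transform_values)


def invert_normalizer(collection: ExperimentCollection, normalizer: Normalizer) -> ExperimentCollection:
    """Inverse of :func:`apply_normalizer`."""
    return _map_collection(collection, normalizer.inverse_values)


def regrid(series: ExperimentSeries, n_points: int) -> ExperimentSeries:
    """Linearly interpolate every channel onto an even grid of ``n_points``
    over the same time span; endpoints are preserved exactly."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    new_time = np.linspace(series.time[0], series.time[-1], n_points)
    new_time[0], new_time[-1] = series.time[0], series.time[-1]
    new_values = np.empty((n_points, len(CHANNELS)))
    for ci in range(len(CHANNELS)):
        col = series.values[:, ci]
        obs = ~np.isnan(col)
        if obs.all():
            new_values[:, ci] = np.interp(new_time, series.time, col)
        elif not obs.any():
            new_values[:, ci] = np.nan
        else:
            new_values[:, ci] = np.interp(new_time, series.time[obs], col[obs])
    out = series.copy()
    out.time = new_time
    out.values = new_values
    return out


@dataclass
class SeriesTensor:
    """Stacked experiments, shape ``(n_sets, n_points, n_channels)``, with the
    channel order recorded to prevent silent permutation."""

    data: np.ndarray
    channels: tuple = CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channels):
            raise ValueError(f"expected (n_sets, n_points, {len(self.channels)}) array")
        if np.isnan(self.data).any():
            raise ValueError("tensor must not contain missing values")

    @property
    def shape(self) -> tuple:
        return self.data.shape


def to_vae_tensor(collection: ExperimentCollection) -> SeriesTensor:
    """Stack an imputed collection into the generative model's input tensor."""
    if len(collection) == 0:
        raise ValueError("empty collection")
    lengths = {s.n_points for s in collection}
    if len(lengths) != 1:
        raise ValueError(f"ragged collection lengths {sorted(lengths)}; regrid first")
    return SeriesTensor(collection.stacked_values())


def to_regression_arrays(collection: ExperimentCollection) -> tuple[np.ndarray, np.ndarray]:
    """Stack the probe channels into ``(n_sets * n_points, 4)`` features and
    ethanol into ``(n_sets * n_points, 1)`` targets, in collection order."""
    tensor = to_vae_tensor(collection).data
    n_sets, n_points, _ = tensor.shape
    cols = [channel_index(c) for c in INPUT_CHANNELS]
    features = tensor[:, :, cols].reshape(n_sets * n_points, len(INPUT_CHANNELS))
    targets = tensor[:, :, channel_index(TARGET_CHANNEL)].reshape(n_sets * n_points, 1)
    return features, targets


def collection_from_tensor(
    tensor: SeriesTensor | np.ndarray,
    time: np.ndarray,
    provenance: str = "synthetic",
    id_prefix: str = "syn",
) -> ExperimentCollection:
    """Wrap a ``(n_sets, n_points, 7)`` array back into a collection."""
    data = tensor.data if isinstance(tensor, SeriesTensor) else np.asarray(tensor, float)
    if data.shape[1] != np.asarray(time).size:
        raise ValueError("time grid length does not match tensor")
    width = max(3, len(str(data.shape[0])))
    return ExperimentCollection(
        [
            ExperimentSeries(
                time=np.asarray(time, float).copy(),
                values=data[i].copy(),
                id=f"{id_prefix}{i + 1:0{width}d}",
                provenance=provenance,
            )
            for i in range(data.shape[0])
        ]
    )
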