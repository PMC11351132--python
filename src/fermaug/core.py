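"""Core containers for fermentation experiment time series.

An experiment is one very-high-gravity (VHG) ethanol fermentation cycle:
a shared time grid plus seven channels — four online probe signals
(pH, redox potential, capacitance, temperature) and three process
concentrations (ethanol, substrate, viable cells).  Channel order is frozen
package-wide so arrays can never be silently permuted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: Frozen channel order used by every array in the package.
CHANNELS: tuple[str, ...] = (
    "pH",
    "redox",
    "capacitance",
    "temperature",
    "ethanol",
    "substrate",
    "cells",
)

#: The four probe channels that feed the soft sensor.
INPUT_CHANNELS: tuple[str, ...] = CHANNELS[:4]

#: The regression target.
TARGET_CHANNEL: str = "ethanol"

#: Physical units per channel, for headers and plot labels.
CHANNEL_UNITS: dict[str, str] = {
    "pH": "-",
    "redox": "mV",
    "capacitance": "pF/cm",
    "temperature": "degC",
    "ethanol": "g/L",
    "substrate": "g/L",
    "cells": "g/L",
}


def channel_index(name: str) -> int:
    """Index of ``name`` in the frozen channel order."""
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}") from None


@dataclass
class ExperimentSeries:
    """One fermentation cycle on a strictly increasing time grid.

    Parameters
    ----------
    time
        Time grid in hours, shape ``(n_points,)``, strictly increasing.
    values
        Channel values, shape ``(n_points, 7)`` in :data:`CHANNELS` order.
        Missing measurements are stored as NaN.
    id
        Unique identifier within a collection.
    provenance
        ``"original"`` for (simulated) experimental cycles, ``"synthetic"``
        for generated ones.
    meta
        Free-form metadata (e.g. applied faults, aeration window).
    """

    time: np.ndarray
    values: np.ndarray
    id: str = "exp"
    provenance: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.values.shape != (self.time.size, len(CHANNELS)):
            raise ValueError(
                f"values must have shape ({self.time.size}, {len(CHANNELS)}), "
                f"got {self.values.shape}"
            )
        if self.provenance not in ("original", "synthetic"):
            raise ValueError("provenance must be 'original' or 'synthetic'")

    @property
    def n_points(self) -> int:
        return self.time.size

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a measurement is missing; shape like values."""
        return np.isnan(self.values)

    def channel(self, name: str) -> np.ndarray:
        """Values of one channel (view)."""
        return self.values[:, channel_index(name)]

    def copy(self, **changes) -> "ExperimentSeries":
        """Deep copy, optionally replacing fields."""
        out = replace(
            self,
            time=self.time.copy(),
            values=self.values.copy(),
            meta=dict(self.meta),
        )
        for key, val in changes.items():
            setattr(out, key, val)
        return out


class ExperimentCollection:
    """Ordered list of :class:`ExperimentSeries` sharing grid length and channels."""

    def __init__(self, series: Sequence[ExperimentSeries]):
        series = list(series)
        if series:
            n = series[0].n_points
            if any(s.n_points != n for s in series):
                raise ValueError("all series in a collection must share grid length")
        ids = [s.id for s in series]
        if len(set(ids)) != len(ids):
            raise ValueError("series ids must be unique within a collection")
        self.series = series

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[ExperimentSeries]:
        return iter(self.series)

    def __getitem__(self, key):
        if isinstance(key, (int, np.integer)):
            return self.series[key]
        if isinstance(key, slice):
            return ExperimentCollection(self.series[key])
        # a sequence of indices selects a sub-collection
        return ExperimentCollection([self.series[int(i)] for i in key])

    @property
    def n_points(self) -> int:
        if not self.series:
            raise ValueError("empty collection has no grid")
        return self.series[0].n_points

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.series]

    def subset(self, indices) -> "ExperimentCollection":
        return self[indices]

    def stacked_values(self) -> np.ndarray:
        """All series stacked into shape ``(n_series, n_points, 7)``."""
        return np.stack([s.values for s in self.series])

    def copy(self) -> "ExperimentCollection":
        return ExperimentCollection([s.copy() for s in self.series])

    def __add__(self, other: "ExperimentCollection") -> "ExperimentCollection":
        return ExperimentCollection(self.series + other.series)
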