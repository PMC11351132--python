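"""Fidelity diagnostics: t-SNE overlays, histogram overlap, prediction plots.

Every plotting operation also returns (and can write) its underlying
numbers, so figures are never the only record of a result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE

from .core import CHANNELS, ExperimentCollection, ExperimentSeries, channel_index
from .metrics import r_squared, rmse
from .preprocess import Normalizer, to_regression_arrays
from .soft_sensor import SoftSensorModel, predict_ethanol

__all__ = [
    "EmbeddingResult",
    "tsne_overlay",
    "histogram_report",
    "histogram_overlap",
    "prediction_overlay",
]


@dataclass
class EmbeddingResult:
    """2-D t-SNE coordinates, one point per experiment, with group labels."""

    coords: np.ndarray          # (n_experiments, 2)
    labels: list[str]           # "original" | "synthetic" per point
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.labels), 2):
            raise ValueError("one 2-D point per labelled experiment required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


def _flatten(collection: ExperimentCollection, normalizer: Normalizer | None) -> np.ndarray:
    data = collection.stacked_values()
    if normalizer is not None:
        data = normalizer.transform_values(data)
    if np.isnan(data).any():
        raise ValueError("collections must be imputed before embedding")
    return data.reshape(len(collection), -1)


def tsne_overlay(
    originals: ExperimentCollection,
    synthetics: ExperimentCollection,
    perplexity: float = 10.0,
    seed: int = 0,
    normalizer: Normalizer | None = None,
    plot_path: str | Path | None = None,
) -> EmbeddingResult:
    """Embed whole experiments (flattened n_points x 7 vectors) in 2-D.

    Originals and synthetics are embedded jointly so their overlap in the
    plane reflects distributional similarity of entire trajectories.
    """
    if len(originals) < 3 or len(synthetics) < 3:
        raise ValueError("need at least 3 experiments per group")
    X = np.vstack([_flatten(originals, normalizer), _flatten(synthetics, normalizer)])
    if perplexity >= X.shape[0]:
        raise ValueError(f"perplexity {perplexity} must be < {X.shape[0]} points")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = np.asarray(tsne.fit_transform(X), dtype=float)
    labels = ["original"] * len(originals) + ["synthetic"] * len(synthetics)
    result = EmbeddingResult(coords=coords, labels=labels,
                             perplexity=perplexity, seed=seed)
    if plot_path is not None:
        fig, ax = plt.subplots(figsize=(6, 5))
        orig = coords[: len(originals)]
        syn = coords[len(originals):]
        ax.scatter(syn[:, 0], syn[:, 1], marker="h", c="tab:blue", alpha=0.6,
                   label="synthetic")
        ax.scatter(orig[:, 0], orig[:, 1], marker="^", c="tab:red", label="original")
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        _dump_json(Path(plot_path).with_suffix(".json"),
                   {"coords": coords.tolist(), "labels": labels})
    return result


def histogram_overlap(a: np.ndarray, b: np.ndarray, bins: int = 30) -> float:
    """Intersection of normalized histograms over the pooled range, in [0, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty channel")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def histogram_report(
    originals: ExperimentCollection,
    synthetics: ExperimentCollection,
    bins: int = 30,
    plot_path: str | Path | None = None,
) -> dict[str, float]:
    """Per-channel histogram-intersection scores between the pooled original
    and synthetic values (1 = identical binned distributions)."""
    scores = {}
    for name in CHANNELS:
        col = channel_index(name)
        a = originals.stacked_values()[:, :, col]
        b = synthetics.stacked_values()[:, :, col]
        scores[name] = histogram_overlap(a, b, bins=bins)
    if plot_path is not None:
        fig, axes = plt.subplots(1, len(CHANNELS), figsize=(3 * len(CHANNELS), 3))
        for ax, name in zip(axes, CHANNELS):
            col = channel_index(name)
            a = originals.stacked_values()[:, :, col].ravel()
            b = synthetics.stacked_values()[:, :, col].ravel()
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            rng = (min(a.min(), b.min()), max(a.max(), b.max()))
            ax.hist(a, bins=bins, range=rng, alpha=0.5, density=True, label="original")
            ax.hist(b, bins=bins, range=rng, alpha=0.5, density=True, label="synthetic")
            ax.set_title(f"{name} ({scores[name]:.2f})", fontsize=9)
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        _dump_json(Path(plot_path).with_suffix(".json"), scores)
    return scores


def prediction_overlay(
    model: SoftSensorModel,
    test_series: ExperimentSeries,
    normalizer: Normalizer | None = None,
    plot_path: str | Path | None = None,
) -> tuple[float, float]:
    """Predicted vs measured ethanol for one test experiment (normalized
    units); returns (R^2, RMSE) computed with the shared metric functions."""
    normalizer = normalizer or model.normalizer
    if normalizer is None:
        raise ValueError("a normalizer is required to scale the test experiment")
    coll = ExperimentCollection([test_series])
    if np.isnan(test_series.channel("ethanol")).all():
        raise ValueError("test experiment is missing its ethanol channel")
    from .preprocess import apply_normalizer  # local import avoids cycle

    features, targets = to_regression_arrays(apply_normalizer(coll, normalizer))
    pred = predict_ethanol(model, features)
    y, y_hat = targets.ravel(), pred.ravel()
    scores = (r_squared(y, y_hat), rmse(y, y_hat))
    if plot_path is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        t = test_series.time
        ax.plot(t[::10], y[::10], "o", ms=3, c="tab:blue", label="measured")
        ax.plot(t, y_hat, c="tab:orange", label="predicted")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("ethanol (normalized)")
        ax.set_title(f"R$^2$={scores[0]:.3f}  RMSE={scores[1]:.3f}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        _dump_json(Path(plot_path).with_suffix(".json"),
                   {"time_h": t.tolist(), "measured": y.tolist(),
                    "predicted": y_hat.tolist(), "r2": scores[0], "rmse": scores[1]})
    return scores


def _dump_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1))
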