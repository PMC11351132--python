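"""Repeated leave-one-experiment-out evaluation of the augmentation regimes.

The protocol mirrors the augmentation study: in each iteration one original
experiment is held out as the test set, the remaining ten originals form
the training core, and — depending on the regime — 0, 10 or the full pool
of synthetic experiments is added.  A fresh soft sensor is trained per
iteration and scored on the held-out original experiment; the resulting
metric distributions across iterations are compared between regimes with
Welch's t-test (means) and the Levene test (spreads).

All metrics are computed in normalized target space: the min-max normalizer
is fit on the iteration's *original training experiments only* and applied
unchanged to the synthetic sets and the held-out experiment, so no test
information leaks into scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import INPUT_CHANNELS, TARGET_CHANNEL, ExperimentCollection, channel_index
from .metrics import (
    adjusted_r_squared,
    levene_test,
    mean_absolute_error,
    percent_change,
    r_squared,
    rmse,
    welch_t_test,
)
from .preprocess import apply_normalizer, fit_normalizer, to_regression_arrays
from .soft_sensor import FNNConfig, predict_ethanol, train_soft_sensor

__all__ = [
    "MetricSet",
    "RegimeSpec",
    "MetricDistribution",
    "ComparisonTable",
    "REGIMES",
    "split_experiments",
    "compose_regime",
    "evaluate_split",
    "repeated_evaluation",
    "comparison_table",
]

#: Predictor count entering adjusted R^2 (the four probe channels).
N_PREDICTORS = len(INPUT_CHANNELS)

METRIC_NAMES = ("r2", "adj_r2", "mae", "rmse")


@dataclass
class MetricSet:
    """Test-set metrics of one evaluation split (normalized target space)."""

    r2: float
    adj_r2: float
    mae: float
    rmse: float
    test_id: str = ""

    def __post_init__(self) -> None:
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")
        if self.rmse < 0:
            raise ValueError("RMSE cannot be negative")
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")


@dataclass(frozen=True)
class RegimeSpec:
    """Composition of a training set: 10 originals plus synthetic sets.

    ``n_synthetic`` may be an integer (sampled from the pool without
    replacement) or ``"all"`` (the entire pool, however large it is).
    """

    name: str
    n_synthetic: int | str = 0
    n_original_train: int = 10

    def __post_init__(self) -> None:
        if isinstance(self.n_synthetic, str) and self.n_synthetic != "all":
            raise ValueError("n_synthetic must be an integer or 'all'")
        if isinstance(self.n_synthetic, int) and self.n_synthetic < 0:
            raise ValueError("n_synthetic must be non-negative")


#: The study's three regimes.  "Augmented100" takes the whole synthetic
#: pool (100 sets at full scale), per the study design.
REGIMES: dict[str, RegimeSpec] = {
    "Original": RegimeSpec("Original", 0),
    "Augmented10": RegimeSpec("Augmented10", 10),
    "Augmented100": RegimeSpec("Augmented100", "all"),
}


@dataclass
class MetricDistribution:
    """Per-iteration metric sets of one regime plus their summary."""

    regime: str
    metrics: list[MetricSet]

    @property
    def n_iter(self) -> int:
        return len(self.metrics)

    def values(self, metric: str) -> np.ndarray:
        if metric not in METRIC_NAMES:
            raise KeyError(f"unknown metric {metric!r}")
        return np.array([getattr(m, metric) for m in self.metrics], dtype=float)

    def summary(self) -> pd.DataFrame:
        rows = {
            m: {"mean": self.values(m).mean(), "sd": self.values(m).std(ddof=1)}
            for m in METRIC_NAMES
        }
        return pd.DataFrame(rows).T


def split_experiments(n_sets: int, seed) -> tuple[list[int], int]:
    """Uniformly draw one held-out experiment; the rest train.

    Whole time series stay grouped — the unit of splitting is the
    experiment, never the timestep.
    """
    if n_sets < 2:
        raise ValueError("need at least 2 experiments to split")
    rng = np.random.default_rng(seed)
    test = int(rng.integers(n_sets))
    train = [i for i in range(n_sets) if i != test]
    return train, test


def compose_regime(
    regime: RegimeSpec,
    original_train: ExperimentCollection,
    synthetic_pool: ExperimentCollection,
    seed,
) -> ExperimentCollection:
    """Assemble the training collection for one regime.

    Synthetic sets are drawn from the pool without replacement (or the whole
    pool for ``n_synthetic="all"``); originals always come first in
    stacking order.
    """
    if regime.n_synthetic == "all":
        chosen = list(range(len(synthetic_pool)))
    else:
        if regime.n_synthetic > len(synthetic_pool):
            raise ValueError(
                f"regime {regime.name!r} needs {regime.n_synthetic} synthetic sets "
                f"but the pool holds {len(synthetic_pool)}"
            )
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(len(synthetic_pool), regime.n_synthetic, replace=False))
    if not chosen:
        return ExperimentCollection(list(original_train))
    return original_train + synthetic_pool[chosen]


def evaluate_split(
    originals: ExperimentCollection,
    synthetic_pool: ExperimentCollection,
    regime: RegimeSpec,
    train_ids: list[int],
    test_id: int,
    seed,
    fnn_config: FNNConfig | None = None,
) -> MetricSet:
    """Train one soft sensor under ``regime`` and score the held-out set."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    regime_seed, fnn_seed = ss.spawn(2)
    original_train = originals[train_ids]
    train_coll = compose_regime(regime, original_train, synthetic_pool, regime_seed)
    n_train_sets = len(train_coll)

    normalizer = fit_normalizer(original_train, "minmax")
    train_norm = apply_normalizer(train_coll, normalizer)
    test_norm = apply_normalizer(originals[[test_id]], normalizer)

    features, targets = to_regression_arrays(train_norm)
    cfg = fnn_config or FNNConfig()
    cfg = FNNConfig(**{**cfg.__dict__, "seed": int(fnn_seed.generate_state(1)[0] % 2**31)})
    model = train_soft_sensor(features, targets, cfg, normalizer)

    test_features, test_targets = to_regression_arrays(test_norm)
    pred = predict_ethanol(model, test_features)
    y, y_hat = test_targets.ravel(), pred.ravel()
    r2 = r_squared(y, y_hat)
    return MetricSet(
        r2=r2,
        adj_r2=adjusted_r_squared(r2, N=n_train_sets, p=N_PREDICTORS),
        mae=mean_absolute_error(y, y_hat),
        rmse=rmse(y, y_hat),
        test_id=originals[test_id].id,
    )


def repeated_evaluation(
    originals: ExperimentCollection,
    synthetic_pool: ExperimentCollection,
    regime: RegimeSpec | str,
    n_iter: int = 100,
    base_seed: int = 0,
    fnn_config: FNNConfig | None = None,
) -> MetricDistribution:
    """Run the repeated split protocol for one regime.

    Each iteration draws its own split, regime composition and network seed
    from a hierarchically split base seed, so distributions for different
    regimes at the same ``base_seed`` share their train/test splits.
    """
    if isinstance(regime, str):
        regime = REGIMES[regime]
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_iter)
    results = []
    for i, child in enumerate(children):
        split_seed, eval_seed = child.spawn(2)
        train_ids, test_id = split_experiments(len(originals), split_seed)
        try:
            results.append(
                evaluate_split(
                    originals, synthetic_pool, regime,
                    train_ids, test_id, eval_seed, fnn_config,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"iteration {i} failed for regime {regime.name}") from exc
    return MetricDistribution(regime=regime.name, metrics=results)


@dataclass
class ComparisonTable:
    """Summary comparison of regimes: means, sds, percent changes vs the
    baseline regime, Welch p for means and Levene p for spreads."""

    table: pd.DataFrame
    baseline: str = "Original"
    alpha: float = 0.05

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def comparison_table(
    dist_orig: MetricDistribution,
    dist_aug10: MetricDistribution,
    dist_aug100: MetricDistribution,
    alpha: float = 0.05,
) -> ComparisonTable:
    """Assemble the regime-comparison summary.

    Percent-change cells are blank for the baseline rows and recompute from
    the table's own mean/sd cells.  Adjusted R^2 has no spread comparison
    columns at the baseline scale distinction — it is summarized like the
    other metrics from its per-iteration values.
    """
    dists = [dist_orig, dist_aug10, dist_aug100]
    n = {d.n_iter for d in dists}
    if len(n) != 1:
        raise ValueError(f"distributions disagree on iteration count: {sorted(n)}")
    baseline = dists[0]
    rows = []
    for metric in METRIC_NAMES:
        base_vals = baseline.values(metric)
        for d in dists:
            vals = d.values(metric)
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
            if d is baseline:
                rows.append({
                    "metric": metric, "model": d.regime,
                    "mean": mean, "pct_change_mean": None, "p_welch": None,
                    "sd": sd, "pct_change_sd": None, "p_levene": None,
                    "significant_mean": None, "significant_sd": None,
                })
                continue
            _, _, p_welch = welch_t_test(base_vals, vals)
            _, p_levene = levene_test(base_vals, vals)
            rows.append({
                "metric": metric, "model": d.regime,
                "mean": mean,
                "pct_change_mean": percent_change(float(base_vals.mean()), mean),
                "p_welch": p_welch,
                "sd": sd,
                "pct_change_sd": percent_change(float(base_vals.std(ddof=1)), sd),
                "p_levene": p_levene,
                "significant_mean": p_welch < alpha,
                "significant_sd": p_levene < alpha,
            })
    return ComparisonTable(table=pd.DataFrame(rows), baseline=baseline.regime, alpha=alpha)
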