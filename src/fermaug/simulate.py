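"""Simulator for very-high-gravity (VHG) ethanol fermentation cycles.

Generates batches of fermentation experiments with the statistical structure
the downstream augmentation study assumes: ~10 h cycles sampled on a 500-point
grid, a temperature cascade stepping 34 -> 28 degC in 2 degC drops keyed to
ethanol concentration, an ethanol endpoint near 108 g/L, realistic
between-cycle variability, per-channel sensor noise, and the two sensor
faults the analysis must survive (an entirely missing redox channel and a
systematically offset capacitance probe).

The kinetic core is a Monod growth law with linear ethanol-product inhibition
and a small maintenance term:

    dX/dt = mu_max * S/(K_s + S) * max(0, 1 - P/P_max) * X
    dS/dt = -(1/Y_xs) * dX/dt  -  m * X          (zero once S is exhausted)
    dP/dt = Y_ps * (-dS/dt)

where X, S, P are cell, substrate and ethanol concentrations (g/L).  The
choice is deliberately the simplest model that yields the qualitative VHG
trajectories: a sigmoidal ethanol rise that saturates near the inhibition
ceiling, mirrored substrate depletion, and modest biomass growth.  Probe
channels are derived maps: capacitance is affine in viable cells, redox
declines affinely with ethanol, pH drifts slightly around its setpoint, and
the temperature setpoint follows the ethanol-keyed cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import CHANNELS, INPUT_CHANNELS, ExperimentCollection, ExperimentSeries, channel_index

__all__ = [
    "SimulatorParams",
    "FaultSpec",
    "kinetic_rhs",
    "simulate_experiment",
    "inject_fault",
    "simulate_study",
    "default_fault_plan",
]


@dataclass
class SimulatorParams:
    """Kinetic constants, sensor maps, cascade plan and noise scales.

    Defaults are tuned so a noise-free default run reaches ~108 g/L ethanol
    at 10 h with the cascade ending at 28 degC.
    """

    # grid
    duration_h: float = 10.0
    n_points: int = 500

    # kinetics
    mu_max: float = 0.35        # 1/h, maximum specific growth rate
    K_s: float = 8.0            # g/L, Monod substrate affinity
    Y_ps: float = 0.45          # g ethanol / g substrate
    Y_xs: float = 0.035         # g cells / g substrate
    P_max: float = 113.0        # g/L, ethanol ceiling (full growth inhibition)
    maintenance: float = 0.01   # g substrate / g cells / h
    S0: float = 250.0           # g/L initial substrate (very high gravity)
    X0: float = 8.0             # g/L initial cells (recycled, high pitch)

    # temperature cascade, 2 degC drops keyed to ethanol concentration
    cascade_levels: tuple = (34.0, 32.0, 30.0, 28.0)
    cascade_thresholds: tuple = (40.0, 70.0, 95.0)   # g/L ethanol

    # micro-aeration flag (no kinetic effect; recorded in metadata only)
    aeration_trigger: float = 108.0    # g/L ethanol
    aeration_window_h: float = 3.5

    # sensor maps
    capacitance_gain: float = 0.9      # pF/cm per g/L viable cells
    capacitance_baseline: float = 1.5  # pF/cm
    redox_baseline: float = -80.0      # mV at zero ethanol
    redox_decline: float = 1.0         # mV per g/L ethanol
    pH_setpoint: float = 4.6
    pH_drift: float = 0.15             # total downward drift over the cycle

    # between-cycle sensor variability: probes are recalibrated/refouled
    # between cycles, so their baselines shift from experiment to experiment
    # (ORP probes especially drift by tens of mV)
    redox_baseline_sd: float = 40.0        # mV
    capacitance_baseline_sd: float = 0.3   # pF/cm
    pH_setpoint_sd: float = 0.05

    # stochastic structure
    noise_sd: dict = field(default_factory=lambda: {
        "pH": 0.01,
        "redox": 5.0,
        "capacitance": 0.15,
        "temperature": 0.05,
        "ethanol": 1.5,
        "substrate": 3.0,
        "cells": 0.3,
    })
    between_experiment_cv: float = 0.10

    # integration substeps per output interval (fixed-step RK4)
    n_substeps: int = 10

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        for name in ("mu_max", "K_s", "Y_ps", "Y_xs", "P_max", "S0", "X0", "maintenance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        levels = np.asarray(self.cascade_levels, dtype=float)
        if not np.allclose(np.diff(levels), -2.0):
            raise ValueError("cascade_levels must decrease in 2 degC steps")
        thresholds = np.asarray(self.cascade_thresholds, dtype=float)
        if thresholds.size != levels.size - 1:
            raise ValueError("need one cascade threshold per 2 degC drop")
        if thresholds.size and np.any(np.diff(thresholds) <= 0):
            raise ValueError("cascade_thresholds must be strictly increasing")
        unknown = set(self.noise_sd) - set(CHANNELS)
        if unknown:
            raise ValueError(f"noise_sd has unknown channels: {sorted(unknown)}")

    def with_multipliers(self, mult: dict) -> "SimulatorParams":
        """Copy with kinetic constants scaled by per-experiment multipliers."""
        kwargs = {k: getattr(self, k) * v for k, v in mult.items()}
        base = dict(self.__dict__)
        base["noise_sd"] = dict(self.noise_sd)
        return self.__class__(**{**base, **kwargs})


#: Kinetic constants that receive between-experiment lognormal multipliers.
PERTURBED_CONSTANTS = ("mu_max", "K_s", "Y_ps", "Y_xs", "P_max", "S0", "X0")


def kinetic_rhs(state, t: float, params: SimulatorParams):
    """Time derivatives (dX/dt, dS/dt, dP/dt) of the fermentation kinetics.

    ``state`` is (cells, substrate, ethanol) in g/L.  Derivatives are all
    zero once substrate is exhausted; growth stops at the ethanol ceiling.
    """
    X, S, P = state
    if X < 0 or S < -1e-12 or P < 0:
        raise ValueError(f"negative state rejected: X={X}, S={S}, P={P}")
    if S <= 0:
        return (0.0, 0.0, 0.0)
    inhibition = max(0.0, 1.0 - P / params.P_max)
    dX = params.mu_max * S / (params.K_s + S) * inhibition * X
    dS = -dX / params.Y_xs - params.maintenance * X
    dP = params.Y_ps * (-dS)
    return (dX, dS, dP)


def _integrate(params: SimulatorParams) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 on the output grid with substeps; returns (time, XSP).

    RK4 is used (rather than an adaptive solver) because it preserves the
    linear invariant Y_ps*(S0 - S) = P - P0 exactly and keeps the sampled
    trajectory monotone wherever the derivative does not change sign.
    """
    time = np.linspace(0.0, params.duration_h, params.n_points)
    h = (time[1] - time[0]) / params.n_substeps
    state = np.array([params.X0, params.S0, 0.0], dtype=float)
    out = np.empty((params.n_points, 3))
    out[0] = state

    def rhs(s, t):
        return np.array(kinetic_rhs(np.maximum(s, 0.0), t, params))

    t = 0.0
    for i in range(1, params.n_points):
        for _ in range(params.n_substeps):
            k1 = rhs(state, t)
            k2 = rhs(state + 0.5 * h * k1, t + 0.5 * h)
            k3 = rhs(state + 0.5 * h * k2, t + 0.5 * h)
            k4 = rhs(state + h * k3, t + h)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        if not np.all(np.isfinite(state)):
            raise RuntimeError(
                f"integration diverged at t={t:.3f} h for parameter set {params}"
            )
        out[i] = state
    out[:, 1] = np.maximum(out[:, 1], 0.0)   # clip integrator dust at exhaustion
    return time, out


def _temperature_cascade(ethanol: np.ndarray, params: SimulatorParams) -> np.ndarray:
    levels = np.asarray(params.cascade_levels, dtype=float)
    thresholds = np.asarray(params.cascade_thresholds, dtype=float)
    n_crossed = np.searchsorted(thresholds, ethanol, side="right")
    # the cascade never steps back up even if noise-free ethanol plateaus
    n_crossed = np.maximum.accumulate(n_crossed)
    return levels[n_crossed]


def simulate_experiment(params: SimulatorParams, seed) -> ExperimentSeries:
    """Simulate one fermentation cycle.

    Per-experiment lognormal multipliers (CV = ``between_experiment_cv``)
    are applied to the kinetic constants before integration; probe channels
    are derived from the kinetic trajectory; additive Gaussian noise at
    ``noise_sd`` is applied per channel.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cv = params.between_experiment_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        mult = {
            name: float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))
            for name in PERTURBED_CONSTANTS
        }
        run_params = params.with_multipliers(mult)
    else:
        mult = {}
        run_params = params

    time, xsp = _integrate(run_params)
    cells, substrate, ethanol = xsp[:, 0], xsp[:, 1], xsp[:, 2]

    # per-cycle sensor baselines (probe recalibration between cycles)
    redox_base = params.redox_baseline + rng.normal(0.0, params.redox_baseline_sd)
    cap_base = params.capacitance_baseline + rng.normal(0.0, params.capacitance_baseline_sd)
    pH_set = params.pH_setpoint + rng.normal(0.0, params.pH_setpoint_sd)

    values = np.empty((params.n_points, len(CHANNELS)))
    frac = time / params.duration_h
    values[:, channel_index("pH")] = pH_set - params.pH_drift * frac
    values[:, channel_index("redox")] = redox_base - params.redox_decline * ethanol
    values[:, channel_index("capacitance")] = (
        params.capacitance_gain * cells + cap_base
    )
    values[:, channel_index("temperature")] = _temperature_cascade(ethanol, params)
    values[:, channel_index("ethanol")] = ethanol
    values[:, channel_index("substrate")] = substrate
    values[:, channel_index("cells")] = cells

    for name, sd in params.noise_sd.items():
        if sd > 0:
            col = channel_index(name)
            values[:, col] = values[:, col] + rng.normal(0.0, sd, size=params.n_points)

    above = np.nonzero(ethanol >= params.aeration_trigger)[0]
    aeration_start = float(time[above[0]]) if above.size else None

    return ExperimentSeries(
        time=time,
        values=values,
        id="exp",
        provenance="original",
        meta={
            "kinetic_multipliers": mult,
            "aeration_start_h": aeration_start,
            "aeration_window_h": params.aeration_window_h,
            "faults": [],
        },
    )


@dataclass(frozen=True)
class FaultSpec:
    """A planned sensor fault in one experiment of a study.

    ``missing_channel`` blanks an entire probe channel (failed sensor);
    ``offset_channel`` adds a constant bias (uncalibrated sensor).
    """

    kind: str
    channel: str
    experiment_index: int
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("missing_channel", "offset_channel"):
            raise ValueError(f"unknown fault kind {self.kind!r}")
        if self.channel not in INPUT_CHANNELS:
            raise ValueError(
                f"fault channel must be one of the probe channels {INPUT_CHANNELS}"
            )
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")


def inject_fault(series: ExperimentSeries, fault: FaultSpec) -> ExperimentSeries:
    """Apply one sensor fault, returning a new series; other channels untouched."""
    out = series.copy()
    col = channel_index(fault.channel)
    if fault.kind == "missing_channel":
        out.values[:, col] = np.nan
    elif fault.kind == "offset_channel":
        out.values[:, col] = out.values[:, col] + fault.offset
    else:  # pragma: no cover - guarded by FaultSpec
        raise ValueError(f"unknown fault kind {fault.kind!r}")
    out.meta.setdefault("faults", [])
    out.meta["faults"] = list(out.meta["faults"]) + [
        {"kind": fault.kind, "channel": fault.channel, "offset": fault.offset}
    ]
    return out


def default_fault_plan(n_experiments: int = 11) -> list[FaultSpec]:
    """The study's two sensor problems: one failed redox sensor and one
    consistently offset capacitance probe (distinct experiments)."""
    if n_experiments < 2:
        raise ValueError("need at least 2 experiments for the default fault plan")
    capacitance_idx = min(8, n_experiments - 1)
    redox_idx = 4 if capacitance_idx != 4 else 3
    redox_idx = min(redox_idx, n_experiments - 1)
    if redox_idx == capacitance_idx:
        redox_idx = capacitance_idx - 1
    return [
        FaultSpec("missing_channel", "redox", experiment_index=redox_idx),
        FaultSpec("offset_channel", "capacitance", experiment_index=capacitance_idx,
                  offset=3.5),
    ]


def simulate_study(
    params: SimulatorParams,
    n_experiments: int = 11,
    fault_plan: Optional[Sequence[FaultSpec]] = None,
    seed: int = 0,
) -> ExperimentCollection:
    """Simulate a full study of independent fermentation cycles.

    Seeds are split hierarchically (study seed -> per-experiment child
    seeds), so increasing ``n_experiments`` never perturbs earlier cycles.
    """
    if n_experiments < 2:
        raise ValueError("n_experiments must be >= 2")
    if fault_plan is None:
        fault_plan = default_fault_plan(n_experiments)
    for fault in fault_plan:
        if not (0 <= fault.experiment_index < n_experiments):
            raise IndexError(
                f"fault index {fault.experiment_index} out of range for "
                f"{n_experiments} experiments"
            )
    children = np.random.SeedSequence(seed).spawn(n_experiments)
    series = []
    width = max(2, len(str(n_experiments)))
    for i, child in enumerate(children):
        s = simulate_experiment(params, child)
        s.id = f"exp{i + 1:0{width}d}"
        series.append(s)
    for fault in fault_plan:
        series[fault.experiment_index] = inject_fault(series[fault.experiment_index], fault)
        series[fault.experiment_index].id = series[fault.experiment_index].id
    return ExperimentCollection(series)
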