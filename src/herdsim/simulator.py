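"""Monte-Carlo driver: initialization, realizations, stationary summaries.

A realization initializes a population, applies the synchronous step for a
fixed budget of steps (default 3000), and records strategy frequencies and
per-strategy mean effective payoffs at every step.  The stationary state is
operationally defined as the average over the last 25% of recorded steps.
An experiment repeats this over independent realizations (default 30, each
with seed ``master_seed + i``), optionally drawing a fresh scale-free
network per realization, and reports means and standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, synchronous_step
from .networks import Network, build_scale_free
from .payoffs import GameParams, HerdingParams, compute_payoffs
from .strategies import (
    HC,
    HD,
    N_STRATEGIES,
    NHC,
    STRATEGY_NAMES,
    VARIANT_SETS,
    frequencies,
    strategy_code,
)

__all__ = [
    "SimConfig",
    "TimeSeries",
    "StationarySummary",
    "initialize_population",
    "run_realization",
    "summarize_stationary",
    "run_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo budget and initialization settings."""

    max_steps: int = 3000
    realizations: int = 30
    measure_fraction: float = 0.25
    initial_mix: dict[str, float] | None = None
    master_seed: int = 0
    fresh_network_per_realization: bool = True
    exact_counts: bool = False
    record_payoffs: bool = True

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if self.realizations < 1:
            raise ValueError("realizations must be positive")
        if not 0.0 < self.measure_fraction <= 1.0:
            raise ValueError("measure_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class TimeSeries:
    """Per-step record of one realization.

    ``freq[t, s]`` is the frequency of strategy ``s`` at step ``t``
    (t = 0 is the initial state; there are ``max_steps + 1`` rows).
    ``payoff[t, s]`` is the mean effective payoff of strategy ``s`` at
    step ``t`` (NaN where the strategy is absent).
    """

    freq: np.ndarray
    payoff: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"freq_{name}": self.freq[:, s] for s, name in enumerate(STRATEGY_NAMES)}
        cols |= {f"payoff_{name}": self.payoff[:, s] for s, name in enumerate(STRATEGY_NAMES)}
        return pd.DataFrame(cols).rename_axis("step")


@dataclass(frozen=True)
class StationarySummary:
    """Stationary fractions aggregated over realizations (mean and std)."""

    strategy_mean: np.ndarray
    strategy_std: np.ndarray
    cooperation_mean: float
    cooperation_std: float
    herder_mean: float
    herder_std: float
    realizations: int = 0

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {
            "cooperation_mean": self.cooperation_mean,
            "cooperation_std": self.cooperation_std,
            "herder_mean": self.herder_mean,
            "herder_std": self.herder_std,
            "realizations": self.realizations,
        }
        for s, name in enumerate(STRATEGY_NAMES):
            out[f"freq_{name}_mean"] = float(self.strategy_mean[s])
            out[f"freq_{name}_std"] = float(self.strategy_std[s])
        return out


def _mix_vector(mix: dict[str, float] | None, variant: str) -> np.ndarray:
    """Length-4 probability vector from a name->fraction mapping.

    Defaults: equal 25% over the four strategies in the co-evolutionary
    game; 50/50 cooperators and defectors in the two-strategy games.
    """
    strategy_set = VARIANT_SETS[variant]
    probs = np.zeros(N_STRATEGIES)
    if mix is None:
        probs[strategy_set] = 1.0 / strategy_set.size
        return probs
    for name, frac in mix.items():
        code = strategy_code(name) if name.upper() in STRATEGY_NAMES else None
        if code is None:
            # bare actions C/D map onto the variant's own trait
            if name.upper() == "C":
                code = HC if strategy_set[0] == HC else NHC
            elif name.upper() == "D":
                code = HD if strategy_set[0] == HC else strategy_code("NHD")
            else:
                raise ValueError(f"unknown strategy {name!r}")
        probs[code] += frac
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial mix must sum to 1, got {probs.sum()!r}")
    if np.any(probs[np.setdiff1d(np.arange(N_STRATEGIES), strategy_set)] > 0):
        raise ValueError(f"mix assigns mass outside the {variant} strategy set")
    return probs


def initialize_population(
    net: Network,
    mix: dict[str, float] | np.ndarray | None,
    rng: np.random.Generator,
    variant: str = "four_strategy",
    exact_counts: bool = False,
) -> np.ndarray:
    """Assign initial strategies by i.i.d. categorical draws (default) or
    exact-count shuffled placement."""
    probs = mix if isinstance(mix, np.ndarray) else _mix_vector(mix, variant)
    if abs(float(np.sum(probs)) - 1.0) > 1e-9:
        raise ValueError(f"initial mix must sum to 1, got {float(np.sum(probs))}")
    n = net.node_count
    if exact_counts:
        counts = np.floor(np.asarray(probs) * n).astype(int)
        remainder = n - counts.sum()
        order = np.argsort(-(np.asarray(probs) * n - counts))
        counts[order[:remainder]] += 1
        state = np.repeat(np.arange(N_STRATEGIES, dtype=np.int8), counts)
        rng.shuffle(state)
        return state
    return rng.choice(N_STRATEGIES, size=n, p=probs).astype(np.int8)


def _strategy_mean_payoffs(state: np.ndarray, eff: np.ndarray) -> np.ndarray:
    """Mean effective payoff per strategy; NaN where a strategy is absent."""
    sums = np.bincount(state, weights=eff, minlength=N_STRATEGIES)
    counts = np.bincount(state, minlength=N_STRATEGIES)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def run_realization(
    net: Network,
    gp: GameParams,
    hp: HerdingParams,
    dp: DynamicsParams,
    sc: SimConfig,
    seed: int,
    initial_state: np.ndarray | None = None,
) -> TimeSeries:
    """One seeded Monte-Carlo realization over ``sc.max_steps`` synchronous steps."""
    rng = np.random.default_rng(seed)
    if initial_state is None:
        state = initialize_population(
            net, sc.initial_mix, rng, dp.variant, exact_counts=sc.exact_counts
        )
    else:
        state = np.asarray(initial_state, dtype=np.int8).copy()
    steps = sc.max_steps
    freq = np.empty((steps + 1, N_STRATEGIES))
    payoff = np.full((steps + 1, N_STRATEGIES), np.nan)
    from .dynamics import _discount_mask  # payoffs recorded as the focal side sees them

    for t in range(steps + 1):
        freq[t] = frequencies(state)
        pv = compute_payoffs(state, net, gp, hp)
        if sc.record_payoffs:
            d = _discount_mask(state, dp.variant)
            eff = pv.raw - d * pv.herding_cost
            payoff[t] = _strategy_mean_payoffs(state, eff)
        if t < steps:
            state = synchronous_step(state, net, gp, hp, dp, rng, pv=pv)
    return TimeSeries(freq=freq, payoff=payoff)


def summarize_stationary(series: TimeSeries | np.ndarray, measure_fraction: float = 0.25) -> np.ndarray:
    """Mean strategy frequencies over the last ``measure_fraction`` of steps.

    The window is the final ``ceil(measure_fraction * n_recorded)`` entries.
    """
    if not 0.0 < measure_fraction <= 1.0:
        raise ValueError("measure_fraction must lie in (0, 1]")
    freq = series.freq if isinstance(series, TimeSeries) else np.asarray(series, dtype=np.float64)
    if freq.size == 0:
        raise ValueError("empty time series")
    window = int(np.ceil(measure_fraction * freq.shape[0]))
    return freq[-window:].mean(axis=0)


def run_experiment(
    net: Network | None,
    gp: GameParams,
    hp: HerdingParams,
    dp: DynamicsParams,
    sc: SimConfig,
    network_factory=None,
) -> StationarySummary:
    """Aggregate stationary summaries over ``sc.realizations`` seeded runs.

    Realization ``i`` uses seed ``master_seed + i``.  When
    ``fresh_network_per_realization`` is set and a ``network_factory``
    (callable ``seed -> Network``) is given, each realization gets its own
    network — the convention for scale-free topologies, which avoids
    anchoring results to one particular preferential-attachment draw.
    """
    if net is None and network_factory is None:
        raise ValueError("either a network or a network_factory is required")
    per_real = np.empty((sc.realizations, N_STRATEGIES))
    for i in range(sc.realizations):
        seed = sc.master_seed + i
        if network_factory is not None and (sc.fresh_network_per_realization or net is None):
            net_i = network_factory(seed)
        else:
            net_i = net
        series = run_realization(net_i, gp, hp, dp, sc, seed)
        per_real[i] = summarize_stationary(series, sc.measure_fraction)
    coop = per_real[:, HC] + per_real[:, NHC]
    herd = per_real[:, HC] + per_real[:, HD]
    return StationarySummary(
        strategy_mean=per_real.mean(axis=0),
        strategy_std=per_real.std(axis=0),
        cooperation_mean=float(coop.mean()),
        cooperation_std=float(coop.std()),
        herder_mean=float(herd.mean()),
        herder_std=float(herd.std()),
        realizations=sc.realizations,
    )


def scale_free_factory(n: int, m: int = 2):
    """Callable ``seed -> Network`` drawing a fresh BA graph per realization."""

    def factory(seed: int) -> Network:
        return build_scale_free(n, m, seed=seed)

    return factory
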