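"""Experiment families: S-T phase sweeps and tau sensitivity sweeps.

A sweep runs the Monte-Carlo experiment over a grid of game parameters and
tabulates stationary cooperation, herder fraction and per-strategy
frequencies, together with deltas against the tau = 0 plain pairwise-game
baseline at the same (S, T) cell (matched network spec and seeds).  Results
come back as a tidy :class:`pandas.DataFrame` — one row per (S, T, tau)
cell — ready for CSV export or heatmap rendering downstream.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams
from .networks import Network, build_lattice, build_scale_free, build_well_mixed
from .payoffs import GameParams, HerdingParams
from .simulator import SimConfig, StationarySummary, run_experiment
from .strategies import STRATEGY_NAMES

__all__ = ["NetworkSpec", "SweepSpec", "sweep_st", "sweep_tau", "PHASE_TABLE_COLUMNS"]

logger = logging.getLogger(__name__)

PHASE_TABLE_COLUMNS = (
    ["S", "T", "tau", "cooperation", "cooperation_std", "herders", "herders_std"]
    + [f"freq_{name}" for name in STRATEGY_NAMES]
    + ["baseline_cooperation", "delta_cooperation", "delta_herders"]
)


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative network description, instantiable per realization."""

    kind: str = "scale_free"
    n: int = 1000
    m: int = 2
    rows: int = 70
    cols: int = 70

    def build(self, seed: int | None = None) -> Network:
        if self.kind == "lattice":
            return build_lattice(self.rows, self.cols)
        if self.kind == "scale_free":
            return build_scale_free(self.n, self.m, seed=seed)
        if self.kind == "well_mixed":
            return build_well_mixed(self.n)
        raise ValueError(f"cannot build network of kind {self.kind!r}")

    def factory(self):
        if self.kind == "scale_free":
            return lambda seed: build_scale_free(self.n, self.m, seed=seed)
        fixed = self.build()
        return lambda seed: fixed


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition for a phase sweep."""

    S_values: tuple[float, ...] = tuple(np.round(np.linspace(-1, 1, 21), 6))
    T_values: tuple[float, ...] = tuple(np.round(np.linspace(0, 2, 21), 6))
    tau_values: tuple[float, ...] = (1.0,)
    variant: str = "four_strategy"
    crowd_mode: str = "local"
    network: NetworkSpec = field(default_factory=NetworkSpec)
    beta: float = 5.0
    mu: float = 0.01
    sim: SimConfig = field(default_factory=lambda: SimConfig(realizations=5))
    include_baseline: bool = True

    def __post_init__(self) -> None:
        if not self.S_values or not self.T_values or not self.tau_values:
            raise ValueError("S, T and tau grids must be nonempty")


def _cell(spec: SweepSpec, S: float, T: float, tau: float, variant: str) -> StationarySummary:
    gp = GameParams(S=S, T=T)
    hp = HerdingParams(tau=tau, crowd_mode=spec.crowd_mode)
    dp = DynamicsParams(beta=spec.beta, mu=spec.mu, variant=variant)
    sc = spec.sim if variant == spec.variant else replace(spec.sim, initial_mix=None)
    net = None if spec.network.kind == "scale_free" else spec.network.build()
    try:
        return run_experiment(net, gp, hp, dp, sc, network_factory=spec.network.factory())
    except Exception as exc:  # re-raise with the offending cell identified
        raise RuntimeError(f"sweep cell (S={S}, T={T}, tau={tau}) failed: {exc}") from exc


def _row(S, T, tau, summ: StationarySummary, base: StationarySummary | None) -> dict:
    row = {
        "S": S,
        "T": T,
        "tau": tau,
        "cooperation": summ.cooperation_mean,
        "cooperation_std": summ.cooperation_std,
        "herders": summ.herder_mean,
        "herders_std": summ.herder_std,
    }
    for s, name in enumerate(STRATEGY_NAMES):
        row[f"freq_{name}"] = float(summ.strategy_mean[s])
    if base is None:
        row["baseline_cooperation"] = summ.cooperation_mean
        row["delta_cooperation"] = 0.0
        row["delta_herders"] = 0.0
    else:
        row["baseline_cooperation"] = base.cooperation_mean
        row["delta_cooperation"] = summ.cooperation_mean - base.cooperation_mean
        row["delta_herders"] = summ.herder_mean - base.herder_mean
    return row


def sweep_st(spec: SweepSpec) -> pd.DataFrame:
    """Phase sweep over the (S, T) grid for every tau in the spec.

    Each cell runs the requested variant; when ``include_baseline`` is set
    a matched tau = 0 plain pairwise game is run once per (S, T) and its
    cooperation/herder fractions subtracted to give the deltas.  For
    tau = 0 cells the delta is zero by construction.
    """
    rows = []
    for tau in spec.tau_values:
        for S in spec.S_values:
            for T in spec.T_values:
                t0 = time.perf_counter()
                summ = _cell(spec, S, T, tau, spec.variant)
                base = None
                if spec.include_baseline and not (tau == 0 and spec.variant == "pairwise_plain"):
                    base = _cell(spec, S, T, 0.0, "pairwise_plain")
                rows.append(_row(S, T, tau, summ, base))
                logger.info(
                    "cell S=%.3g T=%.3g tau=%.3g coop=%.3f herd=%.3f (%.1fs)",
                    S, T, tau, summ.cooperation_mean, summ.herder_mean,
                    time.perf_counter() - t0,
                )
    return pd.DataFrame(rows, columns=PHASE_TABLE_COLUMNS)


def sweep_tau(
    spec: SweepSpec,
    st_pairs: tuple[tuple[float, float], ...] = ((-0.4, 0.9), (0.0, 2.0), (-0.1, 1.1)),
) -> pd.DataFrame:
    """Sensitivity of the co-evolutionary game to the social weight tau.

    For each (S, T) pair and each tau, reports the stationary HC and NHC
    fractions (the quantities tracked when asking how the herding weight
    shifts cooperating sub-populations), plus totals.
    """
    rows = []
    for S, T in st_pairs:
        for tau in spec.tau_values:
            summ = _cell(spec, S, T, tau, spec.variant)
            rows.append(_row(S, T, tau, summ, None))
            logger.info(
                "tau sweep S=%.3g T=%.3g tau=%.3g HC=%.3f NHC=%.3f",
                S, T, tau, summ.strategy_mean[0], summ.strategy_mean[2],
            )
    return pd.DataFrame(rows, columns=PHASE_TABLE_COLUMNS)
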