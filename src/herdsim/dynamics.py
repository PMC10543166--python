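"""One synchronous evolutionary step: Fermi imitation with mutation.

Every step, all payoffs and herding costs are computed from the current
state.  Each player then independently either mutates (probability ``mu``,
drawing uniformly from the variant's strategy set, current strategy
included) or attempts imitation (probability ``1 - mu``): it picks one
neighbor uniformly at random and copies that neighbor's full strategy with
the Fermi probability

    p = 1 / (1 + exp(-beta * (Pi'_j - Pi'_i)))

where the effective payoffs Pi' depend on the game variant:

* ``pairwise_plain``      — raw payoffs, no herding cost anywhere.
* ``pairwise_herding``    — every player's payoff is discounted by its
  herding cost (the cost applies population-wide).
* ``four_strategy``       — the asymmetric co-evolutionary game: the
  discount is applied to *both* sides of the comparison if and only if the
  focal player carries the herding trait H.  The model player's own trait
  never enters this pair's evaluation — that asymmetry is the point of the
  bimatrix construction.

All replacements commit simultaneously (synchronous update).

Randomness contract
-------------------
For a population of size Z, one step consumes exactly four draws from the
supplied generator, in this order: ``rng.random(Z)`` (mutation coins),
``rng.integers(set_size, size=Z)`` (mutant strategies), ``rng.random(Z)``
(neighbor choice), ``rng.random(Z)`` (imitation coins).  Fixing this order
makes a step bit-reproducible and lets independent oracles replay it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .networks import Network
from .payoffs import GameParams, HerdingParams, PayoffVector, compute_payoffs
from .strategies import VARIANT_SETS, VARIANTS, is_herder

__all__ = [
    "DynamicsParams",
    "fermi_probability",
    "effective_payoffs",
    "synchronous_step",
]

_P_LO = np.nextafter(0.0, 1.0)
_P_HI = np.nextafter(1.0, 0.0)


@dataclass(frozen=True)
class DynamicsParams:
    """Selection intensity beta, mutation rate mu, and the game variant."""

    beta: float = 5.0
    mu: float = 0.01
    variant: str = "four_strategy"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def strategy_set(self) -> np.ndarray:
        return VARIANT_SETS[self.variant]


def fermi_probability(payoff_diff, beta: float):
    """Logistic imitation probability, overflow-safe, clamped to (0, 1).

    Strictly increasing in the payoff difference; 0.5 at zero difference;
    satisfies p(x) + p(-x) = 1.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    p = expit(beta * np.asarray(payoff_diff, dtype=np.float64))
    p = np.clip(p, _P_LO, _P_HI)
    return float(p) if np.isscalar(payoff_diff) else p


def _discount_mask(state: np.ndarray, variant: str) -> np.ndarray:
    """Per-focal-node indicator: does this node's comparison use discounted payoffs?"""
    if variant == "pairwise_plain":
        return np.zeros(state.size, dtype=bool)
    if variant == "pairwise_herding":
        return np.ones(state.size, dtype=bool)
    return np.asarray(is_herder(state))


def effective_payoffs(
    focal: int,
    model: int,
    pv: PayoffVector,
    state: np.ndarray,
    variant: str,
    net: Network | None = None,
) -> tuple[float, float]:
    """(Pi'_focal, Pi'_model) as evaluated in this pair's Fermi comparison.

    In the four-strategy game the focal player's herding trait decides
    whether both payoffs are discounted by their herding costs; a
    non-herding focal compares raw payoffs even against a herding model.
    """
    if net is not None and not net.well_mixed:
        if model not in net.neighbors(focal):
            raise ValueError(f"nodes {focal} and {model} are not adjacent")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    d = bool(_discount_mask(np.asarray(state), variant)[focal])
    if d:
        return float(pv.raw[focal] - pv.herding_cost[focal]), float(
            pv.raw[model] - pv.herding_cost[model]
        )
    return float(pv.raw[focal]), float(pv.raw[model])


def _random_neighbors(net: Network, u: np.ndarray) -> np.ndarray:
    """One uniformly chosen neighbor per node, from one uniform draw per node.

    Degree-0 nodes map to themselves (imitation becomes a no-op).
    """
    n = net.node_count
    if net.well_mixed:
        j = (u * (n - 1)).astype(np.int64)
        ids = np.arange(n, dtype=np.int64)
        return j + (j >= ids)
    deg = net.degrees
    offset = np.minimum((u * deg).astype(np.int64), np.maximum(deg - 1, 0))
    idx = net.adjacency.indptr[:-1] + offset
    j = net.adjacency.indices[idx].astype(np.int64)
    return np.where(deg > 0, j, np.arange(n, dtype=np.int64))


def synchronous_step(
    state: np.ndarray,
    net: Network,
    gp: GameParams,
    hp: HerdingParams,
    dp: DynamicsParams,
    rng: np.random.Generator,
    pv: PayoffVector | None = None,
) -> np.ndarray:
    """Advance the population one synchronous step; returns the new state.

    ``pv`` may supply payoffs already computed for ``state`` (as the
    simulator does when it records them); they are recomputed otherwise.
    """
    state = np.asarray(state, dtype=np.int8)
    n = net.node_count
    if n == 0:
        raise ValueError("empty network")
    if state.shape != (n,):
        raise ValueError(f"state size {state.shape} does not match Z={n}")
    if pv is None:
        pv = compute_payoffs(state, net, gp, hp)

    strategy_set = dp.strategy_set
    u_mut = rng.random(n)
    mut_pick = rng.integers(0, strategy_set.size, size=n)
    u_nb = rng.random(n)
    u_imit = rng.random(n)

    j = _random_neighbors(net, u_nb)
    d = _discount_mask(state, dp.variant).astype(np.float64)
    diff = (pv.raw[j] - pv.raw) - d * (pv.herding_cost[j] - pv.herding_cost)
    p = fermi_probability(diff, dp.beta)

    new_state = state.copy()
    imitate = (u_mut >= dp.mu) & (u_imit < p) & (j != np.arange(n))
    new_state[imitate] = state[j[imitate]]
    mutate = u_mut < dp.mu
    new_state[mutate] = strategy_set[mut_pick[mutate]]
    return new_state
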