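"""Game payoffs and the herding social cost.

The pairwise game is the standard two-parameter normalization of the
2x2 symmetric game: mutual cooperation pays R = 1, mutual defection P = 0,
a cooperator meeting a defector receives the sucker's payoff S and the
defector the temptation T.  Varying (S, T) over [-1, 1] x [0, 2] spans the
harmony, snowdrift, stag-hunt and prisoner's-dilemma regions.

Players with a herding mentality additionally pay a psychological cost for
standing apart from their crowd:

    h_i = tau * (|C_i| / <k>) * r_i

where |C_i| is the size of player i's crowd set (its degree, or Z - 1 when
the crowd is the whole population), <k> the network mean degree, r_i the
fraction of the crowd whose action differs from i's, and tau >= 0 the
social weight.  tau = 0 switches the mechanism off entirely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .networks import Network
from .strategies import C, D, action_of

__all__ = [
    "GameParams",
    "HerdingParams",
    "PayoffVector",
    "payoff_entry",
    "accumulate_payoffs",
    "herding_ratio",
    "herding_ratios",
    "herding_cost",
    "herding_costs",
    "compute_payoffs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GameParams:
    """(S, T) parameters of the normalized pairwise game; R = 1, P = 0 fixed."""

    S: float
    T: float

    #: normalization constants, not free parameters
    R: float = 1.0
    P: float = 0.0

    def __post_init__(self) -> None:
        if self.R != 1.0 or self.P != 0.0:
            raise ValueError("normalization fixes R = 1 and P = 0")
        if not (-1.0 <= self.S <= 1.0) or not (0.0 <= self.T <= 2.0):
            warnings.warn(
                f"(S={self.S}, T={self.T}) lies outside the standard exploration "
                "ranges S in [-1, 1], T in [0, 2]",
                stacklevel=2,
            )

    def matrix(self) -> np.ndarray:
        """Row-player payoff matrix indexed by (own action, other action)."""
        return np.array([[self.R, self.S], [self.T, self.P]])


@dataclass(frozen=True)
class HerdingParams:
    """Herding-cost configuration: social weight tau and crowd definition."""

    tau: float = 1.0
    crowd_mode: str = "local"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be non-negative, got {self.tau}")
        if self.crowd_mode not in ("local", "well_mixed"):
            raise ValueError(f"crowd_mode must be 'local' or 'well_mixed', got {self.crowd_mode!r}")


@dataclass(frozen=True)
class PayoffVector:
    """Per-node payoffs for one step: raw Pi, herding cost h, adjusted Pi - h."""

    raw: np.ndarray
    herding_cost: np.ndarray

    @property
    def adjusted(self) -> np.ndarray:
        return self.raw - self.herding_cost


def payoff_entry(action_focal: int, action_other: int, params: GameParams) -> float:
    """Single matrix entry: (C,C)->1, (C,D)->S, (D,C)->T, (D,D)->0."""
    if action_focal not in (C, D) or action_other not in (C, D):
        raise ValueError("actions must be C (0) or D (1)")
    return float(params.matrix()[action_focal, action_other])


def _cooperator_neighbor_counts(actions: np.ndarray, net: Network) -> np.ndarray:
    """Number of cooperating crowd members per node."""
    coop = (actions == C).astype(np.float64)
    if net.well_mixed:
        # crowd = everyone else; subtracting own indicator excludes self
        return coop.sum() - coop
    return net.adjacency @ coop


def accumulate_payoffs(state: np.ndarray, net: Network, params: GameParams) -> np.ndarray:
    """Per-node payoff Pi_i summed over all pairwise interactions this step.

    Payoffs are recomputed fresh every step; nothing carries over.  For a
    cooperator with n_C cooperating and n_D defecting neighbors the total is
    n_C * 1 + n_D * S; for a defector it is n_C * T.
    """
    state = np.asarray(state)
    if state.shape != (net.node_count,):
        raise ValueError(
            f"state has {state.shape[0] if state.ndim == 1 else 'wrong'} entries "
            f"for a network of {net.node_count} nodes"
        )
    actions = action_of(state)
    n_coop = _cooperator_neighbor_counts(actions, net)
    n_def = net.degrees - n_coop
    coop_payoff = n_coop * params.R + n_def * params.S
    def_payoff = n_coop * params.T + n_def * params.P
    return np.where(actions == C, coop_payoff, def_payoff)


def herding_ratios(state: np.ndarray, net: Network, crowd_mode: str = "local") -> np.ndarray:
    """r_i for every node: crowd fraction whose *action* differs from i's.

    Only the C/D action enters the comparison — the herding trait is a
    mentality, not an observable behavior.  Degree-0 nodes (possible only
    through custom edge lists) get r = 0 and are effectively inert.
    """
    state = np.asarray(state)
    actions = action_of(state)
    if crowd_mode == "well_mixed" or net.well_mixed:
        n = state.size
        if n < 2:
            raise ValueError("well-mixed crowd needs Z >= 2")
        n_coop_others = (actions == C).sum() - (actions == C)
        n_diff = np.where(actions == C, (n - 1) - n_coop_others, n_coop_others)
        return n_diff / (n - 1)
    degrees = net.degrees
    n_coop = _cooperator_neighbor_counts(actions, net)
    n_diff = np.where(actions == C, degrees - n_coop, n_coop)
    if np.any(degrees == 0):
        logger.warning("degree-0 node(s) present; their herding ratio is defined as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degrees > 0, n_diff / np.maximum(degrees, 1), 0.0)
    return r


def herding_ratio(node: int, state: np.ndarray, net: Network, crowd_mode: str = "local") -> float:
    """Scalar r_i for a single node (convenience wrapper over the vector form)."""
    return float(herding_ratios(state, net, crowd_mode)[node])


def herding_costs(ratios: np.ndarray, net: Network, hp: HerdingParams) -> np.ndarray:
    """Vector of h_i = tau * (k_i / <k>) * r_i.

    In well-mixed crowd mode both the crowd size and <k> equal Z - 1, the
    scale factor cancels, and h = tau * r.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    if np.any((ratios < 0) | (ratios > 1)):
        raise ValueError("herding ratios must lie in [0, 1]")
    if hp.tau == 0:
        return np.zeros_like(ratios)
    if hp.crowd_mode == "well_mixed" or net.well_mixed:
        return hp.tau * ratios
    return hp.tau * (net.degrees / net.mean_degree) * ratios


def herding_cost(node: int, ratio: float, net: Network, hp: HerdingParams) -> float:
    """Scalar h_i for one node given its ratio r_i."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must be in [0, 1], got {ratio}")
    if hp.tau == 0:
        return 0.0
    if hp.crowd_mode == "well_mixed" or net.well_mixed:
        return hp.tau * ratio
    return hp.tau * (float(net.degrees[node]) / net.mean_degree) * ratio


def compute_payoffs(
    state: np.ndarray, net: Network, gp: GameParams, hp: HerdingParams
) -> PayoffVector:
    """Raw payoffs and herding costs for the whole population in one pass."""
    raw = accumulate_payoffs(state, net, gp)
    if hp.tau == 0:
        costs = np.zeros_like(raw)
    else:
        costs = herding_costs(herding_ratios(state, net, hp.crowd_mode), net, hp)
    return PayoffVector(raw=raw, herding_cost=costs)
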