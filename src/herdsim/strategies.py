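"""Strategy encoding shared by the payoff and dynamics modules.

A strategy combines an action (cooperate C / defect D) with a herding
trait (herding H / non-herding NH).  The four combinations are encoded as
small integers so population states are plain ``int8`` arrays:

====  ====  =======  ========
code  name  action   herding
====  ====  =======  ========
0     HC    C        H
1     HD    D        H
2     NHC   C        NH
3     NHD   D        NH
====  ====  =======  ========

``action(s) = s & 1`` (0 = C, 1 = D) and ``is_herder(s) = s < 2``.
The two-strategy games use a fixed trait: the plain pairwise game lives on
{NHC, NHD}, the uniform herding-cost game on {HC, HD}; the co-evolutionary
asymmetric game uses all four.
"""

from __future__ import annotations

import numpy as np

HC, HD, NHC, NHD = 0, 1, 2, 3

STRATEGY_NAMES = ("HC", "HD", "NHC", "NHD")
N_STRATEGIES = 4

C, D = 0, 1
ACTION_NAMES = ("C", "D")

#: strategy sets, by dynamics variant
VARIANT_SETS = {
    "pairwise_plain": np.array([NHC, NHD], dtype=np.int8),
    "pairwise_herding": np.array([HC, HD], dtype=np.int8),
    "four_strategy": np.array([HC, HD, NHC, NHD], dtype=np.int8),
}

VARIANTS = tuple(VARIANT_SETS)


def action_of(state: np.ndarray | int) -> np.ndarray | int:
    """Action component: 0 for C, 1 for D."""
    return state & 1


def is_herder(state: np.ndarray | int) -> np.ndarray | bool:
    """True where the herding trait is H (codes HC, HD)."""
    return state < 2


def strategy_code(name: str) -> int:
    try:
        return STRATEGY_NAMES.index(name.upper())
    except ValueError:
        raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}") from None


def frequencies(state: np.ndarray) -> np.ndarray:
    """Length-4 vector of strategy frequencies (sums to 1)."""
    return np.bincount(state, minlength=N_STRATEGIES) / state.size
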