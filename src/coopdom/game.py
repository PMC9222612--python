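"""Core mechanics of the multilayer prisoner's dilemma.

This module holds the mathematical heart of the simulator: the
single-parameter payoff matrix, the cross-layer dominance conversion that
turns intrinsic strategy *labels* into the *effective* strategies actually
played in a round, per-round accumulated payoffs, and the Fermi
(pairwise-comparison) imitation rule.

Strategies are coded as integers throughout the array code: ``1`` for
cooperate (C), ``0`` for defect (D).  The :class:`Strategy` IntEnum gives
them readable names at the scalar API surface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "Strategy",
    "DominanceMode",
    "PayoffMatrix",
    "PopulationState",
    "pair_payoff",
    "apply_dominance",
    "round_payoffs",
    "fermi_probability",
    "imitation_update",
]

C = 1
D = 0


class Strategy(enum.IntEnum):
    """The two pure strategies of the prisoner's dilemma."""

    D = 0
    C = 1


class DominanceMode(str, enum.Enum):
    """Cross-layer strategy-updating rule.

    ``natural``
        Layers evolve independently; effective strategies equal labels.
    ``coop_dominance``
        If any node in a coupling group carries the cooperate label, every
        member of the group plays C this round.
    ``defect_dominance``
        If any node in a coupling group carries the defect label, every
        member plays D; only all-cooperator groups keep playing C.
    """

    NATURAL = "natural"
    COOP = "coop_dominance"
    DEFECT = "defect_dominance"

    @classmethod
    def coerce(cls, value: "DominanceMode | str") -> "DominanceMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown dominance mode {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class PayoffMatrix:
    """Prisoner's dilemma payoffs generated by the temptation parameter r.

    Reward R = 1, sucker S = -r, temptation T = 1 + r, punishment P = 0.
    For every r > 0 the PD ordering T > R > P > S holds, as does the
    dilemma condition 2R >= T + S (here strictly: T + S = 1 < 2).

    Parameters
    ----------
    r : float
        Temptation parameter, strictly positive.
    """

    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"payoff parameter r must be > 0, got {self.r}")

    @property
    def reward(self) -> float:
        return 1.0

    @property
    def sucker(self) -> float:
        return -self.r

    @property
    def temptation(self) -> float:
        return 1.0 + self.r

    @property
    def punishment(self) -> float:
        return 0.0

    def table(self) -> np.ndarray:
        """2x2 payoff table indexed ``[focal_strategy, opponent_strategy]``."""
        return np.array(
            [
                [self.punishment, self.temptation],  # focal D vs (D, C)
                [self.sucker, self.reward],  # focal C vs (D, C)
            ]
        )


def pair_payoff(
    s_focal: Strategy | int, s_opponent: Strategy | int, matrix: PayoffMatrix
) -> float:
    """Payoff of the focal player in a single pairwise interaction."""
    return float(matrix.table()[int(s_focal), int(s_opponent)])


def apply_dominance(labels, mode: DominanceMode | str, axis: int = 0) -> np.ndarray:
    """Convert strategy labels into the effective strategies played this round.

    ``labels`` holds one strategy per (layer, node); ``axis`` indexes the
    layers, so each slice along it is a coupling group.  Works on a 1-D
    group (one entry per layer) just as well as on a full ``(n_layers, N)``
    state.  The labels themselves are never modified; the round's effective
    strategies are returned as a new array.

    The conversion is idempotent: a group that is uniform after conversion
    maps to itself.
    """
    mode = DominanceMode.coerce(mode)
    arr = np.asarray(labels, dtype=np.int8)
    if arr.size == 0:
        raise ValueError("labels must be non-empty")
    if mode is DominanceMode.NATURAL:
        return arr.copy()
    if mode is DominanceMode.COOP:
        # any C in the group -> everyone plays C
        group = arr.any(axis=axis, keepdims=True)
    else:
        # any D in the group -> everyone plays D; only all-C groups keep C
        group = arr.all(axis=axis, keepdims=True)
    return np.broadcast_to(group, arr.shape).astype(np.int8)


def round_payoffs(layer, effective, matrix: PayoffMatrix) -> np.ndarray:
    """Per-node payoff accumulated over all within-layer neighbours.

    Node x playing strategy ``effective[x]`` meets every graph neighbour y
    once and collects ``pair_payoff(effective[x], effective[y])``; an
    isolated node scores 0.  Payoffs are per-round: nothing carries over
    between rounds.
    """
    eff = np.asarray(effective, dtype=np.float64)
    n_coop_nb = layer.adjacency_matrix() @ eff  # cooperating neighbours
    deg = layer.degrees
    pi_if_c = matrix.reward * n_coop_nb + matrix.sucker * (deg - n_coop_nb)
    pi_if_d = matrix.temptation * n_coop_nb + matrix.punishment * (deg - n_coop_nb)
    return np.where(eff == 1, pi_if_c, pi_if_d)


def fermi_probability(pi_x, pi_y, kappa: float):
    """Probability that x imitates y under the Fermi pairwise-comparison rule.

    W = 1 / (1 + exp((pi_x - pi_y) / kappa)).

    kappa is the selection intensity: small kappa makes imitation nearly
    deterministic in the payoff difference, large kappa approaches random
    drift (W -> 1/2).  Accepts scalars or arrays; numerically stable for
    arbitrarily large payoff differences.
    """
    if not kappa > 0:
        raise ValueError(f"selection intensity kappa must be > 0, got {kappa}")
    z = (np.asarray(pi_y, dtype=np.float64) - np.asarray(pi_x, dtype=np.float64)) / kappa
    return expit(np.clip(z, -500.0, 500.0))


def imitation_update(layer, labels, source, payoffs, kappa: float, rng) -> np.ndarray:
    """Synchronous Fermi imitation step for one layer.

    Every node x picks one uniform-random neighbour y and, with probability
    ``fermi_probability(payoffs[x], payoffs[y], kappa)``, sets its
    next-round label to ``source[y]`` (the strategy it observed y playing);
    otherwise it keeps its current label.  Isolated nodes keep their label.

    Draw order is fixed — one block of neighbour picks, then one block of
    Bernoulli coins, node-major — so runs are bit-reproducible from the rng.

    Parameters
    ----------
    labels : (N,) int array
        Current intrinsic labels.
    source : (N,) int array
        Strategies available for copying (normally the round's effective
        strategies; optionally the labels).
    payoffs : (N,) float array
        This round's payoffs, computed from the same effective strategies.
    """
    labels = np.asarray(labels, dtype=np.int8)
    source = np.asarray(source, dtype=np.int8)
    deg = layer.degrees
    n = layer.n_nodes
    u = rng.random(n)
    # floor(u * deg) indexes into each node's CSR neighbour block
    offset = np.minimum((u * deg).astype(np.int64), np.maximum(deg - 1, 0))
    pos = layer.neighbor_indptr[:-1] + offset
    np.minimum(pos, len(layer.neighbor_indices) - 1, out=pos)  # isolated tail nodes
    picked = layer.neighbor_indices[pos]
    w = fermi_probability(payoffs, payoffs[picked], kappa)
    coins = rng.random(n)
    adopt = (coins < w) & (deg > 0)
    return np.where(adopt, source[picked], labels).astype(np.int8)


@dataclass
class PopulationState:
    """Full strategy state of the multilayer population at one round.

    ``labels`` are the intrinsic strategies (updated only between rounds by
    imitation); ``effective`` are what each node actually played this round
    after dominance conversion; ``payoffs`` the round's accumulated payoffs.
    All three are ``(n_layers, N)`` arrays.
    """

    labels: np.ndarray
    effective: np.ndarray
    payoffs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.effective = np.asarray(self.effective, dtype=np.int8)
        if self.labels.shape != self.effective.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != effective shape "
                f"{self.effective.shape}"
            )
        if self.payoffs is None:
            self.payoffs = np.zeros(self.labels.shape, dtype=np.float64)

    @property
    def n_layers(self) -> int:
        return self.labels.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[1]
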