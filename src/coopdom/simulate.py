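"""Simulation driver: rounds, trajectories, replicates and summaries.

A simulation advances a :class:`~coopdom.game.PopulationState` over a
:class:`~coopdom.networks.MultilayerNetwork` in synchronous rounds:

1. dominance conversion turns the current labels into the round's
   effective strategies, per coupling group;
2. per-layer payoffs accumulate over all within-layer neighbours;
3. every node imitates a random neighbour by the Fermi rule, and the new
   labels commit together at the next round.

The principal observable is the per-layer cooperator fraction over time;
stationary behaviour is summarised over the trailing window of the run and
pooled across independent replicates (fresh network realisations each).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .game import (
    DominanceMode,
    PayoffMatrix,
    PopulationState,
    apply_dominance,
    imitation_update,
    round_payoffs,
)
from .networks import Layer, LayerSpec, MultilayerNetwork, build_layer

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SummaryStats",
    "initialize_labels",
    "cooperator_fraction",
    "step",
    "run",
    "run_replicates",
    "summarize",
    "sweep_r",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulation experiment.

    r : temptation parameter of the payoff matrix (> 0)
    kappa : Fermi selection intensity (default 0.1)
    mode : dominance rule coupling the layers
    initial_fractions : per-layer initial cooperator fraction, each in [0,1]
    n_steps : number of synchronous rounds (default 1000)
    counting : which strategies the cooperator fraction counts —
        "label" (intrinsic labels, the default) or "effective" (what was
        actually played after dominance conversion)
    imitation_source : what an imitating node copies from its neighbour —
        the neighbour's "effective" played strategy (default; what the
        node actually observed) or its intrinsic "label"
    seed : root seed; every replicate and layer stream derives from it
    n_replicates : independent repetitions with fresh networks (default 20)
    stationary_window : trailing steps over which summaries average
        (default 200)
    """

    r: float
    mode: DominanceMode | str = DominanceMode.NATURAL
    initial_fractions: tuple[float, ...] = (0.5, 0.5)
    kappa: float = 0.1
    n_steps: int = 1000
    counting: str = "label"
    imitation_source: str = "effective"
    seed: int = 0
    n_replicates: int = 20
    stationary_window: int = 200

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        object.__setattr__(self, "mode", DominanceMode.coerce(self.mode))
        object.__setattr__(
            self, "initial_fractions", tuple(float(f) for f in self.initial_fractions)
        )
        for f in self.initial_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"initial fraction {f} outside [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        if self.counting not in ("label", "effective"):
            raise ValueError(f"counting must be 'label' or 'effective', got {self.counting!r}")
        if self.imitation_source not in ("label", "effective"):
            raise ValueError(
                f"imitation_source must be 'label' or 'effective', got {self.imitation_source!r}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if not 1 <= self.stationary_window <= self.n_steps:
            raise ValueError(
                f"stationary_window must be in [1, n_steps], got {self.stationary_window}"
            )

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class Trajectory:
    """Per-layer cooperator-fraction time series of one run.

    ``fractions`` has shape ``(n_layers, n_steps + 1)``; index 0 is the
    initial state, so ``fractions[l][0] == round(f_l * N) / N``.
    """

    fractions: np.ndarray
    config: SimulationConfig
    replicate: int = 0

    @property
    def n_layers(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.fractions.shape[1] - 1

    def stationary_mean(self, window: int | None = None) -> np.ndarray:
        window = window or self.config.stationary_window
        return self.fractions[:, -window:].mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        n_layers, n_rec = self.fractions.shape
        return pd.DataFrame(
            {
                "replicate": self.replicate,
                "step": np.tile(np.arange(n_rec), n_layers),
                "layer": np.repeat(np.arange(n_layers), n_rec),
                "fraction": self.fractions.ravel(),
            }
        )


@dataclass
class SummaryStats:
    """Stationary-window summary pooled across replicates.

    ``means``/``sds`` are per-layer statistics of the cooperator fraction
    over the last ``window`` recorded steps of every replicate.
    """

    means: np.ndarray
    sds: np.ndarray
    n_replicates: int
    window: int

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "n_replicates": self.n_replicates,
            "window": self.window,
        }


def _layer_seedseqs(
    seed: int, replicate: int, n_layers: int
) -> list[np.random.SeedSequence]:
    """Deterministic per-(replicate, layer) seed chains from one root seed.

    Keyed construction (not sequential spawning) so that a single-layer run
    can be handed exactly the stream a layer would receive inside a
    multilayer run — in natural mode the two are then bit-identical.
    """
    return [
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate, ell))
        for ell in range(n_layers)
    ]


def initialize_labels(
    multilayer: MultilayerNetwork,
    initial_fractions: Sequence[float],
    rngs,
) -> PopulationState:
    """Place exactly round(f_l * N) cooperator labels uniformly per layer.

    ``rngs`` is one Generator per layer (or a single Generator used for
    all layers).  Effective strategies start equal to labels and payoffs
    at zero.
    """
    n_layers, n = multilayer.n_layers, multilayer.n_nodes
    if len(initial_fractions) != n_layers:
        raise ValueError(
            f"{len(initial_fractions)} initial fractions for {n_layers} layers"
        )
    if isinstance(rngs, np.random.Generator):
        rngs = [rngs] * n_layers
    labels = np.zeros((n_layers, n), dtype=np.int8)
    for ell, (f, rng) in enumerate(zip(initial_fractions, rngs)):
        n_coop = int(np.floor(f * n + 0.5))
        coop_ids = rng.choice(n, size=n_coop, replace=False)
        labels[ell, coop_ids] = 1
    return PopulationState(labels=labels, effective=labels.copy())


def cooperator_fraction(
    state: PopulationState, layer_index: int, counting: str = "label"
) -> float:
    """Fraction of cooperators in one layer, by label or by played strategy."""
    if not 0 <= layer_index < state.n_layers:
        raise IndexError(f"no layer {layer_index}")
    if counting == "label":
        strategies = state.labels[layer_index]
    elif counting == "effective":
        strategies = state.effective[layer_index]
    else:
        raise ValueError(f"counting must be 'label' or 'effective', got {counting!r}")
    return float(strategies.mean())


def step(
    multilayer: MultilayerNetwork,
    state: PopulationState,
    config: SimulationConfig,
    rngs,
) -> PopulationState:
    """One synchronous round: dominance, payoffs, Fermi imitation.

    Returns a new state whose ``labels`` are next round's committed labels
    and whose ``effective``/``payoffs`` are what was played and earned in
    *this* round.  ``rngs`` is one Generator per layer (or one shared).
    """
    if isinstance(rngs, np.random.Generator):
        rngs = [rngs] * multilayer.n_layers
    matrix = PayoffMatrix(config.r)
    effective = apply_dominance(state.labels, config.mode, axis=0)
    payoffs = np.empty_like(effective, dtype=np.float64)
    next_labels = np.empty_like(state.labels)
    for ell, layer in enumerate(multilayer):
        payoffs[ell] = round_payoffs(layer, effective[ell], matrix)
    for ell, (layer, rng) in enumerate(zip(multilayer, rngs)):
        source = effective[ell] if config.imitation_source == "effective" else state.labels[ell]
        next_labels[ell] = imitation_update(
            layer, state.labels[ell], source, payoffs[ell], config.kappa, rng
        )
    return PopulationState(labels=next_labels, effective=effective, payoffs=payoffs)


def run(
    multilayer: MultilayerNetwork,
    config: SimulationConfig,
    *,
    replicate: int = 0,
    layer_seedseqs: Sequence[np.random.SeedSequence] | None = None,
) -> Trajectory:
    """Run ``config.n_steps`` rounds and record the cooperator fractions.

    The trajectory has ``n_steps + 1`` entries per layer; entry 0 is the
    initial state.  With ``counting="label"`` entry t reads the labels
    committed after round t; with ``counting="effective"`` it reads the
    strategies played during round t (post-dominance, pre-commit).
    Fully reproducible from ``(config, replicate)``.
    """
    n_layers = multilayer.n_layers
    if layer_seedseqs is None:
        layer_seedseqs = _layer_seedseqs(config.seed, replicate, n_layers)
    # each layer's chain: child 0 reserved for network build, 1 for the
    # initial labels, 2 for the per-step imitation draws
    chains = [ss.spawn(3) for ss in layer_seedseqs]
    init_rngs = [np.random.default_rng(c[1]) for c in chains]
    step_rngs = [np.random.default_rng(c[2]) for c in chains]

    state = initialize_labels(multilayer, config.initial_fractions, init_rngs)
    fractions = np.empty((n_layers, config.n_steps + 1), dtype=np.float64)
    for ell in range(n_layers):
        fractions[ell, 0] = cooperator_fraction(state, ell, "label")
    for t in range(1, config.n_steps + 1):
        state = step(multilayer, state, config, step_rngs)
        for ell in range(n_layers):
            fractions[ell, t] = cooperator_fraction(state, ell, config.counting)
    return Trajectory(fractions=fractions, config=config, replicate=replicate)


def run_replicates(
    layer_specs: Sequence[LayerSpec], config: SimulationConfig
) -> list[Trajectory]:
    """Run ``config.n_replicates`` independent simulations.

    Every replicate rebuilds fresh network realisations from its own seed
    chain, draws fresh initial labels and runs the full dynamics.
    """
    trajectories = []
    for rep in range(config.n_replicates):
        seqs = _layer_seedseqs(config.seed, rep, len(layer_specs))
        layers = [
            build_layer(spec, seed=ss.spawn(3)[0])
            for spec, ss in zip(layer_specs, seqs)
        ]
        multilayer = MultilayerNetwork(layers)
        trajectories.append(
            run(multilayer, config, replicate=rep, layer_seedseqs=seqs)
        )
    return trajectories


def summarize(trajectories: Sequence[Trajectory], window: int | None = None) -> SummaryStats:
    """Pooled per-layer stationary mean and sd over the trailing window."""
    if not trajectories:
        raise ValueError("no trajectories to summarize")
    shapes = {t.fractions.shape for t in trajectories}
    if len(shapes) != 1:
        raise ValueError(f"trajectories have mismatched shapes: {shapes}")
    window = window or trajectories[0].config.stationary_window
    n_recorded = trajectories[0].fractions.shape[1] - 1
    if window > n_recorded:
        raise ValueError(f"window {window} exceeds recorded steps {n_recorded}")
    # (n_replicates, n_layers, window) -> pool replicate & time axes
    tail = np.stack([t.fractions[:, -window:] for t in trajectories])
    return SummaryStats(
        means=tail.mean(axis=(0, 2)),
        sds=tail.std(axis=(0, 2)),
        n_replicates=len(trajectories),
        window=window,
    )


def sweep_r(
    layer_specs: Sequence[LayerSpec],
    r_values: Sequence[float],
    config_template: SimulationConfig,
) -> pd.DataFrame:
    """Stationary summaries over a grid of payoff parameters r.

    For each r, runs ``config_template.n_replicates`` independent
    simulations (fresh networks and initial conditions each) and tabulates
    the per-layer stationary mean and sd.

    Returns a DataFrame with columns
    ``r, layer, mean, sd, n_replicates, window``.
    """
    r_values = list(r_values)
    if not r_values:
        raise ValueError("r_values must be non-empty")
    rows = []
    for r in r_values:
        config = config_template.with_(r=float(r))
        stats = summarize(run_replicates(layer_specs, config))
        for ell in range(len(stats.means)):
            rows.append(
                {
                    "r": float(r),
                    "layer": ell,
                    "mean": float(stats.means[ell]),
                    "sd": float(stats.sds[ell]),
                    "n_replicates": stats.n_replicates,
                    "window": stats.window,
                }
            )
    return pd.DataFrame(rows)
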