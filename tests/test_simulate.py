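import numpy as np
import pytest

from coopdom.game import PopulationState, apply_dominance
from coopdom.networks import LayerSpec, MultilayerNetwork, build_ba, build_ws
from coopdom.simulate import (
    SimulationConfig,
    Trajectory,
    _layer_seedseqs,
    cooperator_fraction,
    initialize_labels,
    run,
    run_replicates,
    step,
    summarize,
    sweep_r,
)
from conftest import make_multilayer


def small_config(**overrides):
    kwargs = dict(
        r=0.5, initial_fractions=(0.5, 0.5), n_steps=50, stationary_window=10, seed=1
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            dict(r=-0.1),
            dict(kappa=0.0),
            dict(initial_fractions=(0.5, 1.2)),
            dict(counting="majority"),
            dict(imitation_source="payoff"),
            dict(stationary_window=100, n_steps=50),
            dict(n_replicates=0),
        ],
    )
    def test_bad_values_rejected(self, overrides):
        with pytest.raises(ValueError):
            small_config(**overrides)

    def test_mode_coerced_from_string(self):
        assert small_config(mode="coop_dominance").mode.value == "coop_dominance"


class TestInitialization:
    @pytest.mark.parametrize("f,expected", [(0.5, 250), (0.3, 150), (0.0, 0), (1.0, 500)])
    def test_exact_cooperator_counts(self, f, expected):
        ml = MultilayerNetwork([build_ba(500, 2, seed=0)])
        state = initialize_labels(ml, [f], np.random.default_rng(0))
        assert int(state.labels.sum()) == expected

    def test_effective_starts_equal_to_labels(self):
        ml = make_multilayer(2, 20)
        state = initialize_labels(ml, [0.5, 0.3], np.random.default_rng(3))
        assert np.array_equal(state.labels, state.effective)
        assert np.all(state.payoffs == 0.0)

    def test_wrong_fraction_count_rejected(self):
        ml = make_multilayer(2, 20)
        with pytest.raises(ValueError):
            initialize_labels(ml, [0.5], np.random.default_rng(0))


class TestCounting:
    def test_label_vs_effective_after_coop_dominance(self):
        # one C label in layer 0 only: the coupled node plays C in both layers
        labels = np.array([[1, 0], [0, 0]], dtype=np.int8)
        state = PopulationState(
            labels=labels, effective=apply_dominance(labels, "coop_dominance")
        )
        assert cooperator_fraction(state, 1, "label") == 0.0
        assert cooperator_fraction(state, 1, "effective") == 0.5
        assert cooperator_fraction(state, 0, "label") == 0.5

    def test_bad_layer_index(self):
        state = PopulationState(
            labels=np.zeros((1, 4), dtype=np.int8),
            effective=np.zeros((1, 4), dtype=np.int8),
        )
        with pytest.raises(IndexError):
            cooperator_fraction(state, 3)


class TestDynamics:
    @pytest.mark.parametrize("mode", ["natural", "coop_dominance", "defect_dominance"])
    @pytest.mark.parametrize("fraction", [0.0, 1.0])
    def test_uniform_states_are_absorbing(self, mode, fraction):
        ml = make_multilayer(2, 30, seed=4)
        config = small_config(
            mode=mode, initial_fractions=(fraction, fraction), n_steps=100,
            stationary_window=100,
        )
        traj = run(ml, config)
        assert np.all(traj.fractions == fraction)

    def test_coupled_node_converts_in_both_layers(self):
        # coop dominance: a lone C label at node 0 of layer 0 makes the
        # whole coupling group play C this round
        ml = make_multilayer(2, 10, seed=8)
        labels = np.zeros((2, 10), dtype=np.int8)
        labels[0, 7] = 1
        state = PopulationState(labels=labels, effective=labels.copy())
        new = step(ml, state, small_config(mode="coop_dominance", n_steps=5,
                                           stationary_window=5),
                   np.random.default_rng(0))
        assert new.effective[0, 7] == 1 and new.effective[1, 7] == 1

    def test_trajectory_shape_and_bounds(self):
        ml = make_multilayer(3, 40, seed=2)
        config = SimulationConfig(
            r=0.3, initial_fractions=(0.5, 0.3, 0.5), n_steps=80,
            stationary_window=20, seed=5,
        )
        traj = run(ml, config)
        assert traj.fractions.shape == (3, 81)
        assert np.all((0.0 <= traj.fractions) & (traj.fractions <= 1.0))
        assert traj.fractions[0, 0] == pytest.approx(round(0.5 * 40) / 40)
        assert traj.fractions[1, 0] == pytest.approx(round(0.3 * 40) / 40)

    def test_bit_identical_reruns(self):
        ml = make_multilayer(2, 50, seed=6)
        config = small_config(seed=77)
        a = run(ml, config)
        b = run(ml, config)
        assert np.array_equal(a.fractions, b.fractions)

    def test_replicates_differ(self):
        ml = make_multilayer(2, 50, seed=6)
        config = small_config(seed=77)
        a = run(ml, config, replicate=0)
        b = run(ml, config, replicate=1)
        assert not np.array_equal(a.fractions, b.fractions)

    def test_natural_mode_decomposes_into_single_layers(self):
        """Uncoupled layers: the multilayer run equals per-layer runs."""
        layers = [build_ba(60, 2, seed=1), build_ws(60, 4, 0.5, seed=2)]
        ml = MultilayerNetwork(layers)
        config = small_config(mode="natural", initial_fractions=(0.5, 0.3), seed=13)
        joint = run(ml, config)
        seqs = _layer_seedseqs(config.seed, 0, 2)
        for ell, layer in enumerate(layers):
            single = run(
                MultilayerNetwork([layer]),
                config.with_(initial_fractions=(config.initial_fractions[ell],)),
                layer_seedseqs=[seqs[ell]],
            )
            assert np.array_equal(joint.fractions[ell], single.fractions[0])

    def test_dominance_counting_orderings(self):
        """Effective counts bound label counts under each dominance mode."""
        ml = make_multilayer(2, 40, seed=9)
        for mode, cmp in [("coop_dominance", np.greater_equal),
                          ("defect_dominance", np.less_equal)]:
            config = small_config(mode=mode, initial_fractions=(0.5, 0.4), seed=21)
            lab = run(ml, config.with_(counting="label"))
            eff = run(ml, config.with_(counting="effective"))
            # compare the played strategies of round t with the labels they
            # were converted from (recorded at t-1)
            assert np.all(cmp(eff.fractions[:, 1:], lab.fractions[:, :-1]))


class TestSummaries:
    def _const_traj(self, value, n_steps=20, window=10):
        config = SimulationConfig(
            r=0.5, initial_fractions=(value,), n_steps=n_steps,
            stationary_window=window, seed=0,
        )
        return Trajectory(np.full((1, n_steps + 1), value), config)

    def test_constant_trajectory(self):
        stats = summarize([self._const_traj(0.4)])
        assert stats.means[0] == pytest.approx(0.4)
        assert stats.sds[0] == pytest.approx(0.0)

    def test_pooling_across_replicates(self):
        stats = summarize([self._const_traj(0.2), self._const_traj(0.6)])
        assert stats.means[0] == pytest.approx(0.4)
        assert stats.n_replicates == 2

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            summarize([self._const_traj(0.4)], window=100)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            summarize([self._const_traj(0.4, n_steps=20), self._const_traj(0.4, n_steps=30)])


class TestSweep:
    def test_single_point_matches_direct_run(self):
        specs = [LayerSpec.ba(40, 2), LayerSpec.ws(40, 4, 0.5)]
        config = SimulationConfig(
            r=0.5, initial_fractions=(0.5, 0.3), n_steps=30,
            stationary_window=10, seed=3, n_replicates=1,
        )
        table = sweep_r(specs, [0.5], config)
        direct = summarize(run_replicates(specs, config))
        assert table["mean"].tolist() == pytest.approx(direct.means.tolist())
        assert len(table) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_r([LayerSpec.ba(40, 2)], [], small_config(initial_fractions=(0.5,)))

    def test_replicates_rebuild_networks(self):
        specs = [LayerSpec.ba(40, 2)]
        config = SimulationConfig(
            r=0.5, initial_fractions=(0.5,), n_steps=5, stationary_window=5,
            seed=3, n_replicates=2,
        )
        trajs = run_replicates(specs, config)
        assert len(trajs) == 2
        assert [t.replicate for t in trajs] == [0, 1]
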