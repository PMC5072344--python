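"""GA fitness, basin estimation, control search, essentiality."""

import numpy as np
import pytest

from boolscape.control import (GAConfig, essentiality, estimate_B,
                               exhaustive_control_search, fitness, ga_search)
from boolscape.landscape import MarkerConfig, basin_fraction, enumerate_landscape
from boolscape.network import apply_mutations, parse_bnet
from boolscape.synth import TOY_CONTROL

GA_FAST = GAConfig(population_size=40, generations=60, basin_samples=500,
                   rng_seed=7)


class TestFitness:
    def test_zero_basin_gives_zero(self):
        assert fitness(0.0, 197, 0) == 0.0
        assert fitness(0.0, 197, 50) == 0.0

    def test_full_basin_is_doubled(self):
        # B=1, n=197, four nodes selected: 2 * 193^2
        assert fitness(1.0, 197, 4) == 74498.0

    def test_partial_basin_direct_arithmetic(self):
        assert fitness(0.5, 10, 0) == pytest.approx(12.5)

    def test_doubling_discontinuity_is_exact(self):
        """The x2 bonus applies at B == 1 exactly, not within a tolerance."""
        n, k = 20, 2
        just_below = 999 / 1000  # counted-sample fraction, not a float fuzz
        assert fitness(1.0, n, k) == 2 * (n - k) ** 2
        assert fitness(just_below, n, k) < (n - k) ** 2
        assert fitness(1.0, n, k) == pytest.approx(
            2 * fitness(1.0 - 1e-12, n, k), rel=1e-9)

    @pytest.mark.parametrize("B,n,k", [(-0.1, 10, 0), (1.1, 10, 0),
                                       (0.5, 10, 11), (0.5, 10, -1)])
    def test_out_of_range_rejected(self, B, n, k):
        with pytest.raises(ValueError):
            fitness(B, n, k)


class TestEstimateB:
    def test_empty_control_matches_enumerated_fraction(self, toy, toy_landscapes):
        net, markers, _ = toy
        exact = basin_fraction(toy_landscapes[0], "normal_proliferation")
        est = estimate_B(net, {}, markers, "normal_proliferation",
                         basin_samples=2000, rng=np.random.default_rng(5))
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(est - exact) <= 4 * se

    def test_pinning_markers_to_quiescent_pattern_gives_full_basin(self, toy):
        """Forcing every marker into the quiescent pattern leaves no other
        attractor phenotype."""
        net, markers, _ = toy
        pins = {markers.cyclinD: 0, markers.cyclinE: 0, markers.cyclinA: 0,
                markers.cyclinB: 0, markers.caspase: 0, markers.ecadherin: 1,
                markers.mmp: 0, markers.rho: 0}
        assert estimate_B(net, pins, markers, "quiescent",
                          basin_samples=500,
                          rng=np.random.default_rng(0)) == 1.0

    def test_bounded(self, toy):
        net, markers, _ = toy
        B = estimate_B(net, TOY_CONTROL, markers, "quiescent",
                       basin_samples=200, rng=np.random.default_rng(1))
        assert 0.0 <= B <= 1.0


class TestGASearch:
    def test_recovers_planted_control_at_carcinoma_stage(self, toy):
        """The GA finds the planted single-node reversion (beta-catenin OFF),
        the optimum over all pin-sets of size <= 2 by exhaustive search."""
        net, markers, profile = toy
        staged = apply_mutations(net, profile, 4)
        result = ga_search(staged, markers, "quiescent", GA_FAST)
        assert dict(result.controls) == TOY_CONTROL
        assert result.achieved_B == 1.0
        # exhaustive oracle: no other set of size <= 2 has higher fitness
        table = exhaustive_control_search(staged, markers, "quiescent",
                                          max_size=2)
        best_controls, best_B = table[0]
        n = staged.n_nodes
        assert best_controls == TOY_CONTROL and best_B == 1.0
        assert result.fitness == fitness(best_B, n, len(best_controls))

    def test_unique_single_node_control_at_every_stage(self, toy):
        """beta-catenin:0 is the only single-node pin with full quiescent
        coverage, at every tumorigenesis stage."""
        net, markers, profile = toy
        for stage in range(len(profile) + 1):
            staged = apply_mutations(net, profile, stage)
            singles = [c for c, B in
                       exhaustive_control_search(staged, markers, "quiescent",
                                                 max_size=1)
                       if len(c) == 1 and B == 1.0]
            assert singles == [TOY_CONTROL]

    def test_already_satisfied_landscape_yields_empty_set(self, toy):
        """If every initial state already reaches the desired phenotype the
        optimal chromosome selects nothing."""
        net, markers, _ = toy
        quiet = net.with_pins(TOY_CONTROL)  # all-quiescent by construction
        cfg = GAConfig(population_size=20, generations=10, basin_samples=200,
                       rng_seed=3)
        result = ga_search(quiet, markers, "quiescent", cfg)
        assert result.controls == []
        assert result.achieved_B == 1.0

    def test_fitness_history_non_decreasing_with_elitism(self, toy):
        net, markers, profile = toy
        staged = apply_mutations(net, profile, 4)
        result = ga_search(staged, markers, "quiescent",
                           GAConfig(population_size=20, generations=15,
                                    basin_samples=200, rng_seed=11))
        hist = result.best_fitness_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_deterministic_given_seed(self, toy):
        net, markers, profile = toy
        staged = apply_mutations(net, profile, 4)
        cfg = GAConfig(population_size=16, generations=8, basin_samples=200,
                       rng_seed=21)
        r1 = ga_search(staged, markers, "quiescent", cfg)
        r2 = ga_search(staged, markers, "quiescent", cfg)
        assert r1.controls == r2.controls
        assert r1.best_fitness_history == r2.best_fitness_history

    def test_mutated_nodes_excluded_from_search(self, toy):
        net, markers, profile = toy
        staged = apply_mutations(net, profile, 4)
        result = ga_search(staged, markers, "quiescent", GA_FAST)
        assert not set(result.nodes) & {"APC", "KRAS", "PTEN", "TP53"}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(crossover_rate=1.5)


class TestEssentiality:
    def test_member_of_full_set_is_the_full_set_here(self, toy):
        """The planted control set has one member, so its essentiality
        equals the full set's coverage."""
        net, markers, profile = toy
        staged = apply_mutations(net, profile, 4)
        res = essentiality(staged, ("bcatenin", 0), markers, "quiescent",
                           n_samples=1000, seed=5)
        assert res.value == 1.0

    def test_singles_never_beat_full_set(self, toy):
        """Essentiality of any single node is bounded by the full control
        set's achieved coverage (which is 1 here)."""
        net, markers, profile = toy
        staged = apply_mutations(net, profile, 2)
        for node, direction in [("Snail", 0), ("MMP", 0), ("P115RhoGEF", 0)]:
            res = essentiality(staged, (node, direction), markers,
                               "quiescent", n_samples=500, seed=8)
            assert 0.0 <= res.value <= 1.0

    def test_node_without_path_to_markers_leaves_baseline(self):
        """Pinning a node with no directed path to any marker cannot move
        the desired basin (exhaustive before/after)."""
        rules = "\n".join([
            "Dangler, Src",          # reads the network, influences nothing
            "Src, Src",
            "CyclinD, Src & !CyclinB", "CyclinE, CyclinD & !CyclinB",
            "CyclinA, CyclinE", "CyclinB, CyclinA",
            "Casp, 0", "Ecad, 1", "MMP, 0", "Rho, 0",
        ])
        net = parse_bnet(rules)
        markers = MarkerConfig("CyclinD", "CyclinE", "CyclinA", "CyclinB",
                               "Casp", "Ecad", "MMP", "Rho")
        base = basin_fraction(enumerate_landscape(net, markers), "quiescent")
        for v in (0, 1):
            pinned = basin_fraction(
                enumerate_landscape(net.with_pins({"Dangler": v}), markers),
                "quiescent")
            assert pinned == pytest.approx(base)

    def test_unknown_node_rejected(self, toy):
        net, markers, _ = toy
        with pytest.raises(ValueError, match="unknown control node"):
            essentiality(net, ("Missing", 0), markers, "quiescent")
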