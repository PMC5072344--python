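"""Landscape estimation, exact enumeration, and phenotype classification."""

import numpy as np
import pytest

from boolscape.landscape import (CLASS_NAMES, MarkerConfig, basin_fraction,
                                 classify_attractor, enumerate_landscape,
                                 mutation_sweep, sample_landscape)
from boolscape.network import Mutation, MutationProfile, parse_bnet
from boolscape.simulate import Attractor
from boolscape.synth import SyntheticSpec, random_network

from conftest import generic_markers

ROLES = ("CyclinD", "CyclinE", "CyclinA", "CyclinB",
         "Casp", "Ecad", "MMP", "Rho")
MARKER_NET = parse_bnet("\n".join(f"{n}, {n}" for n in ROLES))
MARKERS = MarkerConfig(*ROLES)


def attractor_from(columns: dict[str, list[int]], length: int) -> Attractor:
    """Build an attractor cycle from per-marker columns (others zero)."""
    mat = np.zeros((length, len(ROLES)), dtype=np.uint8)
    for name, col in columns.items():
        mat[:, MARKER_NET.index[name]] = col
    return Attractor.from_cycle([mat[i] for i in range(length)])


def shifted(col, k):
    return col[k:] + col[:k]


class TestClassification:
    def test_all_zero_point_attractor_is_quiescent(self):
        att = attractor_from({}, 1)
        label = classify_attractor(att, MARKERS, MARKER_NET)
        assert label.class_name == "quiescent"
        assert not label.proliferative and not label.metastatic

    def test_ordered_cascade_with_cyclin_d_dropping_is_normal_proliferation(self):
        att = attractor_from({
            "CyclinD": [1, 1, 1, 0, 0, 0],
            "CyclinE": [0, 1, 1, 1, 0, 0],
            "CyclinA": [0, 0, 1, 1, 1, 0],
            "CyclinB": [0, 0, 0, 1, 1, 1],
            "Ecad":    [1, 1, 1, 1, 1, 1],
        }, 6)
        label = classify_attractor(att, MARKERS, MARKER_NET)
        assert label.class_name == "normal_proliferation"
        assert label.normal_regulation and not label.metastatic

    def test_constitutive_cyclin_d_with_metastasis_is_cancer_progression(self):
        att = attractor_from({
            "CyclinD": [1, 1, 1, 1, 1, 1],
            "CyclinE": [0, 1, 1, 1, 0, 0],
            "CyclinA": [0, 0, 1, 1, 1, 0],
            "CyclinB": [0, 0, 0, 1, 1, 1],
            "Ecad":    [0, 0, 0, 0, 0, 0],
            "MMP":     [1, 1, 1, 1, 1, 1],
            "Rho":     [0, 1, 0, 1, 0, 1],
        }, 6)
        label = classify_attractor(att, MARKERS, MARKER_NET)
        assert label.class_name == "cancer_progression"
        assert not label.normal_regulation and label.metastatic

    def test_wrong_cyclin_order_is_not_proliferative(self):
        # cascade runs D, E, B, A — B fires before A
        att = attractor_from({
            "CyclinD": [1, 1, 1, 0, 0, 0],
            "CyclinE": [0, 1, 1, 1, 0, 0],
            "CyclinB": [0, 0, 1, 1, 1, 0],
            "CyclinA": [0, 0, 0, 1, 1, 1],
        }, 6)
        assert not classify_attractor(att, MARKERS, MARKER_NET).proliferative

    def test_point_attractor_never_proliferative_or_metastatic(self):
        att = attractor_from({"CyclinD": [1], "MMP": [1]}, 1)
        label = classify_attractor(att, MARKERS, MARKER_NET)
        assert not label.proliferative and not label.metastatic

    def test_constant_rho_blocks_metastasis(self):
        att = attractor_from({
            "Ecad": [0, 0], "MMP": [1, 1], "Rho": [1, 1],
        }, 2)
        assert not classify_attractor(att, MARKERS, MARKER_NET).metastatic

    def test_caspase_on_throughout_sets_apoptotic_flag(self):
        att = attractor_from({"Casp": [1, 1]}, 2)
        assert classify_attractor(att, MARKERS, MARKER_NET).apoptotic

    @pytest.mark.parametrize("rotation", range(6))
    def test_classification_rotation_invariant(self, rotation):
        cols = {
            "CyclinD": [1, 1, 1, 1, 1, 1],
            "CyclinE": [0, 1, 1, 1, 0, 0],
            "CyclinA": [0, 0, 1, 1, 1, 0],
            "CyclinB": [0, 0, 0, 1, 1, 1],
            "Ecad":    [0, 0, 0, 0, 0, 0],
            "MMP":     [1, 1, 1, 1, 1, 1],
            "Rho":     [0, 1, 0, 1, 0, 1],
        }
        base = classify_attractor(attractor_from(cols, 6), MARKERS, MARKER_NET)
        rot = {k: shifted(v, rotation) for k, v in cols.items()}
        label = classify_attractor(attractor_from(rot, 6), MARKERS, MARKER_NET)
        assert label == base

    def test_missing_marker_raises(self):
        bad = MarkerConfig(*(["Nope"] + list(ROLES[1:])))
        with pytest.raises(ValueError, match="unknown node"):
            bad.validate(MARKER_NET)


class TestEnumerate:
    def test_oscillator_pair_single_basin(self):
        # A,!B / B,A is a pure 4-cycle; padding nodes collapse to 0
        net = parse_bnet("A, !B\nB, A\n" +
                         "\n".join(f"P{i}, 0" for i in range(6)))
        ls = enumerate_landscape(net, generic_markers(net))
        assert len(ls.entries) == 1
        assert ls.entries[0].attractor.period == 4
        assert ls.entries[0].basin_count == ls.sample_size == 256

    def test_constant_network_single_point(self):
        net = parse_bnet("\n".join(f"N{i}, 1" for i in range(8)))
        ls = enumerate_landscape(net, generic_markers(net))
        assert len(ls.entries) == 1
        assert ls.entries[0].attractor.states == ((1,) * 8,)

    def test_identity_network_every_state_its_own_basin(self):
        net = parse_bnet("\n".join(f"N{i}, N{i}" for i in range(8)))
        ls = enumerate_landscape(net, generic_markers(net))
        assert len(ls.entries) == 256
        assert all(e.basin_count == 1 for e in ls.entries)

    def test_too_many_free_nodes_rejected(self):
        net = parse_bnet("\n".join(f"N{i}, N{i}" for i in range(9)))
        with pytest.raises(ValueError, match="free nodes"):
            enumerate_landscape(net, generic_markers(net), max_free_nodes=8)


class TestSampleVsEnumerate:
    N_SAMPLES = 4000

    @pytest.mark.parametrize("seed", range(12))
    def test_sampled_fractions_track_exact_basins(self, seed):
        """Sampled basin fractions are binomially consistent with the
        exhaustive landscape, and every sampled attractor is exact."""
        spec = SyntheticSpec(n_nodes=8 + seed % 5, max_in_degree=3,
                             n_inputs=1, rng_seed=seed)
        net = random_network(spec)
        markers = generic_markers(net)
        exact = enumerate_landscape(net, markers)
        samp = sample_landscape(net, markers, self.N_SAMPLES,
                                rng=np.random.default_rng(9000 + seed))
        ex, sa = exact.basin_fractions(), samp.basin_fractions()
        assert set(sa) <= set(ex)
        for key, p in ex.items():
            se = max(np.sqrt(p * (1 - p) / self.N_SAMPLES), 1e-9)
            assert abs(sa.get(key, 0.0) - p) <= 6 * se

    def test_sampling_deterministic_given_seed(self, toy):
        net, markers, _ = toy
        a = sample_landscape(net, markers, 500, rng=np.random.default_rng(3))
        b = sample_landscape(net, markers, 500, rng=np.random.default_rng(3))
        assert a.basin_fractions() == b.basin_fractions()

    def test_sample_size_validation(self, toy):
        net, markers, _ = toy
        with pytest.raises(ValueError):
            sample_landscape(net, markers, 0)


class TestBasinFraction:
    def test_class_fractions_partition_unity(self, toy_landscapes):
        for ls in toy_landscapes:
            total = sum(basin_fraction(ls, c) for c in CLASS_NAMES.values())
            assert total == pytest.approx(1.0)

    def test_metastatic_flag_superset_of_cancer_progression(self, toy_landscapes):
        for ls in toy_landscapes:
            assert (basin_fraction(ls, "metastatic")
                    >= basin_fraction(ls, "cancer_progression"))

    def test_unknown_selector_raises(self, toy_landscapes):
        with pytest.raises(KeyError):
            basin_fraction(toy_landscapes[0], "definitely_not_a_class")


class TestMutationSweep:
    def test_fractions_sum_to_one_at_every_stage(self, toy):
        net, markers, profile = toy
        table = mutation_sweep(net, markers, profile, method="enumerate")
        class_cols = list(CLASS_NAMES.values())
        assert np.allclose(table[class_cols].sum(axis=1), 1.0)

    def test_planted_mutation_silences_apoptosis(self, toy):
        """With DNA damage ON, caspase is active until TP53 is deleted."""
        net, markers, _ = toy
        damage_on = MarkerConfig(**markers.marker_nodes(),
                                 inputs_on=("EGF", "ECM", "Wnt", "DNAdam"))
        profile = MutationProfile([Mutation("TP53", 0, "TP53")])
        table = mutation_sweep(net, damage_on, profile, method="enumerate")
        assert table["flag_apoptotic"].iloc[0] == 1.0
        assert table["flag_apoptotic"].iloc[1] == 0.0

    def test_sampling_size_robustness(self, toy):
        """Class fractions at n=2,000 vs n=10,000 agree within 3 pooled SE."""
        net, markers, profile = toy
        small = mutation_sweep(net, markers, profile, n_samples=2000, seed=11)
        large = mutation_sweep(net, markers, profile, n_samples=10000, seed=12)
        for cls in CLASS_NAMES.values():
            for p1, p2 in zip(small[cls], large[cls]):
                pooled = (2000 * p1 + 10000 * p2) / 12000
                se = np.sqrt(max(pooled * (1 - pooled), 1e-12)
                             * (1 / 2000 + 1 / 10000))
                assert abs(p1 - p2) <= max(3 * se, 1e-9)
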