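"""Reverse control: GA search for minimal control-node sets.

A *control set* is a minimal set of nodes pinned to fixed values (on top of
any driver-mutation pins) such that every initial state of the network
converges to an attractor of a desired phenotype group — quiescent or
normal-proliferative.  Because exhaustive state-space coverage is
infeasible on large networks, the desired-group basin fraction B is
estimated from randomly sampled trajectories (1,000 by default), and
candidate sets are evolved with a genetic algorithm whose fitness

    fitness = B^3 * (n - sum_i X_i)^2 * 2   if B == 1
            = B^3 * (n - sum_i X_i)^2       otherwise

rewards full coverage (the doubling applies only at exactly B = 1, decided
on counted samples) and parsimony (X_i = 1 iff node i is selected; n =
network node count).

Chromosomes carry one ternary gene per node — unselected, pin-0 or pin-1 —
so the search learns pin directions as well as membership.  Nodes already
pinned (driver mutations, input condition) are excluded from the search
space.

*Essentiality* of a single control node is the desired-group basin fraction
achieved by pinning that node alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .landscape import MarkerConfig, basin_fraction, sample_landscape
from .network import BooleanNetwork
from .simulate import SimulationConfig

UNSELECTED = -1


def fitness(B: float, n: int, num_selected: int) -> float:
    """GA fitness of a chromosome with desired-basin fraction ``B`` and
    ``num_selected`` selected nodes out of ``n``.

    The factor 2 applies only when B equals 1 exactly — full coverage is a
    categorical event decided on counted samples, not a tolerance.
    """
    if not 0.0 <= B <= 1.0:
        raise ValueError(f"B must be in [0, 1], got {B}")
    if not 0 <= num_selected <= n:
        raise ValueError(f"num_selected must be in [0, {n}], got {num_selected}")
    base = (B ** 3) * (n - num_selected) ** 2
    return base * 2.0 if B == 1.0 else base


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; everything that shapes the search, logged with
    results for reproducibility."""

    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float | None = None   # per-gene; default 1/n
    elitism: int = 1
    tournament_size: int = 3
    basin_samples: int = 1000
    stagnation_limit: int = 30
    confirm_factor: int = 10
    rng_seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if r is not None and not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class ControlSet:
    """A candidate reverse-control intervention and its achieved coverage."""

    controls: list[tuple[str, int]]      # (node, pin direction)
    achieved_B: float                    # confirmation estimate
    sampled_B: float                     # estimate used during the search
    desired_group: str
    stage_label: str = ""
    fitness: float = 0.0
    best_fitness_history: list[float] = field(default_factory=list)
    ga_config: GAConfig | None = None

    @property
    def nodes(self) -> list[str]:
        return [n for n, _ in self.controls]

    def as_pins(self) -> dict[str, int]:
        return dict(self.controls)


@dataclass(frozen=True)
class EssentialityResult:
    node: str
    direction: int
    value: float                 # desired-group basin fraction in [0, 1]
    desired_group: str
    stage_label: str = ""


def estimate_B(network: BooleanNetwork, controls: dict[str, int],
               markers: MarkerConfig, desired_group: str,
               basin_samples: int = 1000,
               rng: np.random.Generator | int | None = None,
               config: SimulationConfig | None = None) -> float:
    """Desired-group basin fraction under ``controls`` pinned on top of the
    network's existing (mutation) pins."""
    net = network.with_pins(controls) if controls else network
    ls = sample_landscape(net, markers, n_samples=basin_samples,
                          config=config, rng=rng)
    return basin_fraction(ls, desired_group)


def _chromosome_rng(base_seed: int | None, genes: np.ndarray) -> np.random.Generator:
    """Deterministic per-chromosome generator: same genes -> same basin
    sample, so fitness is a pure function of the chromosome."""
    crc = zlib.crc32(genes.tobytes())
    return np.random.default_rng(np.random.SeedSequence((base_seed or 0, crc)))


def _genes_to_controls(genes: np.ndarray, eligible: np.ndarray,
                       node_names: list[str]) -> dict[str, int]:
    return {node_names[i]: int(genes[i])
            for i in np.flatnonzero(eligible) if genes[i] != UNSELECTED}


def ga_search(network: BooleanNetwork, markers: MarkerConfig,
              desired_group: str, ga_config: GAConfig | None = None,
              sim_config: SimulationConfig | None = None,
              stage_label: str = "") -> ControlSet:
    """Evolve a minimal control set driving the landscape into
    ``desired_group``.

    The stage network must already carry its mutation pins; pinned nodes and
    the input-condition nodes are ineligible as controls.  Deterministic
    given ``ga_config.rng_seed``.  The returned set's ``achieved_B`` comes
    from a confirmation pass with a fresh seed and ``confirm_factor`` x the
    search-time basin samples.
    """
    cfg = ga_config or GAConfig()
    markers.validate(network)
    n = network.n_nodes
    names = network.node_names
    ineligible = set(network.pins) | set(markers.input_pins())
    eligible = np.array([nm not in ineligible for nm in names])
    if not eligible.any():
        raise ValueError("no eligible control nodes")
    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n

    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed or 0, 0xC0DE)))

    def evaluate(genes: np.ndarray) -> tuple[float, float]:
        controls = _genes_to_controls(genes, eligible, names)
        B = estimate_B(network, controls, markers, desired_group,
                       basin_samples=cfg.basin_samples,
                       rng=_chromosome_rng(cfg.rng_seed, genes),
                       config=sim_config)
        return fitness(B, n, len(controls)), B

    cache: dict[bytes, tuple[float, float]] = {}

    def eval_cached(genes: np.ndarray) -> tuple[float, float]:
        key = genes.tobytes()
        if key not in cache:
            cache[key] = evaluate(genes)
        return cache[key]

    def random_chromosome() -> np.ndarray:
        genes = np.full(n, UNSELECTED, dtype=np.int8)
        k = int(rng.integers(1, 4))  # start sparse: 1-3 selected nodes
        pool = np.flatnonzero(eligible)
        pick = rng.choice(pool, size=min(k, len(pool)), replace=False)
        genes[pick] = rng.integers(0, 2, size=len(pick), dtype=np.int8)
        return genes

    population = [np.full(n, UNSELECTED, dtype=np.int8)]  # empty set is a candidate
    while len(population) < cfg.population_size:
        population.append(random_chromosome())

    scored = [(eval_cached(g), g) for g in population]
    history: list[float] = []
    stagnant = 0

    def tie_rank(item):
        (fit, _B), genes = item
        n_sel = int(np.sum(genes[eligible] != UNSELECTED))
        sel_names = tuple(sorted(names[i] for i in np.flatnonzero(eligible)
                                 if genes[i] != UNSELECTED))
        # maximize fitness; break ties toward fewer nodes, then lexicographic
        return (fit, -n_sel, tuple(-ord(c) for s in sel_names for c in s))

    best = max(scored, key=tie_rank)

    for _gen in range(cfg.generations):
        history.append(best[0][0])
        # selection: tournaments
        def select() -> np.ndarray:
            idx = rng.integers(0, len(scored), size=cfg.tournament_size)
            return max((scored[i] for i in idx), key=lambda t: t[0][0])[1]

        elite = sorted(scored, key=tie_rank, reverse=True)[:cfg.elitism]
        next_pop: list[np.ndarray] = [g.copy() for _, g in elite]
        while len(next_pop) < cfg.population_size:
            p1, p2 = select(), select()
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(n) < 0.5
                child = np.where(mask, p1, p2).astype(np.int8)
            else:
                child = p1.copy()
            mut_mask = (rng.random(n) < mut_rate) & eligible
            if mut_mask.any():
                child[mut_mask] = rng.integers(-1, 2, size=int(mut_mask.sum()),
                                               dtype=np.int8)
            child[~eligible] = UNSELECTED
            next_pop.append(child)
        scored = [(eval_cached(g), g) for g in next_pop]
        gen_best = max(scored, key=tie_rank)
        if gen_best[0][0] > best[0][0]:
            best = gen_best
            stagnant = 0
        else:
            stagnant += 1
            if tie_rank(gen_best) > tie_rank(best):
                best = gen_best
        if stagnant >= cfg.stagnation_limit:
            break
    history.append(best[0][0])

    (best_fit, best_B), best_genes = best
    controls = _genes_to_controls(best_genes, eligible, names)
    confirm_rng = np.random.default_rng(
        np.random.SeedSequence(((cfg.rng_seed or 0) + 1, 0xF17A)))
    achieved = estimate_B(network, controls, markers, desired_group,
                          basin_samples=cfg.basin_samples * cfg.confirm_factor,
                          rng=confirm_rng, config=sim_config)
    return ControlSet(controls=sorted(controls.items()),
                      achieved_B=achieved, sampled_B=best_B,
                      desired_group=desired_group, stage_label=stage_label,
                      fitness=best_fit, best_fitness_history=history,
                      ga_config=cfg)


def essentiality(network: BooleanNetwork, control: tuple[str, int],
                 markers: MarkerConfig, desired_group: str,
                 n_samples: int = 1000, seed: int | None = None,
                 config: SimulationConfig | None = None,
                 stage_label: str = "") -> EssentialityResult:
    """Desired-group basin fraction when a single control node is pinned on
    top of the stage's mutation pins."""
    node, direction = control
    if node not in network.index:
        raise ValueError(f"unknown control node {node!r}")
    value = estimate_B(network, {node: direction}, markers, desired_group,
                       basin_samples=n_samples,
                       rng=np.random.default_rng(seed), config=config)
    return EssentialityResult(node=node, direction=direction, value=value,
                              desired_group=desired_group,
                              stage_label=stage_label)


def exhaustive_control_search(network: BooleanNetwork, markers: MarkerConfig,
                              desired_group: str, max_size: int = 2,
                              enumerate_basins: bool = True,
                              basin_samples: int = 1000,
                              seed: int | None = None) -> list[tuple[dict[str, int], float]]:
    """Brute-force oracle: evaluate every pin-set of size <= max_size over
    eligible nodes, returning (controls, B) sorted by fitness (descending,
    fewer nodes first).  With ``enumerate_basins`` the basin fraction is
    exact (small networks only)."""
    from itertools import combinations, product

    from .landscape import enumerate_landscape

    markers.validate(network)
    ineligible = set(network.pins) | set(markers.input_pins())
    nodes = [nm for nm in network.node_names if nm not in ineligible]
    n = network.n_nodes

    def B_of(controls: dict[str, int]) -> float:
        net = network.with_pins(controls) if controls else network
        if enumerate_basins:
            ls = enumerate_landscape(net, markers)
            return basin_fraction(ls, desired_group)
        return estimate_B(network, controls, markers, desired_group,
                          basin_samples, rng=np.random.default_rng(seed))

    results = []
    for size in range(0, max_size + 1):
        for combo in combinations(nodes, size):
            for vals in product((0, 1), repeat=size):
                controls = dict(zip(combo, vals))
                B = B_of(controls)
                results.append((controls, B))
    results.sort(key=lambda cb: (fitness(cb[1], n, len(cb[0])),
                                 -len(cb[0]),
                                 tuple(sorted(cb[0]))),
                 reverse=True)
    return results
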