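"""Attractor-landscape estimation and phenotype classification.

The attractor landscape of a Boolean signaling network is the set of its
attractors together with their basins of attraction.  On large networks the
landscape is estimated by following randomly sampled initial states to
their attractors (the basin count of an attractor = number of samples that
converged to it); on small networks (<= 20 free nodes) it is computed
exactly by enumerating every state.

Attractors are mapped to cell phenotypes through marker nodes:

* **proliferative** — the attractor is cyclic and the cyclins switch on in
  the cell-cycle order CyclinD -> CyclinE -> CyclinA -> CyclinB (a CyclinD
  held constitutively ON still counts as leading the cascade);
* **normal regulation** — proliferative, with CyclinD *not* ON in every
  cycle state (constitutive CyclinD marks abnormal, oncogene-like drive);
* **metastatic** — E-cadherin OFF and MMP ON throughout, with Rho
  oscillating over the cycle (migratory push-pull);
* **apoptotic** — caspase ON in every state (reported as an orthogonal
  flag, outside the 8-class taxonomy).

The three criteria (normal regulation, proliferative, metastatic) define
eight attractor classes; the two headline classes are *normal
proliferation* (regulated cycling, no metastasis) and *cancer progression*
(abnormal cycling plus metastasis).  *Quiescent* = neither proliferative
nor metastatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .network import BooleanNetwork
from .simulate import (Attractor, SimulationConfig, find_attractor,
                       step_batch)

MARKER_ROLES = ("cyclinD", "cyclinE", "cyclinA", "cyclinB",
                "caspase", "ecadherin", "mmp", "rho")

#: class names indexed by (normal_regulation, proliferative, metastatic)
CLASS_NAMES: dict[tuple[int, int, int], str] = {
    (1, 1, 0): "normal_proliferation",
    (0, 1, 1): "cancer_progression",
    (0, 0, 0): "quiescent",
    (0, 1, 0): "abnormal_proliferation",
    (0, 0, 1): "metastatic_non_proliferative",
    (1, 1, 1): "normal_proliferation_metastatic",
    # unreachable under the flag definitions (normal regulation implies
    # proliferative) but kept so the taxonomy is a total map of 3 bits
    (1, 0, 0): "regulated_non_proliferative",
    (1, 0, 1): "regulated_metastatic",
}
FLAG_NAMES = ("proliferative", "normal_regulation", "metastatic", "apoptotic")


@dataclass(frozen=True)
class MarkerConfig:
    """Maps phenotype marker roles to node names, plus the input condition.

    ``inputs_on`` / ``inputs_off`` are external-input nodes pinned to 1 / 0
    before any landscape analysis (the growth condition: EGF, ECM and Wnt ON
    in the source system).
    """

    cyclinD: str
    cyclinE: str
    cyclinA: str
    cyclinB: str
    caspase: str
    ecadherin: str
    mmp: str
    rho: str
    inputs_on: tuple[str, ...] = ()
    inputs_off: tuple[str, ...] = ()

    def marker_nodes(self) -> dict[str, str]:
        return {role: getattr(self, role) for role in MARKER_ROLES}

    def validate(self, network: BooleanNetwork) -> None:
        for role, node in self.marker_nodes().items():
            if node not in network.index:
                raise ValueError(f"marker {role!r} -> unknown node {node!r}")
        names = list(self.marker_nodes().values())
        if len(set(names)) != len(names):
            raise ValueError("marker roles must map to distinct nodes")
        for node in (*self.inputs_on, *self.inputs_off):
            if node not in network.index:
                raise ValueError(f"input-condition node {node!r} not in network")

    def input_pins(self) -> dict[str, int]:
        pins = {n: 1 for n in self.inputs_on}
        pins.update({n: 0 for n in self.inputs_off})
        return pins


@dataclass(frozen=True)
class PhenotypeLabel:
    """Phenotype flags of one attractor plus its derived 8-way class."""

    proliferative: bool
    normal_regulation: bool
    metastatic: bool
    apoptotic: bool

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[(int(self.normal_regulation),
                            int(self.proliferative),
                            int(self.metastatic))]

    def matches(self, selector: str) -> bool:
        """True if this label matches a class name or a flag name."""
        if selector in CLASS_NAMES.values():
            return self.class_name == selector
        if selector in FLAG_NAMES:
            return bool(getattr(self, selector))
        raise KeyError(f"unknown phenotype class or flag {selector!r}")


def _onsets(column: np.ndarray) -> list[int]:
    """Indices t where the node switches 0 -> 1 between cycle steps t-1, t
    (circular)."""
    L = len(column)
    return [t for t in range(L) if column[t] == 1 and column[(t - 1) % L] == 0]


def _cascade_ordered(d_opts: list[int | None], e_on: list[int],
                     a_on: list[int], b_on: list[int], L: int) -> bool:
    """Is there a rotation in which chosen onsets follow D, E, A, B?

    A ``None`` in ``d_opts`` is the constitutively-ON CyclinD wildcard: the
    cascade is then anchored at CyclinE.
    """
    for d, e, a, b in product(d_opts, e_on, a_on, b_on):
        anchor = e if d is None else d
        offs = [(e - anchor) % L, (a - anchor) % L, (b - anchor) % L]
        if offs[0] <= offs[1] <= offs[2]:
            return True
    return False


def classify_attractor(attractor: Attractor, markers: MarkerConfig,
                       network: BooleanNetwork) -> PhenotypeLabel:
    """Assign phenotype flags to an attractor from its marker-node dynamics."""
    mat = attractor.state_matrix()
    idx = {role: network.index[node]
           for role, node in markers.marker_nodes().items()}
    L = mat.shape[0]

    apoptotic = bool(np.all(mat[:, idx["caspase"]] == 1))

    proliferative = False
    if L > 1:
        cd = mat[:, idx["cyclinD"]]
        ce = mat[:, idx["cyclinE"]]
        ca = mat[:, idx["cyclinA"]]
        cb = mat[:, idx["cyclinB"]]
        d_on: list[int | None] = list(_onsets(cd))
        if not d_on and np.all(cd == 1):
            d_on = [None]  # constitutively active CyclinD leads by default
        e_on, a_on, b_on = _onsets(ce), _onsets(ca), _onsets(cb)
        if d_on and e_on and a_on and b_on:
            proliferative = _cascade_ordered(d_on, e_on, a_on, b_on, L)

    normal_regulation = proliferative and not bool(np.all(mat[:, idx["cyclinD"]] == 1))

    metastatic = False
    if L > 1:
        rho = mat[:, idx["rho"]]
        metastatic = (bool(np.all(mat[:, idx["ecadherin"]] == 0))
                      and bool(np.all(mat[:, idx["mmp"]] == 1))
                      and bool(rho.min() != rho.max()))

    return PhenotypeLabel(proliferative=proliferative,
                          normal_regulation=normal_regulation,
                          metastatic=metastatic,
                          apoptotic=apoptotic)


@dataclass
class LandscapeEntry:
    attractor: Attractor
    basin_count: int
    label: PhenotypeLabel


@dataclass
class AttractorLandscape:
    """Attractors with (sampled or exact) basin counts and phenotype labels."""

    entries: list[LandscapeEntry]
    sample_size: int
    rng_seed: int | None = None
    input_condition: dict[str, int] = field(default_factory=dict)
    exhaustive: bool = False

    def __post_init__(self):
        total = sum(e.basin_count for e in self.entries)
        if total != self.sample_size:
            raise ValueError(
                f"basin counts sum to {total}, expected sample_size={self.sample_size}")

    def basin_fractions(self) -> dict[tuple[int, ...], float]:
        return {e.attractor.canonical_key: e.basin_count / self.sample_size
                for e in self.entries}

    def class_fractions(self) -> dict[str, float]:
        out = {name: 0.0 for name in CLASS_NAMES.values()}
        for e in self.entries:
            out[e.label.class_name] += e.basin_count / self.sample_size
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append({
                "attractor_key": "|".join(map(str, e.attractor.canonical_key)),
                "period": e.attractor.period,
                "basin_count": e.basin_count,
                "basin_fraction": e.basin_count / self.sample_size,
                "class": e.label.class_name,
                **{f: bool(getattr(e.label, f)) for f in FLAG_NAMES},
            })
        return pd.DataFrame(rows).sort_values(
            "basin_count", ascending=False, ignore_index=True)


def basin_fraction(landscape: AttractorLandscape, selector: str) -> float:
    """Fraction of sampled initial states whose attractor matches a class
    name (e.g. ``"normal_proliferation"``) or a flag (e.g. ``"metastatic"``,
    which may span several classes)."""
    if not landscape.entries:
        raise ValueError("empty landscape")
    return sum(e.basin_count for e in landscape.entries
               if e.label.matches(selector)) / landscape.sample_size


def _condition_network(network: BooleanNetwork,
                       markers: MarkerConfig) -> BooleanNetwork:
    pins = markers.input_pins()
    return network.with_pins(pins) if pins else network


def sample_landscape(network: BooleanNetwork, markers: MarkerConfig,
                     n_samples: int = 10000,
                     config: SimulationConfig | None = None,
                     rng: np.random.Generator | int | None = None
                     ) -> AttractorLandscape:
    """Estimate the landscape from uniformly sampled initial states.

    The input condition of ``markers`` is pinned first; initial states are
    uniform over the remaining free nodes.  Attractors reached by several
    samples are merged by canonical key.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    markers.validate(network)
    net = _condition_network(network, markers)
    config = config or SimulationConfig()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    # Trajectories of a deterministic network merge as soon as they share a
    # state, so successor pointers and attractor assignments are memoized
    # across samples: each distinct state costs one rule evaluation ever.
    from .simulate import pack_state, step, unpack_state

    succ: dict[int, int] = {}
    attr_of: dict[int, int] = {}
    attractors: list[Attractor] = []
    counts: list[int] = []
    free = net.free_idx
    n = net.n_nodes
    pins_packed = 0
    for i, v in zip(net.pin_idx, net.pin_val):
        if v:
            pins_packed |= 1 << int(i)

    for _ in range(n_samples):
        bits = gen.integers(0, 2, size=len(free))
        key = pins_packed
        for j, node_i in enumerate(free):
            if bits[j]:
                key |= 1 << int(node_i)
        path: list[int] = []
        pathpos: dict[int, int] = {}
        while key not in attr_of and key not in pathpos:
            if len(path) > config.max_attractor_steps:
                raise RuntimeError(
                    f"no attractor within {config.max_attractor_steps} steps")
            pathpos[key] = len(path)
            path.append(key)
            nxt = succ.get(key)
            if nxt is None:
                nxt = pack_state(step(net, unpack_state(key, n)))
                succ[key] = nxt
            key = nxt
        if key in attr_of:
            aid = attr_of[key]
        else:
            cycle = [unpack_state(k, n) for k in path[pathpos[key]:]]
            aid = len(attractors)
            attractors.append(Attractor.from_cycle(cycle))
            counts.append(0)
        for k in path:
            attr_of[k] = aid
        counts[aid] += 1

    entries = [LandscapeEntry(att, c, classify_attractor(att, markers, net))
               for att, c in zip(attractors, counts) if c > 0]
    return AttractorLandscape(entries=entries, sample_size=n_samples,
                              rng_seed=seed,
                              input_condition=markers.input_pins())


def enumerate_landscape(network: BooleanNetwork, markers: MarkerConfig,
                        max_free_nodes: int = 20) -> AttractorLandscape:
    """Exact landscape by visiting all 2^f states over the f free nodes.

    Successors are computed in one vectorized sweep; attractors are found by
    pointer-chasing in the functional graph.  Usable as a brute-force oracle
    for :func:`sample_landscape` on networks with <= ``max_free_nodes`` free
    nodes.
    """
    markers.validate(network)
    net = _condition_network(network, markers)
    free = net.free_idx
    f = len(free)
    if f > max_free_nodes:
        raise ValueError(f"{f} free nodes exceeds max_free_nodes={max_free_nodes}")

    m = 1 << f
    # all states: row s has free bits of s, pinned bits at their pins
    states = np.zeros((m, net.n_nodes), dtype=np.uint8)
    for j, node_i in enumerate(free):
        states[:, node_i] = (np.arange(m) >> j) & 1
    if len(net.pin_idx):
        states[:, net.pin_idx] = net.pin_val

    succ_states = step_batch(net, states)
    weights = (1 << np.arange(f)).astype(np.int64)
    succ = succ_states[:, free].astype(np.int64) @ weights  # free-bit index

    attr_id = np.full(m, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for s0 in range(m):
        if attr_id[s0] >= 0:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        s = s0
        while attr_id[s] < 0 and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if attr_id[s] >= 0:
            aid = attr_id[s]
        else:  # new cycle discovered within this path
            aid = len(cycles)
            cycles.append(path[pos[s]:])
        for p in path:
            attr_id[p] = aid

    entries: list[LandscapeEntry] = []
    basin_counts = np.bincount(attr_id, minlength=len(cycles))
    for aid, cycle in enumerate(cycles):
        cyc_states = [states[s].copy() for s in cycle]
        att = Attractor.from_cycle(cyc_states)
        entries.append(LandscapeEntry(att, int(basin_counts[aid]),
                                      classify_attractor(att, markers, net)))
    return AttractorLandscape(entries=entries, sample_size=m,
                              input_condition=markers.input_pins(),
                              exhaustive=True)


def mutation_sweep(network: BooleanNetwork, markers: MarkerConfig,
                   profile, n_samples: int = 10000,
                   config: SimulationConfig | None = None,
                   seed: int | None = None,
                   method: str = "sample") -> pd.DataFrame:
    """Landscape class fractions at every driver-mutation stage.

    Stage 0 is the unmutated network; stage k pins the first k mutations.
    Each stage is sampled with its own generator spawned from ``seed`` so
    stages are independent but the whole sweep is reproducible.  Returns a
    stage x class table (plus flag columns), fractions in [0, 1].
    """
    from .network import apply_mutations  # local import avoids cycle at module load

    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(profile) + 1)
    for stage in range(len(profile) + 1):
        net = apply_mutations(network, profile, stage)
        if method == "enumerate":
            ls = enumerate_landscape(net, markers)
        elif method == "sample":
            ls = sample_landscape(net, markers, n_samples, config,
                                  rng=np.random.default_rng(child_seeds[stage]))
        else:
            raise ValueError(f"unknown method {method!r}")
        row = {"stage": stage,
               "label": profile.stage_labels()[stage],
               "n_attractors": len(ls.entries)}
        row.update(ls.class_fractions())
        for flag in FLAG_NAMES:
            row[f"flag_{flag}"] = basin_fraction(ls, flag)
        rows.append(row)
    return pd.DataFrame(rows)
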