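"""Synthetic networks and the hand-built colorectal-like test fixture.

Two generators live here:

* :func:`random_network` — seeded random Boolean networks of configurable
  size and in-degree, used for property tests (parser round-trips,
  sampled-vs-exact basin agreement);

* :func:`toy_colorectal_fixture` — a 20-node, exhaustively enumerable
  miniature of a colorectal signaling system: growth inputs (EGF, ECM,
  Wnt), a Wnt/beta-catenin axis, a cyclin cascade, an E-cadherin/MMP/Rho
  metastasis branch, a caspase branch, and analogs of the four driver
  genes (APC, KRAS, PTEN, TP53) whose sequential pinning deforms the
  attractor landscape.

The fixture is authored by hand, not sampled, so its landscape is stable
and interpretable.  Its load-bearing facts — a normal-proliferation cyclic
attractor under growth inputs, a metastatic basin that grows strictly with
each driver mutation, and a unique single-node control (beta-catenin OFF)
restoring quiescence with full coverage at every stage — are locked by
exhaustive enumeration in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import MarkerConfig
from .network import BooleanNetwork, MutationProfile, parse_bnet


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random Boolean network draw."""

    n_nodes: int = 12
    max_in_degree: int = 3
    n_inputs: int = 1
    and_bias: float = 0.5       # probability an internal join uses AND (vs OR)
    not_bias: float = 0.3       # probability a literal is negated
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.max_in_degree < 1:
            raise ValueError("max_in_degree must be >= 1")
        if not 0 <= self.n_inputs < self.n_nodes:
            raise ValueError("n_inputs must be in [0, n_nodes)")


def random_network(spec: SyntheticSpec) -> BooleanNetwork:
    """Draw a weakly connected random Boolean network.

    Nodes N000..N{n-1}; the first ``n_inputs`` are external inputs.  Every
    regulated node takes at least one parent from the nodes preceding it,
    which guarantees weak connectivity; rules are random AND/OR/NOT
    compositions of the chosen parents.  Deterministic given
    ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    width = len(str(spec.n_nodes - 1))
    names = [f"N{i:0{width}d}" for i in range(spec.n_nodes)]
    lines = []
    referenced: set[int] = set()
    for i in range(spec.n_inputs, spec.n_nodes):
        k = int(rng.integers(1, spec.max_in_degree + 1))
        anchor_pool = max(i, 1)
        anchor = int(rng.integers(0, anchor_pool))  # parent from the prefix
        others = [j for j in range(spec.n_nodes) if j != anchor]
        extra = list(rng.choice(others, size=min(k - 1, len(others)),
                                replace=False)) if k > 1 else []
        parents = [anchor] + [int(j) for j in extra]
        referenced.update(parents)
        lits = []
        for j in parents:
            neg = "!" if rng.random() < spec.not_bias else ""
            lits.append(f"{neg}{names[j]}")
        expr = lits[0]
        for lit in lits[1:]:
            op = "&" if rng.random() < spec.and_bias else "|"
            expr = f"({expr}) {op} {lit}"
        lines.append(f"{names[i]}, {expr}")
    # make sure every input is referenced so serialization round-trips
    regulated = list(range(spec.n_inputs, spec.n_nodes))
    for i in range(spec.n_inputs):
        if i not in referenced and regulated:
            tgt = int(rng.choice(regulated))
            lines[tgt - spec.n_inputs] = (
                lines[tgt - spec.n_inputs] + f" | ({names[i]} & !{names[i]})")
            referenced.add(i)
    return parse_bnet("\n".join(lines) + "\n")


#: The planted minimal reversion to quiescence: beta-catenin pinned OFF
#: silences both the cyclin cascade and every metastasis latch trigger.
TOY_CONTROL = {"bcatenin": 0}


def toy_colorectal_fixture() -> tuple[BooleanNetwork, MarkerConfig, MutationProfile]:
    """The colorectal-like network with its marker configuration and the
    APC -> KRAS -> PTEN -> TP53 driver-mutation profile.

    Loaded from the packaged ``data/toy_colorectal.bnet`` and
    ``data/toy_colorectal.yaml`` files, which carry the model's commentary.
    """
    from importlib import resources

    from .io import load_analysis_config

    data = resources.files("boolscape") / "data"
    network = parse_bnet((data / "toy_colorectal.bnet").read_text())
    markers, profile = load_analysis_config(data / "toy_colorectal.yaml")
    markers.validate(network)
    return network, markers, profile
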