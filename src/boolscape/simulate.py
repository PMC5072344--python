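"""Synchronous Boolean simulation: state updates, trajectories, attractors.

Update semantics are deterministic and synchronous: every regulated node
evaluates its rule on the *previous* state simultaneously; external inputs
hold their current value; pinned nodes hold their pin.  Under these
semantics every trajectory is eventually periodic, ending in either a fixed
point (point attractor) or a minimal repeating cycle (cyclic attractor).

States are numpy uint8 vectors aligned to the network's node order, packed
to Python ints (bit i = node i) for hashing during cycle detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import BooleanNetwork


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for trajectory simulation.

    total_steps / steady_window drive steady-state activity measurements
    (average over the final window of a fixed-length run); the defaults —
    1000 steps, window 100 — are the protocol used for all input-output
    sweeps.  max_attractor_steps caps cycle detection.
    """

    total_steps: int = 1000
    steady_window: int = 100
    max_attractor_steps: int = 10000
    rng_seed: int | None = None

    def __post_init__(self):
        if self.total_steps <= 0 or self.steady_window <= 0 or self.max_attractor_steps <= 0:
            raise ValueError("all step counts must be positive")
        if self.steady_window > self.total_steps:
            raise ValueError("steady_window must be <= total_steps")


def pack_state(state: np.ndarray) -> int:
    """Pack a 0/1 vector into an int, node i at bit i."""
    key = 0
    for i, b in enumerate(state):
        if b:
            key |= 1 << i
    return key


def unpack_state(key: int, n: int) -> np.ndarray:
    return np.fromiter(((key >> i) & 1 for i in range(n)), dtype=np.uint8, count=n)


def step(network: BooleanNetwork, state: np.ndarray) -> np.ndarray:
    """One synchronous update.  Returns a fresh state array."""
    if len(state) != network.n_nodes:
        raise ValueError("state length does not match network")
    new = state.copy()  # inputs (no rule) carry their value forward
    for i in np.flatnonzero(network.has_rule):
        parents = network.parent_idx[i]
        idx = 0
        for j, p in enumerate(parents):
            if state[p]:
                idx |= 1 << j
        new[i] = network.tables[i][idx]
    if len(network.pin_idx):
        new[network.pin_idx] = network.pin_val
    return new


def apply_pins(network: BooleanNetwork, state: np.ndarray) -> np.ndarray:
    """Force pinned entries of ``state`` to their pin values (copy)."""
    s = np.asarray(state, dtype=np.uint8).copy()
    if len(network.pin_idx):
        s[network.pin_idx] = network.pin_val
    return s


def step_batch(network: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Synchronous update of many states at once; ``states`` is (m, n)."""
    new = states.copy()
    for i in np.flatnonzero(network.has_rule):
        parents = network.parent_idx[i]
        if len(parents):
            weights = (1 << np.arange(len(parents))).astype(np.int64)
            idx = states[:, parents].astype(np.int64) @ weights
        else:
            idx = np.zeros(len(states), dtype=np.int64)
        new[:, i] = network.tables[i][idx]
    if len(network.pin_idx):
        new[:, network.pin_idx] = network.pin_val
    return new


@dataclass(frozen=True)
class Attractor:
    """A point or cyclic attractor, stored in canonical rotation.

    ``states`` is the minimal cycle, rotated so that the packed-int smallest
    state comes first; ``canonical_key`` is the tuple of packed states in
    that rotation, identical for any rotation of the same cycle.
    """

    states: tuple[tuple[int, ...], ...]   # cycle of state bit-tuples
    canonical_key: tuple[int, ...]

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_point(self) -> bool:
        return len(self.states) == 1

    def state_matrix(self) -> np.ndarray:
        return np.array(self.states, dtype=np.uint8)

    @staticmethod
    def from_cycle(states: list[np.ndarray]) -> "Attractor":
        keys = [pack_state(s) for s in states]
        pivot = keys.index(min(keys))
        order = list(range(pivot, len(keys))) + list(range(pivot))
        rot_states = tuple(tuple(int(b) for b in states[i]) for i in order)
        rot_keys = tuple(keys[i] for i in order)
        return Attractor(states=rot_states, canonical_key=rot_keys)


@dataclass
class Trajectory:
    """States visited from an initial condition until the attractor closes."""

    states: list[np.ndarray] = field(default_factory=list)
    transient_length: int = 0
    attractor: Attractor | None = None

    def activity_matrix(self) -> np.ndarray:
        return np.array(self.states, dtype=np.uint8)


class AttractorSearchError(RuntimeError):
    """No repeated state within max_attractor_steps — cap too small."""


def find_attractor(network: BooleanNetwork, initial: np.ndarray,
                   config: SimulationConfig | None = None
                   ) -> tuple[Attractor, int]:
    """Follow a trajectory to its attractor via visited-state hashing.

    Returns the canonicalized attractor and the transient length (number of
    steps before the trajectory first enters the cycle).
    """
    config = config or SimulationConfig()
    state = apply_pins(network, initial)
    seen: dict[int, int] = {}
    states: list[np.ndarray] = []
    for t in range(config.max_attractor_steps + 1):
        key = pack_state(state)
        if key in seen:
            start = seen[key]
            cycle = states[start:]
            return Attractor.from_cycle(cycle), start
        seen[key] = t
        states.append(state)
        state = step(network, state)
    raise AttractorSearchError(
        f"no attractor within {config.max_attractor_steps} steps")


def simulate(network: BooleanNetwork, initial: np.ndarray,
             n_steps: int) -> np.ndarray:
    """Run ``n_steps`` synchronous updates; returns (n_steps+1, n) matrix
    including the initial state."""
    state = apply_pins(network, initial)
    out = np.empty((n_steps + 1, network.n_nodes), dtype=np.uint8)
    out[0] = state
    for t in range(1, n_steps + 1):
        state = step(network, state)
        out[t] = state
    return out


def steady_state_activity(traj: np.ndarray | Trajectory | Attractor,
                          node_index: int,
                          config: SimulationConfig | None = None) -> float:
    """Average activity of one node over the last ``steady_window`` steps.

    For an explicit trajectory matrix the mean is taken over its final
    window rows.  For an :class:`Attractor` the exact cycle average is
    returned (the infinite-horizon limit of the windowed mean).
    """
    config = config or SimulationConfig()
    if isinstance(traj, Attractor):
        return float(traj.state_matrix()[:, node_index].mean())
    if isinstance(traj, Trajectory):
        traj = traj.activity_matrix()
    traj = np.asarray(traj)
    if traj.shape[0] < config.steady_window:
        raise ValueError(
            f"trajectory has {traj.shape[0]} steps, shorter than "
            f"steady_window={config.steady_window}")
    return float(traj[-config.steady_window:, node_index].mean())
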