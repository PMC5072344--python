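"""Input-output (dose-response) sweeps.

An external input's *intensity* is its average ON fraction over the
simulation.  Sweeping intensity from 0 to 100 % in 1 % steps and recording
the steady-state activity of a readout node (mean over the last window of a
fixed-length run, averaged over random initial conditions) gives a
dose-response curve for the Boolean model, analogous to a ligand titration.

Fractional intensity is realized per step either as an independent
Bernoulli(p) draw (default; the input flickers with mean p) or as a
deterministic duty cycle with the same mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import BooleanNetwork
from .simulate import SimulationConfig, step_batch


@dataclass
class DoseResponseCurve:
    input_node: str
    output_node: str
    intensity: np.ndarray          # requested input ON fraction, in [0, 1]
    mean_activity: np.ndarray      # steady-state output activity per point
    sd_activity: np.ndarray
    realized_intensity: np.ndarray  # measured input ON fraction per point
    reps: int
    rng_seed: int | None = None
    mode: str = "bernoulli"
    baseline: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "intensity": self.intensity,
            "mean_activity": self.mean_activity,
            "sd_activity": self.sd_activity,
            "realized_intensity": self.realized_intensity,
        })


def _duty_cycle_schedule(p: float, n_steps: int) -> np.ndarray:
    """Deterministic 0/1 schedule of length n_steps with mean ~= p
    (Bresenham spreading: ON at t iff floor((t+1)p) > floor(tp))."""
    t = np.arange(n_steps, dtype=np.float64)
    return (np.floor((t + 1) * p) - np.floor(t * p) >= 1).astype(np.uint8)


def sweep_input(network: BooleanNetwork, input_node: str, output_node: str,
                reps: int = 5, config: SimulationConfig | None = None,
                grid: np.ndarray | None = None,
                baseline: dict[str, int] | None = None,
                mode: str = "bernoulli",
                seed: int | None = None) -> DoseResponseCurve:
    """Sweep one external input's intensity and read out one node.

    Parameters
    ----------
    input_node:
        Must be an external input (no update rule).  Its state is reassigned
        every step according to the intensity schedule.
    baseline:
        Fixed values for the *other* external inputs during the sweep
        (default: all OFF).
    reps:
        Number of random initial conditions averaged per grid point.
    """
    if output_node not in network.index:
        raise ValueError(f"unknown output node {output_node!r}")
    if input_node not in network.input_nodes:
        raise ValueError(f"{input_node!r} is not an external input")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode not in ("bernoulli", "duty_cycle"):
        raise ValueError(f"unknown mode {mode!r}")

    config = config or SimulationConfig()
    grid = np.round(np.arange(0, 101) / 100.0, 2) if grid is None else np.asarray(grid, float)
    base = {n: 0 for n in network.input_nodes if n != input_node}
    base.update(baseline or {})
    for n in base:
        if n not in network.index:
            raise ValueError(f"baseline node {n!r} not in network")

    rng = np.random.default_rng(seed)
    in_i = network.index[input_node]
    out_i = network.index[output_node]
    base_idx = np.array([network.index[n] for n in base], dtype=np.intp)
    base_val = np.array([base[n] for n in base], dtype=np.uint8)

    means = np.empty(len(grid))
    sds = np.empty(len(grid))
    realized = np.empty(len(grid))
    n_steps = config.total_steps
    window = config.steady_window

    for gi, p in enumerate(grid):
        states = rng.integers(0, 2, size=(reps, network.n_nodes), dtype=np.uint8)
        if len(base_idx):
            states[:, base_idx] = base_val
        if mode == "duty_cycle":
            sched = _duty_cycle_schedule(float(p), n_steps + 1)
        out_trace = np.empty((n_steps + 1, reps), dtype=np.uint8)
        in_trace = np.empty((n_steps + 1, reps), dtype=np.uint8)
        for t in range(n_steps + 1):
            if mode == "bernoulli":
                states[:, in_i] = (rng.random(reps) < p).astype(np.uint8)
            else:
                states[:, in_i] = sched[t]
            in_trace[t] = states[:, in_i]
            out_trace[t] = states[:, out_i]
            if t < n_steps:
                states = step_batch(network, states)
                if len(base_idx):
                    states[:, base_idx] = base_val
        per_rep = out_trace[-window:].mean(axis=0)
        means[gi] = per_rep.mean()
        sds[gi] = per_rep.std(ddof=1) if reps > 1 else 0.0
        realized[gi] = in_trace.mean()

    return DoseResponseCurve(input_node=input_node, output_node=output_node,
                             intensity=grid, mean_activity=means,
                             sd_activity=sds, realized_intensity=realized,
                             reps=reps, rng_seed=seed, mode=mode,
                             baseline=base)
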