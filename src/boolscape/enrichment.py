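"""Drug-target enrichment of control nodes.

Tests whether approved-drug targets are over-represented among identified
control nodes relative to random node sets drawn from the same network: a
one-sided two-sample chi-squared test on the 2x2 table

    rows:    control set  |  pooled random draws
    columns: target       |  non-target

The target list is user-supplied (TSV: node, is_target).  The one-sided
p-value is half the two-sided chi-squared p when the control-set target
frequency exceeds the random frequency, else 1 minus half of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: control, random
    statistic: float
    p_one_sided: float
    p_two_sided: float
    control_target_freq: float
    random_target_freq: float
    n_random_draws: int
    set_size: int
    rng_seed: int | None = None
    monte_carlo_p: float | None = None


def load_target_flags(path) -> dict[str, int]:
    """Read a two-column TSV (node, is_target in {0,1}) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "is_target"],
                     comment="#", dtype={"node": str})
    flags = {}
    for node, val in zip(df["node"], df["is_target"]):
        if int(val) not in (0, 1):
            raise ValueError(f"is_target for {node!r} must be 0 or 1")
        flags[str(node)] = int(val)
    return flags


def drug_target_enrichment(control_nodes: list[str],
                           target_flags: dict[str, int],
                           network_nodes: list[str],
                           n_random: int = 1000,
                           set_size: int | None = None,
                           seed: int | None = None,
                           monte_carlo: bool = False) -> EnrichmentResult:
    """Chi-squared enrichment of targets in ``control_nodes`` vs random sets.

    ``n_random`` uniform draws of ``set_size`` nodes (default: the control
    set's size) are pooled into the comparison row.  With ``monte_carlo``
    an empirical one-sided p (fraction of random sets with target count >=
    the control set's) is reported alongside.
    """
    if not control_nodes:
        raise ValueError("empty control set")
    missing = [n for n in control_nodes if n not in network_nodes]
    if missing:
        raise ValueError(f"control nodes not in network: {missing}")
    uncovered = [n for n in network_nodes if n not in target_flags]
    if uncovered:
        raise ValueError(f"target_flags missing nodes, e.g. {uncovered[:3]}")
    size = len(control_nodes) if set_size is None else set_size
    if size > len(network_nodes):
        raise ValueError("set_size exceeds node count")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")

    rng = np.random.default_rng(seed)
    ctrl_hits = sum(target_flags[n] for n in control_nodes)
    ctrl_total = len(control_nodes)

    nodes = np.asarray(network_nodes, dtype=object)
    flags = np.array([target_flags[n] for n in network_nodes], dtype=np.int64)
    draw_hits = np.empty(n_random, dtype=np.int64)
    for i in range(n_random):
        pick = rng.choice(len(nodes), size=size, replace=False)
        draw_hits[i] = flags[pick].sum()
    rand_hits = int(draw_hits.sum())
    rand_total = n_random * size

    table = np.array([[ctrl_hits, ctrl_total - ctrl_hits],
                      [rand_hits, rand_total - rand_hits]], dtype=np.int64)
    # degenerate columns (e.g. zero targets anywhere) carry no signal
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        stat, p2 = 0.0, 1.0
    else:
        stat, p2, _, _ = stats.chi2_contingency(table, correction=False)
    ctrl_freq = ctrl_hits / ctrl_total
    rand_freq = rand_hits / rand_total
    p1 = p2 / 2.0 if ctrl_freq > rand_freq else 1.0 - p2 / 2.0

    mc_p = None
    if monte_carlo:
        mc_p = float((np.sum(draw_hits >= ctrl_hits) + 1) / (n_random + 1))

    return EnrichmentResult(
        table=((int(table[0, 0]), int(table[0, 1])),
               (int(table[1, 0]), int(table[1, 1]))),
        statistic=float(stat), p_one_sided=float(p1), p_two_sided=float(p2),
        control_target_freq=ctrl_freq, random_target_freq=rand_freq,
        n_random_draws=n_random, set_size=size, rng_seed=seed,
        monte_carlo_p=mc_p)
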