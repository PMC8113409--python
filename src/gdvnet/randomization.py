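"""Degree-preserving randomization (DPR) null model.

Double-edge swaps - replace edges (a,b),(c,d) by (a,d),(c,b) when the four
endpoints are distinct and the new edges are absent - preserve every node's
degree exactly while scrambling all higher-order structure.  With enough
successful swaps the rewired graph is an approximately uniform sample from
the graphs with the given degree sequence.  The published analysis fixes no
swap count; the default here is the common 10x|E| successful-swap heuristic,
with an attempt guard so near-complete graphs (where few legal swaps exist)
cannot livelock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph import SimpleGraph
from .relevance import ConnectivityMatrix, positive_part, threshold_binarize

logger = logging.getLogger(__name__)

__all__ = ["RewireConfig", "dpr", "dpr_cohort"]


@dataclass(frozen=True)
class RewireConfig:
    """Swap budget and seed for degree-preserving rewiring."""

    swap_multiplier: int = 10   # successful swaps = multiplier * |E|
    seed: int = 0
    max_attempt_factor: int = 100  # attempt guard = factor * |E|

    def __post_init__(self):
        if self.swap_multiplier < 1:
            raise ValueError("swap_multiplier must be >= 1")


def dpr(g: SimpleGraph, cfg: RewireConfig) -> SimpleGraph:
    """Rewire ``g`` by double-edge swaps, preserving each node's degree.

    Performs ``swap_multiplier * |E|`` successful swaps, or stops early when
    ``max_attempt_factor * |E|`` attempts have been spent (graphs with no
    swappable pair, e.g. a triangle or a 2-edge path, come back unchanged).
    """
    m = g.n_edges
    if m < 2:
        return SimpleGraph(g.n_nodes, g.edges)
    rng = np.random.default_rng(cfg.seed)
    edges = [list(e) for e in sorted(g.edges)]
    present = set(g.edges)
    target = cfg.swap_multiplier * m
    max_attempts = cfg.max_attempt_factor * m
    swaps = attempts = 0
    while swaps < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in present or e2 in present:
            continue
        present.discard((a, b) if a < b else (b, a))
        present.discard((c, d) if c < d else (d, c))
        present.add(e1)
        present.add(e2)
        edges[i] = [a, d]
        edges[j] = [c, b]
        swaps += 1
    if swaps < target:
        logger.info("dpr: stopped after %d/%d swaps (%d attempts); the graph "
                    "admits few legal swaps", swaps, target, attempts)
    return SimpleGraph(g.n_nodes, present)


def dpr_cohort(
    subjects: list[tuple[str, ConnectivityMatrix]],
    threshold: float,
    cfg: RewireConfig,
) -> list[tuple[str, SimpleGraph]]:
    """Threshold each subject's matrix and rewire it with a derived seed.

    Subject ``i`` uses seed ``cfg.seed + i``, so the cohort is reproducible
    from the base seed while subjects stay independent.
    """
    out = []
    for i, (sid, F) in enumerate(subjects):
        g = threshold_binarize(positive_part(F), threshold)
        sub_cfg = RewireConfig(swap_multiplier=cfg.swap_multiplier,
                               seed=cfg.seed + i,
                               max_attempt_factor=cfg.max_attempt_factor)
        out.append((sid, dpr(g, sub_cfg)))
    return out
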