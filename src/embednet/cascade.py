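"""Deterministic threshold cascade: regular vs bursting spreading.

Formalizes the toy-network argument: a node activates once the input units
accumulated on it reach a threshold theta; an activated node emits along each
out-edge exactly once, at the tier after its activation — 1 unit when firing
regularly, B units when bursting. The externally driven seed node emits S
units. With regular firing the cascade size tracks out-degree; with bursting
it tracks the k-shell-out index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netgen import DirectedNetwork


@dataclass(frozen=True)
class CascadeParams:
    """theta: activation threshold; spikes_burst (B) and spikes_stimulus (S)
    in input units; a regular node emits exactly 1 unit per out-edge."""

    theta: float = 3.0
    spikes_burst: float = 4.0
    spikes_stimulus: float = 5.0
    mode: str = "regular"

    def __post_init__(self):
        if self.theta <= 1:
            raise ValueError("theta must exceed the regular emission of 1 unit")
        if self.mode not in ("regular", "bursting"):
            raise ValueError("mode must be 'regular' or 'bursting'")
        if self.spikes_burst < self.theta:
            raise ValueError("burst emission B must be >= theta")
        if self.spikes_stimulus < self.theta:
            raise ValueError("stimulus emission S must be >= theta")

    @property
    def emission(self) -> float:
        return self.spikes_burst if self.mode == "bursting" else 1.0


@dataclass
class CascadeResult:
    active_set: set[int]
    activation_tier: dict[int, int]
    emitted: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.active_set)


def run_cascade(
    network: DirectedNetwork, seed_node: int, params: CascadeParams
) -> CascadeResult:
    """Propagate a single activation wave from ``seed_node``.

    Synchronous tiers: at tier 0 the seed emits S units along each out-edge;
    a not-yet-active node activates at tier t+1 iff its accumulated input
    reaches theta; nodes activated at tier t emit (1 or B units per out-edge)
    at tier t. Terminates when no node activates. Deterministic.
    """
    if not 0 <= seed_node < network.n_nodes:
        raise ValueError(f"unknown seed node {seed_node}")
    n = network.n_nodes
    succ: list[list[int]] = [[] for _ in range(n)]
    for pre, post in network.edges:
        succ[pre].append(int(post))

    received = np.zeros(n)
    active = np.zeros(n, dtype=bool)
    active[seed_node] = True
    tier_of = {seed_node: 0}
    emitted: list[float] = []
    frontier = [seed_node]
    tier = 0
    while frontier:
        tier_emitted = 0.0
        arriving = np.zeros(n)
        for v in frontier:
            units = params.spikes_stimulus if tier_of[v] == 0 else params.emission
            for w in succ[v]:
                arriving[w] += units
                tier_emitted += units
        emitted.append(tier_emitted)
        received += arriving
        newly = np.flatnonzero(~active & (received >= params.theta))
        active[newly] = True
        tier += 1
        for v in newly:
            tier_of[int(v)] = tier
        frontier = [int(v) for v in newly]
    return CascadeResult(
        active_set=set(int(v) for v in np.flatnonzero(active)),
        activation_tier=tier_of,
        emitted=emitted,
    )


def run_cascade_fixedpoint(
    network: DirectedNetwork, seed_node: int, params: CascadeParams
) -> set[int]:
    """Test oracle: recompute the full activation set from scratch each tier
    until a fixed point; returns the active set only.
    """
    if not 0 <= seed_node < network.n_nodes:
        raise ValueError(f"unknown seed node {seed_node}")
    active = {seed_node}
    while True:
        # accumulated input at each node from every activated node so far
        received: dict[int, float] = {}
        for pre, post in network.edges:
            pre, post = int(pre), int(post)
            if pre in active:
                units = (params.spikes_stimulus if pre == seed_node
                         else params.emission)
                received[post] = received.get(post, 0.0) + units
        new = {v for v, amount in received.items()
               if v not in active and amount >= params.theta}
        if not new:
            return active
        active |= new
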