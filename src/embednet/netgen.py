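"""Network generation and serialization.

Every network the study needs originates here: multifractal ensembles with
tunably heterogeneous topology, Erdős–Rényi controls matched in size and
density, the 900-neuron modular-hub fixture used for the thought experiment,
and the fixed 14-node toy network used for the regular-vs-bursting cascade
argument.

Networks are directed, simple (no self-loops, no multi-edges) and carry a
per-node excitatory/inhibitory label. Node ids are 0-based internally and
displayed 1-based where figure conventions call for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

EXC = 0
INH = 1

#: hard cap on k^m refined intervals of the generating measure
MAX_REFINED_INTERVALS = 4096


class NetworkFormatError(ValueError):
    """Raised when a serialized network fails to parse or validate."""


@dataclass(frozen=True)
class GeneratingMeasure:
    """A k x k link-probability measure iterated ``m`` times.

    The unit interval is split into ``k`` categories with the given
    ``lengths``; iterating the measure ``m`` times refines it into ``k**m``
    intervals whose lengths are m-fold products of ``lengths`` and whose
    pairwise link probabilities are m-fold products of ``link_probs`` entries.
    """

    link_probs: np.ndarray
    lengths: np.ndarray
    iterations: int

    def __init__(self, link_probs, lengths, iterations: int):
        P = np.asarray(link_probs, dtype=float)
        ell = np.asarray(lengths, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1] or P.shape[0] < 2:
            raise ValueError("link_probs must be a k x k matrix with k >= 2")
        if ell.shape != (P.shape[0],):
            raise ValueError("lengths must have one entry per category")
        if np.any(ell <= 0):
            raise ValueError("lengths must be positive")
        if abs(ell.sum() - 1.0) > 1e-12:
            raise ValueError("lengths must sum to 1")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("link_probs entries must lie in [0, 1]")
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        if P.shape[0] ** iterations > MAX_REFINED_INTERVALS:
            raise ValueError(
                f"k^m = {P.shape[0] ** iterations} refined intervals exceeds "
                f"the limit of {MAX_REFINED_INTERVALS}"
            )
        object.__setattr__(self, "link_probs", P)
        object.__setattr__(self, "lengths", ell)
        object.__setattr__(self, "iterations", int(iterations))

    @property
    def n_categories(self) -> int:
        return self.link_probs.shape[0]

    def refined(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (interval lengths, pairwise probabilities) after iteration.

        Lengths has shape (k**m,), probabilities (k**m, k**m); interval ``s``
        corresponds to the base-k digit sequence of ``s`` (most significant
        digit = first iteration level).
        """
        lengths = self.lengths.copy()
        probs = self.link_probs.copy()
        for _ in range(self.iterations - 1):
            lengths = np.kron(lengths, self.lengths)
            probs = np.kron(probs, self.link_probs)
        return lengths, probs

    def to_dict(self) -> dict:
        return {
            "link_probs": self.link_probs.tolist(),
            "lengths": self.lengths.tolist(),
            "iterations": self.iterations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingMeasure":
        return cls(d["link_probs"], d["lengths"], d["iterations"])


@dataclass
class DirectedNetwork:
    """A simple directed graph with excitatory/inhibitory node labels.

    ``edges`` is an (E, 2) integer array of (pre, post) pairs, unique and
    sorted lexicographically; ``node_kind`` holds EXC/INH per node;
    ``gen_meta`` records generator name, parameters and seed.
    """

    n_nodes: int
    edges: np.ndarray
    node_kind: np.ndarray
    gen_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.node_kind = np.asarray(self.node_kind, dtype=np.int8)
        if self.node_kind.shape != (self.n_nodes,):
            raise ValueError("node_kind must have one entry per node")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
            self.edges = self.edges[order]
            if len(self.edges) > 1:
                dup = np.all(np.diff(self.edges, axis=0) == 0, axis=1)
                if dup.any():
                    raise ValueError("duplicate directed edges are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def excitatory(self) -> np.ndarray:
        return np.flatnonzero(self.node_kind == EXC)

    @property
    def inhibitory(self) -> np.ndarray:
        return np.flatnonzero(self.node_kind == INH)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_nodes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in range(self.n_nodes):
            g.add_node(int(v), kind="I" if self.node_kind[v] == INH else "E")
        g.add_edges_from(map(tuple, self.edges.tolist()))
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return (
            self.n_nodes == other.n_nodes
            and np.array_equal(self.edges, other.edges)
            and np.array_equal(self.node_kind, other.node_kind)
            and self.gen_meta == other.gen_meta
        )


def _trailing_inhibitory(n_nodes: int, inh_fraction: float) -> np.ndarray:
    """E/I labels with the inhibitory block at the highest node ids."""
    n_inh = int(round(n_nodes * inh_fraction))
    kind = np.full(n_nodes, EXC, dtype=np.int8)
    if n_inh:
        kind[n_nodes - n_inh:] = INH
    return kind


def generate_multifractal_network(
    measure: GeneratingMeasure,
    n_nodes: int,
    target_mean_degree: float,
    inh_fraction: float = 0.2,
    seed: int = 0,
    max_clip_fraction: float = 0.01,
    directed_mode: bool = True,
) -> DirectedNetwork:
    """Draw a directed network from an iterated generating measure.

    Each node receives an independent uniform coordinate on [0, 1); the
    link probability of an ordered pair is the iterated measure value at the
    two coordinates, globally rescaled so the expected edge count equals
    ``n_nodes * target_mean_degree``. The two directions of a pair are
    sampled independently (``directed_mode=True``) or tied (reciprocal
    edges) otherwise.

    Raises ``ValueError`` if rescaling pushes more than ``max_clip_fraction``
    of ordered pairs above probability 1 (measure too concentrated for the
    requested density).
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if target_mean_degree >= n_nodes - 1:
        raise ValueError("target_mean_degree must be < n_nodes - 1")
    rng = np.random.default_rng(seed)
    lengths, probs = measure.refined()
    boundaries = np.cumsum(lengths)
    coords = rng.random(n_nodes)
    cat = np.searchsorted(boundaries, coords, side="right")
    cat = np.minimum(cat, len(lengths) - 1)

    counts = np.bincount(cat, minlength=len(lengths)).astype(float)
    pair_mass = counts @ probs @ counts - counts @ np.diag(probs)
    if pair_mass <= 0:
        raise ValueError("generating measure assigns zero mass to all pairs")
    scale = n_nodes * target_mean_degree / pair_mass
    scaled = probs * scale
    if np.any(scaled > 1.0):
        over = scaled > 1.0
        n_over_pairs = counts @ (over * np.ones_like(probs)) @ counts
        frac = n_over_pairs / (n_nodes * (n_nodes - 1))
        if frac > max_clip_fraction:
            raise ValueError(
                f"rescaled link probability exceeds 1 (scale factor "
                f"{scale:.3g}) for {frac:.1%} of pairs; measure too "
                f"concentrated for the requested density"
            )
        scaled = np.clip(scaled, 0.0, 1.0)

    # sample in row blocks to bound memory on large n
    rows_per_block = max(1, int(2e7) // n_nodes)
    pre_list, post_list = [], []
    for start in range(0, n_nodes, rows_per_block):
        stop = min(start + rows_per_block, n_nodes)
        p_block = scaled[np.ix_(cat[start:stop], cat)]
        if directed_mode:
            u = rng.random(p_block.shape)
        else:
            raise NotImplementedError("reciprocal (undirected) sampling mode")
        hit = u < p_block
        idx = np.arange(start, stop)
        hit[idx - start, idx] = False  # no self-loops
        r, c = np.nonzero(hit)
        pre_list.append(r + start)
        post_list.append(c)
    edges = np.column_stack([np.concatenate(pre_list), np.concatenate(post_list)])
    return DirectedNetwork(
        n_nodes=n_nodes,
        edges=edges,
        node_kind=_trailing_inhibitory(n_nodes, inh_fraction),
        gen_meta={
            "generator": "multifractal",
            "seed": int(seed),
            "measure": measure.to_dict(),
            "target_mean_degree": float(target_mean_degree),
            "inh_fraction": float(inh_fraction),
        },
    )


def generate_er_network(
    n_nodes: int,
    n_edges: int,
    inh_fraction: float = 0.2,
    seed: int = 0,
) -> DirectedNetwork:
    """Uniformly sample exactly ``n_edges`` distinct directed non-self edges."""
    max_edges = n_nodes * (n_nodes - 1)
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must lie in [0, {max_edges}]")
    rng = np.random.default_rng(seed)
    chosen = np.empty(0, dtype=np.int64)
    while len(chosen) < n_edges:
        need = n_edges - len(chosen)
        draw = rng.integers(0, max_edges, size=int(need * 1.2) + 16)
        chosen = np.unique(np.concatenate([chosen, draw]))
    if len(chosen) > n_edges:
        # drop a uniform subset to hit the exact count
        chosen = rng.permutation(chosen)[:n_edges]
    pre, rem = np.divmod(chosen, n_nodes - 1)
    post = rem + (rem >= pre)  # skip the diagonal
    return DirectedNetwork(
        n_nodes=n_nodes,
        edges=np.column_stack([pre, post]),
        node_kind=_trailing_inhibitory(n_nodes, inh_fraction),
        gen_meta={"generator": "er", "seed": int(seed), "n_edges": int(n_edges),
                  "inh_fraction": float(inh_fraction)},
    )


def matched_er_network(network: DirectedNetwork, seed: int = 0) -> DirectedNetwork:
    """ER control preserving node count, edge count and E/I labels."""
    er = generate_er_network(network.n_nodes, network.n_edges, seed=seed)
    er.node_kind = network.node_kind.copy()
    er.gen_meta["matched_to"] = network.gen_meta.get("generator", "unknown")
    return er


def build_modular_hub_network(
    n_large_exc: int = 583,
    n_large_inh: int = 167,
    n_small: int = 150,
    n_hubs: int = 30,
    p_within: float = 0.1,
    hub_fan_out: int = 100,
    inh_frac: float = 200.0 / 900.0,
    seed: int = 0,
) -> DirectedNetwork:
    """The modular Gedankenexperiment fixture.

    A large and a small subnetwork, each internally random with connection
    probability ``p_within``; ``n_hubs`` excitatory nodes of the large
    subnetwork additionally project one-way onto the small subnetwork with
    fan-out ``hub_fan_out``. No edge leads from the small subnetwork back to
    the large one. Defaults give 900 nodes (700 excitatory displayed 1-700,
    200 inhibitory displayed 701-900) with a 150-node small subnetwork.

    The small subnetwork's own E/I split follows ``inh_frac`` so the global
    excitatory/inhibitory counts match the displayed id blocks.
    """
    n_small_inh = int(round(n_small * inh_frac))
    n_small_exc = n_small - n_small_inh
    n_exc = n_large_exc + n_small_exc
    n_inh = n_large_inh + n_small_inh
    n_total = n_exc + n_inh
    if n_small <= 0 or n_large_exc <= 0 or n_large_inh < 0:
        raise ValueError("inconsistent subnetwork sizes")
    if n_hubs > n_large_exc or hub_fan_out > n_small:
        raise ValueError("hub specification exceeds subnetwork sizes")

    # id layout: [large exc][small exc][large inh][small inh]
    large = np.concatenate([
        np.arange(n_large_exc),
        np.arange(n_exc, n_exc + n_large_inh),
    ])
    small = np.concatenate([
        np.arange(n_large_exc, n_exc),
        np.arange(n_exc + n_large_inh, n_total),
    ])
    rng = np.random.default_rng(seed)

    def random_block(nodes: np.ndarray) -> np.ndarray:
        m = len(nodes)
        hit = rng.random((m, m)) < p_within
        np.fill_diagonal(hit, False)
        r, c = np.nonzero(hit)
        return np.column_stack([nodes[r], nodes[c]])

    hubs = rng.choice(large[:n_large_exc], size=n_hubs, replace=False)
    hub_edges = []
    for h in hubs:
        targets = rng.choice(small, size=hub_fan_out, replace=False)
        hub_edges.append(np.column_stack([np.full(hub_fan_out, h), targets]))
    edges = np.concatenate([random_block(large), random_block(small)] + hub_edges)
    # hub projections may duplicate existing large-internal edges: dedupe
    edges = np.unique(edges, axis=0)

    kind = np.full(n_total, EXC, dtype=np.int8)
    kind[n_exc:] = INH
    return DirectedNetwork(
        n_nodes=n_total,
        edges=edges,
        node_kind=kind,
        gen_meta={
            "generator": "modular_hub",
            "seed": int(seed),
            "p_within": float(p_within),
            "hub_fan_out": int(hub_fan_out),
            "hub_nodes": sorted(int(h) for h in hubs),
            "small_nodes": sorted(int(s) for s in small),
            "large_nodes": sorted(int(v) for v in large),
        },
    )


# The fixed 14-node toy network (displayed ids 1-14, stored 0-based).
# Printed constraints: node 1 -> {2,3,4,6}; node 5 -> {7..14}; nodes 7-14
# are sinks. The core clique among {1,2,3,4,6} plus the 6 -> 5 bridge is the
# minimal completion that lets a bursting cascade from node 1 cover all 14
# nodes while ranking node 1 above node 5 in the k-shell-out decomposition.
TOY_EDGES_1BASED: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (1, 4), (1, 6),
    (2, 3), (2, 4),
    (3, 4), (3, 6),
    (4, 6), (4, 1),
    (6, 1), (6, 2), (6, 5),
    (5, 7), (5, 8), (5, 9), (5, 10), (5, 11), (5, 12), (5, 13), (5, 14),
)


def build_toy_network() -> DirectedNetwork:
    """The 14-node regular-vs-bursting illustration network; idempotent."""
    edges = np.array(TOY_EDGES_1BASED, dtype=np.int64) - 1
    return DirectedNetwork(
        n_nodes=14,
        edges=edges,
        node_kind=np.zeros(14, dtype=np.int8),
        gen_meta={"generator": "toy", "seed": 0},
    )


# ---------------------------------------------------------------------------
# default ensemble specification

def default_ensemble_spec(
    n_networks: int = 100,
    n_nodes: int = 600,
    mean_degree: float = 15.0,
    n_er_controls: int = 5,
    master_seed: int = 0,
) -> list[dict]:
    """Parameter draws for the default topology-spectrum ensemble.

    One hundred 2-category measures with m in {2, 3}: seventy percent
    assortative (diagonal-dominant, clustering above the ER level, SWI
    above 1) and thirty percent disassortative (off-diagonal-dominant,
    bipartite-leaning, clustering below the ER level, SWI below 1) — so
    realized small-world indices span values below and above 1 — plus ER
    controls at matched size and density.
    """
    specs = []
    for i in range(n_networks):
        prng = np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(i,)))
        if prng.random() < 0.7:  # assortative draw
            d1, d2 = prng.uniform(0.3, 0.95, size=2)
            o = prng.uniform(0.02, 0.4)
        else:  # disassortative draw
            d1, d2 = prng.uniform(0.02, 0.25, size=2)
            o = prng.uniform(0.4, 0.9)
        l0 = prng.uniform(0.2, 0.8)
        specs.append({
            "kind": "multifractal",
            "network_id": i,
            "n_nodes": n_nodes,
            "mean_degree": mean_degree,
            "measure": {
                "link_probs": [[d1, o], [o, d2]],
                "lengths": [l0, 1.0 - l0],
                "iterations": int(prng.integers(2, 4)),
            },
            "seed": i,
        })
    for j in range(n_er_controls):
        specs.append({
            "kind": "er",
            "network_id": n_networks + j,
            "n_nodes": n_nodes,
            "n_edges": int(round(n_nodes * mean_degree)),
            "seed": n_networks + j,
        })
    return specs


def realize_spec(spec: dict) -> DirectedNetwork:
    """Instantiate one entry of an ensemble specification."""
    if spec["kind"] == "multifractal":
        return generate_multifractal_network(
            GeneratingMeasure.from_dict(spec["measure"]),
            n_nodes=spec["n_nodes"],
            target_mean_degree=spec["mean_degree"],
            seed=spec["seed"],
        )
    if spec["kind"] == "er":
        return generate_er_network(
            spec["n_nodes"], spec["n_edges"], seed=spec["seed"])
    raise ValueError(f"unknown network kind {spec['kind']!r}")


# ---------------------------------------------------------------------------
# serialization

def write_network(network: DirectedNetwork, path, format: str = "tsv") -> None:
    """Serialize to edge-list TSV or GraphML. Round-trips exactly."""
    if format == "tsv":
        inh = network.inhibitory
        meta = json.dumps(network.gen_meta, sort_keys=True)
        inh_frac = len(inh) / network.n_nodes if network.n_nodes else 0.0
        gen = network.gen_meta.get("generator", "unknown")
        seed = network.gen_meta.get("seed", "NA")
        with open(path, "w") as fh:
            fh.write(f"# nodes={network.n_nodes} inh_frac={inh_frac:.6g} "
                     f"generator={gen} seed={seed}\n")
            fh.write(f"# inh_nodes={json.dumps([int(v) for v in inh])}\n")
            fh.write(f"# meta={meta}\n")
            for pre, post in network.edges:
                fh.write(f"{pre}\t{post}\n")
    elif format == "graphml":
        g = network.to_networkx()
        g.graph["gen_meta"] = json.dumps(network.gen_meta, sort_keys=True)
        g.graph["n_nodes"] = network.n_nodes
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path, format: str | None = None) -> DirectedNetwork:
    """Parse a serialized network; raises NetworkFormatError on bad input."""
    path = str(path)
    if format is None:
        format = "graphml" if path.endswith((".graphml", ".xml")) else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "graphml":
        return _read_graphml(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: str) -> DirectedNetwork:
    n_nodes = None
    inh_nodes: Sequence[int] = ()
    gen_meta: dict = {}
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("inh_nodes="):
                    inh_nodes = json.loads(body[len("inh_nodes="):])
                elif body.startswith("meta="):
                    gen_meta = json.loads(body[len("meta="):])
                else:
                    for tok in body.split():
                        if tok.startswith("nodes="):
                            n_nodes = int(tok[len("nodes="):])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 'pre<TAB>post', got {line!r}")
            try:
                pre, post = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise NetworkFormatError(
                    f"{path}:{lineno}: non-integer node id") from exc
            if pre == post:
                raise NetworkFormatError(
                    f"{path}:{lineno}: self-loop {pre}->{post} not allowed")
            edges.append((pre, post))
    if n_nodes is None:
        raise NetworkFormatError(f"{path}: missing '# nodes=' header")
    kind = np.full(n_nodes, EXC, dtype=np.int8)
    for v in inh_nodes:
        if not 0 <= v < n_nodes:
            raise NetworkFormatError(f"{path}: inhibitory id {v} out of range")
        kind[v] = INH
    try:
        return DirectedNetwork(
            n_nodes=n_nodes,
            edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
            node_kind=kind,
            gen_meta=gen_meta,
        )
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from exc


def _read_graphml(path: str) -> DirectedNetwork:
    try:
        g = nx.read_graphml(path, node_type=int)
    except Exception as exc:  # lxml/expat errors vary
        raise NetworkFormatError(f"{path}: {exc}") from exc
    n_nodes = int(g.graph.get("n_nodes", g.number_of_nodes()))
    kind = np.full(n_nodes, EXC, dtype=np.int8)
    for v, data in g.nodes(data=True):
        k = data.get("kind", "E")
        if k == "I":
            kind[v] = INH
        elif k != "E":
            raise NetworkFormatError(
                f"{path}: unknown node kind {k!r} for node {v}")
    gen_meta = json.loads(g.graph.get("gen_meta", "{}"))
    try:
        return DirectedNetwork(
            n_nodes=n_nodes,
            edges=np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2),
            node_kind=kind,
            gen_meta=gen_meta,
        )
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from exc
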