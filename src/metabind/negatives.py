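"""Network-based negative sampling on the bipartite drug-target network.

Measured interactions (of either label) define a bipartite graph between
proteins and molecules.  Protein-molecule pairs that are far apart in this
network — shortest path length of at least 7 hops — are declared nonbinding,
augmenting the scarce measured negatives and countering the annotation
imbalance that otherwise lets classifiers learn degree shortcuts.

The network is unweighted, so breadth-first search computes the same
distances Dijkstra's algorithm would, at lower cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graphs import BINDING, NONBINDING, InteractionRecord

DEFAULT_THRESHOLD = 7


def _pnode(pid: str):
    return ("p", pid)


def _mnode(mid: str):
    return ("m", mid)


@dataclass
class BipartiteDTINetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)
    measured_pairs: set = field(default_factory=set)
    n_pos: dict = field(default_factory=dict)   # per-protein measured positives
    n_neg: dict = field(default_factory=dict)   # per-protein measured negatives

    @property
    def protein_nodes(self) -> set[str]:
        return {n[1] for n in self.graph.nodes if n[0] == "p"}

    @property
    def molecule_nodes(self) -> set[str]:
        return {n[1] for n in self.graph.nodes if n[0] == "m"}

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for a, b in self.graph.edges:
            p, m = (a, b) if a[0] == "p" else (b, a)
            out.add((p[1], m[1]))
        return out


def build_network(records: list[InteractionRecord]) -> BipartiteDTINetwork:
    """Bipartite graph over all measured (protein, molecule) pairs."""
    if not records:
        raise ValueError("no records")
    net = BipartiteDTINetwork()
    for r in records:
        net.graph.add_node(_pnode(r.protein_id))
        net.graph.add_node(_mnode(r.molecule_id))
        net.graph.add_edge(_pnode(r.protein_id), _mnode(r.molecule_id))
        if r.pair not in net.measured_pairs:
            net.measured_pairs.add(r.pair)
            key = "n_pos" if r.label == BINDING else "n_neg"
            counts = getattr(net, key)
            counts[r.protein_id] = counts.get(r.protein_id, 0) + 1
    return net


def shortest_distance(net: BipartiteDTINetwork, protein_id: str,
                      molecule_id: str) -> float:
    """Unweighted hop count between a protein and a molecule; inf if disconnected."""
    p, m = _pnode(protein_id), _mnode(molecule_id)
    if p not in net.graph:
        raise KeyError(f"unknown protein {protein_id!r}")
    if m not in net.graph:
        raise KeyError(f"unknown molecule {molecule_id!r}")
    try:
        return float(nx.shortest_path_length(net.graph, p, m))
    except nx.NetworkXNoPath:
        return math.inf


def sample_network_negatives(net: BipartiteDTINetwork,
                             threshold: int = DEFAULT_THRESHOLD,
                             max_per_protein=("auto"),
                             seed: int = 0,
                             include_disconnected: bool = False,
                             ) -> list[InteractionRecord]:
    """Generate nonbinding records for pairs with network distance >= threshold.

    ``max_per_protein``:
      * ``"auto"`` (default): per protein, sample just enough negatives to
        bring its positive ratio to <= 0.5 (the augmentation's stated purpose);
      * an integer: uniform cap per protein;
      * ``None``: no cap, return every qualifying pair.

    Pairs in different components have infinite distance and are excluded
    unless ``include_disconnected`` — absence of network evidence is not the
    same as being provably far.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = sorted(net.protein_nodes)
    molecules = sorted(net.molecule_nodes)

    out: list[InteractionRecord] = []
    for pid in proteins:
        dist = nx.single_source_shortest_path_length(net.graph, _pnode(pid))
        candidates = []
        for mid in molecules:
            if (pid, mid) in net.measured_pairs:
                continue
            d = dist.get(_mnode(mid), math.inf)
            if d >= threshold and (include_disconnected or math.isfinite(d)):
                candidates.append(mid)
        if max_per_protein is None:
            chosen = candidates
        else:
            if max_per_protein == "auto":
                # enough negatives that positives are at most half
                cap = max(0, net.n_pos.get(pid, 0) - net.n_neg.get(pid, 0))
            else:
                cap = int(max_per_protein)
            if len(candidates) > cap:
                idx = rng.choice(len(candidates), size=cap, replace=False)
                chosen = [candidates[i] for i in sorted(idx)]
            else:
                chosen = candidates
        out.extend(InteractionRecord(pid, mid, NONBINDING, "network_negative")
                   for mid in chosen)
    return out


def positive_ratio_by_protein(records: list[InteractionRecord]) -> dict[str, float]:
    """Fraction of binding annotations per protein (the imbalance histogram)."""
    pos: dict[str, int] = {}
    tot: dict[str, int] = {}
    for r in records:
        tot[r.protein_id] = tot.get(r.protein_id, 0) + 1
        if r.label == BINDING:
            pos[r.protein_id] = pos.get(r.protein_id, 0) + 1
    return {p: pos.get(p, 0) / tot[p] for p in tot}
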