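"""Median-joining haplotype networks (Bandelt, Forster & Roehl 1999).

The network starts from the epsilon-relaxed minimum spanning network over the
observed haplotypes and iteratively adds quasi-median (Steiner) vectors for
feasible triplets when they shorten connections, until a fixed point; median
vectors left with degree <= 2 are pruned.  All tie-breaking is by node label
so the construction is deterministic and input-order invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import networkx as nx
import numpy as np

from .gendist import DistanceMatrix
from .seqdata import HaplotypeSet

__all__ = [
    "MjnParams",
    "hamming_matrix",
    "median_joining",
    "write_edge_list",
    "write_gml",
]

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class MjnParams:
    """Median-joining tolerance: epsilon >= 0 widens the feasible-link set."""

    epsilon: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def _hamming(a: str, b: str) -> int:
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x in _UNAMBIGUOUS and y in _UNAMBIGUOUS
    )


def _changed_positions(a: str, b: str) -> list[int]:
    return [
        i
        for i, (x, y) in enumerate(zip(a, b))
        if x != y and x in _UNAMBIGUOUS and y in _UNAMBIGUOUS
    ]


def hamming_matrix(haplotypes: HaplotypeSet) -> DistanceMatrix:
    """Integer Hamming distances over unambiguous positions."""
    n = haplotypes.n
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _hamming(haplotypes.seqs[i], haplotypes.seqs[j])
    return DistanceMatrix(list(haplotypes.labels), out)


def _minimax_weights(graph: nx.Graph) -> dict[tuple[str, str], float]:
    """Minimax path weight (minimum over paths of the maximum edge weight)
    between all node pairs, from a minimum spanning tree."""
    mst = nx.minimum_spanning_tree(graph, weight="weight")
    nodes = sorted(graph.nodes)
    out: dict[tuple[str, str], float] = {}
    for i, u in enumerate(nodes):
        # single-source traversal of the MST tracking the max edge seen
        best = {u: 0.0}
        stack = [u]
        while stack:
            cur = stack.pop()
            for nbr in mst.neighbors(cur):
                if nbr not in best:
                    best[nbr] = max(best[cur], mst[cur][nbr]["weight"])
                    stack.append(nbr)
        for v in nodes[i + 1 :]:
            out[(u, v)] = out[(v, u)] = best[v]
    return out


def _epsilon_network(seqs: dict[str, str], epsilon: int) -> nx.Graph:
    """Minimum spanning network: edges whose weight is within epsilon of the
    minimax connection weight between their endpoints."""
    labels = sorted(seqs)
    complete = nx.Graph()
    complete.add_nodes_from(labels)
    for i, u in enumerate(labels):
        for v in labels[i + 1 :]:
            complete.add_edge(u, v, weight=_hamming(seqs[u], seqs[v]))
    if len(labels) < 2:
        return complete
    minimax = _minimax_weights(complete)
    net = nx.Graph()
    net.add_nodes_from(labels)
    for i, u in enumerate(labels):
        for v in labels[i + 1 :]:
            w = complete[u][v]["weight"]
            if w <= minimax[(u, v)] + epsilon:
                net.add_edge(u, v, weight=w)
    return net


def _quasi_median(a: str, b: str, c: str) -> str:
    """Per-column majority consensus of three sequences.

    Columns where all three states differ (or any state is ambiguous)
    contribute the state of the first sequence, so only majority columns can
    move the median off its parents.
    """
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def median_joining(haplotypes: HaplotypeSet, params: MjnParams = MjnParams()) -> nx.Graph:
    """Build the median-joining network for a set of observed haplotypes.

    Returns a networkx graph whose nodes carry ``kind`` ("observed" or
    "median"), ``sequence`` and ``count`` attributes, and whose edges carry
    ``weight`` (mutation count) and ``positions`` (changed alignment columns).
    """
    if haplotypes.n < 1:
        raise ValueError("need at least one haplotype")
    seqs: dict[str, str] = dict(zip(haplotypes.labels, haplotypes.seqs))
    counts = {l: len(m) for l, m in zip(haplotypes.labels, haplotypes.members)}
    observed = set(haplotypes.labels)
    seq_to_label = {s: l for l, s in seqs.items()}

    n_median = 0
    while True:
        net = _epsilon_network(seqs, params.epsilon)
        # feasible triplets: u-v and u-w linked in the current network
        candidates: dict[str, int] = {}
        for u in sorted(net.nodes):
            nbrs = sorted(net.neighbors(u))
            for i, v in enumerate(nbrs):
                for w in nbrs[i + 1 :]:
                    m = _quasi_median(seqs[u], seqs[v], seqs[w])
                    if m in seq_to_label:
                        continue
                    cost = _hamming(m, seqs[u]) + _hamming(m, seqs[v]) + _hamming(m, seqs[w])
                    if m not in candidates or cost < candidates[m]:
                        candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        added = False
        for m in sorted(candidates):
            if candidates[m] <= lam + params.epsilon:
                n_median += 1
                label = f"mv{n_median}"
                seqs[label] = m
                seq_to_label[m] = label
                counts[label] = 0
                added = True
        if not added:  # pragma: no cover - defensive
            break

    # prune obsolete median vectors (degree <= 2), iterating to stability
    while True:
        net = _epsilon_network(seqs, params.epsilon)
        prunable = sorted(
            n for n in net.nodes if n not in observed and net.degree(n) <= 2
        )
        if not prunable:
            break
        for label in prunable:
            seq_to_label.pop(seqs[label], None)
            del seqs[label]
            del counts[label]

    net = _epsilon_network(seqs, params.epsilon)
    graph = nx.Graph()
    for label in sorted(seqs):
        graph.add_node(
            label,
            kind="observed" if label in observed else "median",
            sequence=seqs[label],
            count=counts[label],
        )
    for u, v, data in net.edges(data=True):
        graph.add_edge(
            u,
            v,
            weight=int(data["weight"]),
            positions=_changed_positions(seqs[u], seqs[v]),
        )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """CSV edge list: from,to,steps,positions (positions ;-separated, 0-based)."""
    with open(path, "w") as fh:
        fh.write("from,to,steps,positions\n")
        for u, v, data in sorted(graph.edges(data=True)):
            pos = ";".join(str(p) for p in data["positions"])
            fh.write(f"{u},{v},{data['weight']},{pos}\n")


def write_gml(graph: nx.Graph, path: str | Path) -> None:
    export = nx.Graph()
    for node, data in graph.nodes(data=True):
        export.add_node(node, kind=data["kind"], count=data["count"])
    for u, v, data in graph.edges(data=True):
        export.add_edge(u, v, weight=data["weight"])
    nx.write_gml(export, str(path))
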