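"""DNA-barcode population genetics: haplotype collapsing, p and Kimura
2-parameter distances, and median-joining haplotype networks.

The median-joining construction follows Bandelt, Forster & Röhl (1999):
a minimum-spanning network over the haplotypes (all links tied, within
``epsilon``, with the bottleneck connection threshold), augmented with
majority-consensus median vectors of linked triplets whenever they reduce
the total connection cost, iterated to a fixed point, followed by removal
of obsolete median nodes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

AMBIGUOUS = frozenset("RYSWKMBDHVN-.?")
UNAMBIGUOUS = frozenset("ACGT")
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class Haplotype:
    sequence: str
    frequency: int
    member_ids: tuple[str, ...]


@dataclass
class HaplotypeSet:
    """Distinct sequences with specimen frequencies, from an alignment."""

    alignment_length: int
    haplotypes: list[Haplotype]

    @property
    def n_specimens(self) -> int:
        return sum(h.frequency for h in self.haplotypes)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    model: str  # "p" or "K2P"


def collapse_haplotypes(
    aligned: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    complete_deletion: bool = True,
) -> HaplotypeSet:
    """Merge identical aligned sequences into haplotypes.

    With ``complete_deletion`` (default), every alignment column containing
    a gap or ambiguity code in any sequence is removed before comparison.
    Haplotypes are ordered by first occurrence.
    """
    if not aligned:
        raise ValueError("no sequences")
    seqs = [s.upper() for s in aligned]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not all the same length")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(seqs))]
    if complete_deletion:
        keep = [j for j in range(L) if all(s[j] in UNAMBIGUOUS for s in seqs)]
        seqs = ["".join(s[j] for j in keep) for s in seqs]
        L = len(keep)
    groups: dict[str, list[str]] = {}
    for sid, s in zip(ids, seqs):
        groups.setdefault(s, []).append(sid)
    haps = [Haplotype(s, len(m), tuple(m)) for s, m in groups.items()]
    return HaplotypeSet(L, haps)


def _comparable(s1: str, s2: str):
    for a, b in zip(s1.upper(), s2.upper()):
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS:
            yield a, b


def p_distance(s1: str, s2: str) -> float:
    """Proportion of differing sites, pairwise deletion of ambiguous sites."""
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    pairs = list(_comparable(s1, s2))
    if not pairs:
        raise ValueError("no comparable sites")
    return sum(a != b for a, b in pairs) / len(pairs)


def k2p_distance(s1: str, s2: str) -> float:
    """Kimura 2-parameter distance.

    With P and Q the transition and transversion proportions over
    comparable sites, d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).  Returns
    NaN when a logarithm argument is non-positive (saturation).
    """
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    pairs = list(_comparable(s1, s2))
    if not pairs:
        raise ValueError("no comparable sites")
    n = len(pairs)
    ts = sum((a, b) in TRANSITIONS for a, b in pairs)
    tv = sum(a != b and (a, b) not in TRANSITIONS for a, b in pairs)
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def distance_matrix(
    seqs: Sequence[str], labels: Optional[Sequence[str]] = None, model: str = "K2P"
) -> DistanceMatrix:
    fn = {"K2P": k2p_distance, "k2p": k2p_distance, "p": p_distance}[model]
    labels = list(labels) if labels is not None else [f"seq{i + 1}" for i in range(len(seqs))]
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = fn(seqs[i], seqs[j])
    return DistanceMatrix(labels, d, "p" if model == "p" else "K2P")


def max_pairwise_distance(dm: DistanceMatrix) -> tuple[float, tuple[str, str]]:
    """Maximum off-diagonal distance and one attaining pair.

    Undefined (NaN) entries are excluded with a warning; ties are broken
    toward the first pair in label order.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two sequences")
    best: Optional[float] = None
    pair = None
    saw_nan = False
    for i, j in itertools.combinations(range(n), 2):
        v = dm.d[i, j]
        if math.isnan(v):
            saw_nan = True
            continue
        if best is None or v > best:
            best, pair = v, (dm.labels[i], dm.labels[j])
    if saw_nan:
        warnings.warn("undefined (saturated) distances excluded from the maximum")
    if best is None:
        raise ValueError("all pairwise distances undefined")
    return best, pair


# --- median-joining network -------------------------------------------------


@dataclass
class MJNetwork:
    """Haplotype network; nodes are sequence strings on the collapsed
    alignment, observed nodes carry specimen frequencies, inferred median
    vectors carry frequency 0.  Edge attribute ``steps`` is the Hamming
    distance between the endpoint vectors."""

    graph: nx.Graph
    observed: list[str] = field(default_factory=list)

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def to_gml(self, path: str) -> None:
        nx.write_gml(self.graph, path)

    def to_dot(self) -> str:
        lines = ["graph haplotype_network {"]
        names = {n: f"H{i + 1}" for i, n in enumerate(self.graph.nodes)}
        for n, d in self.graph.nodes(data=True):
            shape = "circle" if d["kind"] == "observed" else "point"
            lines.append(
                f'  {names[n]} [label="{names[n]} (n={d["frequency"]})", shape={shape}];'
            )
        for u, v, d in self.graph.edges(data=True):
            lines.append(f'  {names[u]} -- {names[v]} [label="{d["steps"]}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def hamming(s1: str, s2: str) -> int:
    return sum(a != b for a, b in zip(s1, s2))


def _msn_edges(nodes: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Minimum-spanning network: every link whose length is within
    ``epsilon`` of the bottleneck (minimax-path) distance of its pair."""
    if len(nodes) < 2:
        return []
    complete = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        complete.add_edge(u, v, weight=hamming(u, v))
    mst = nx.minimum_spanning_tree(complete)
    edges = []
    for u, v in itertools.combinations(nodes, 2):
        path = nx.shortest_path(mst, u, v)
        bottleneck = max(
            mst[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        d = complete[u][v]["weight"]
        if d <= bottleneck + epsilon:
            edges.append((u, v, d))
    return edges


def _mst_cost(nodes: list[str]) -> int:
    if len(nodes) < 2:
        return 0
    g = nx.Graph()
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=hamming(u, v))
    return int(sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g)))


def _median(u: str, v: str, w: str, anchor: str) -> str:
    """Per-column majority consensus of three sequences; three-way ties
    resolved toward ``anchor`` (the first observed haplotype) for
    deterministic builds."""
    out = []
    for a, b, c, ref in zip(u, v, w, anchor):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(ref)
    return "".join(out)


def median_joining_network(hs: HaplotypeSet, epsilon: int = 0, max_rounds: int = 50) -> MJNetwork:
    """Median-joining network of a haplotype set.

    Candidate medians are generated from triplets joined in the current
    minimum-spanning network and admitted when they strictly reduce the
    total connection (spanning) cost; generation iterates to a fixed point
    and obsolete medians (absent from every shortest path between observed
    haplotypes) are deleted.
    """
    observed = [h.sequence for h in hs.haplotypes]
    freq = {h.sequence: h.frequency for h in hs.haplotypes}
    if not observed:
        raise ValueError("empty haplotype set")
    anchor = observed[0]
    nodes = list(dict.fromkeys(observed))

    for _ in range(max_rounds):
        edges = _msn_edges(nodes, epsilon)
        adj = nx.Graph()
        adj.add_nodes_from(nodes)
        adj.add_weighted_edges_from(edges, weight="steps")
        cost = _mst_cost(nodes)
        candidates = set()
        for v in adj.nodes:
            for u, w in itertools.combinations(adj[v], 2):
                m = _median(u, v, w, anchor)
                if m not in nodes:
                    candidates.add(m)
        best_gain, best_m = 0, None
        for m in sorted(candidates):
            gain = cost - _mst_cost(nodes + [m])
            if gain > best_gain:  # ties resolved to the lexicographically first
                best_gain, best_m = gain, m
        if best_m is None:
            break
        nodes.append(best_m)

    # prune medians not on any shortest path between observed haplotypes
    while True:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, d in _msn_edges(nodes, epsilon):
            g.add_edge(u, v, steps=d, weight=d)
        needed = set(observed)
        for a, b in itertools.combinations(observed, 2):
            for path in nx.all_shortest_paths(g, a, b, weight="weight"):
                needed.update(path)
        drop = [n for n in nodes if n not in needed]
        if not drop:
            break
        nodes = [n for n in nodes if n in needed]

    net = nx.Graph()
    for n in nodes:
        kind = "observed" if n in freq else "median"
        net.add_node(n, kind=kind, frequency=freq.get(n, 0))
    for u, v, d in _msn_edges(nodes, epsilon):
        net.add_edge(u, v, steps=d)
    if len(nodes) == 1:
        pass
    elif not nx.is_connected(net):  # pragma: no cover - MSN is connected by construction
        raise RuntimeError("median-joining network is not connected")
    return MJNetwork(net, observed)
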