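"""Protein-protein interaction network container and degree-matched sampling.

The interactome is an undirected, unweighted graph of protein identifiers.
All topological quantities used by the proximity measures -- shortest-path
distances, closeness centrality, degree bins for the randomization null
model -- are computed here. Analyses are expected to run on the largest
connected component, where every pairwise distance is finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "DegreeBins",
    "load_network",
    "largest_connected_component",
    "shortest_path_lengths",
    "closeness_centrality",
    "build_degree_bins",
    "sample_degree_matched",
]


class Interactome:
    """An undirected PPI network with cached node indexing and distances.

    Node identifiers are opaque strings taken verbatim (no case folding).
    Self-loops are removed on construction; parallel edges cannot exist in
    the underlying simple graph. The all-pairs shortest-path matrix is
    computed lazily and cached, which is the workhorse behind the proximity
    measures (distances are small integers; unreachable pairs are stored
    as -1).
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph(graph)
        loops = list(nx.selfloop_edges(g))
        if loops:
            g.remove_edges_from(loops)
            logger.debug("dropped %d self-loop(s)", len(loops))
        self._g = g
        self._nodes: list = sorted(g.nodes)
        self._index: dict = {n: i for i, n in enumerate(self._nodes)}
        self._dist: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> list:
        """Nodes in deterministic (sorted) order."""
        return list(self._nodes)

    @property
    def node_set(self) -> set:
        return set(self._nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self._g.edges}

    @property
    def degree(self) -> dict:
        return dict(self._g.degree)

    def __contains__(self, node) -> bool:
        return node in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def indices(self, nodes: Iterable) -> np.ndarray:
        """Integer indices of ``nodes`` into the distance matrix rows."""
        try:
            return np.fromiter(
                (self._index[n] for n in nodes), dtype=np.intp
            )
        except KeyError as exc:
            raise KeyError(f"node {exc.args[0]!r} not in the interactome") from None

    def is_connected(self) -> bool:
        return nx.is_connected(self._g)

    # -- distances ---------------------------------------------------------

    def distance_matrix(self) -> np.ndarray:
        """All-pairs unweighted shortest-path matrix (int32, -1 = unreachable).

        Cached after the first call. Row/column order follows ``self.nodes``.
        """
        if self._dist is None:
            adj = nx.to_scipy_sparse_array(self._g, nodelist=self._nodes, format="csr")
            d = _sp_shortest_path(adj, method="D", unweighted=True, directed=False)
            out = np.full(d.shape, -1, dtype=np.int32)
            finite = np.isfinite(d)
            out[finite] = d[finite].astype(np.int32)
            self._dist = out
        return self._dist

    def distance(self, u, v) -> int:
        d = self.distance_matrix()[self._index[u], self._index[v]]
        return int(d)


@dataclass(frozen=True)
class DegreeBins:
    """Partition of the nodes into degree intervals ``[lower, upper)``.

    Each bin holds at least ``min_bin_size`` nodes (the last interval may
    have been merged downward to satisfy the floor). Bins jointly cover
    every node of the graph they were built from.
    """

    bins: tuple  # of (lower: int, upper: int, members: tuple)
    min_bin_size: int

    def bin_for_degree(self, k: int):
        for lo, hi, members in self.bins:
            if lo <= k < hi:
                return lo, hi, members
        raise KeyError(f"degree {k} is not covered by any bin")

    def members_for_degree(self, k: int) -> tuple:
        return self.bin_for_degree(k)[2]

    @property
    def sizes(self) -> list:
        return [len(m) for _, _, m in self.bins]


# -- construction ----------------------------------------------------------


def load_network(path, format: str = "edgelist") -> Interactome:
    """Read an undirected network from a two-column edge list or a SIF file.

    Duplicate edges and self-loops are dropped (their counts are logged).
    Identifiers are taken verbatim. Lines starting with ``#`` and blank
    lines are skipped.
    """
    path = Path(path)
    if format not in ("edgelist", "sif"):
        raise ValueError(f"unknown format {format!r}")
    g = nx.Graph()
    n_self, n_dup, n_rows = 0, 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "edgelist":
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}"
                    )
                pairs = [(fields[0], fields[1])]
            else:  # sif: source, interaction type, one or more partners
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF row needs source, relation and >=1 target"
                    )
                pairs = [(fields[0], t) for t in fields[2:]]
            for u, v in pairs:
                n_rows += 1
                if u == v:
                    n_self += 1
                    continue
                if g.has_edge(u, v):
                    n_dup += 1
                    continue
                g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges found")
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s) out of %d rows",
            path, n_self, n_dup, n_rows,
        )
    return Interactome(g)


def largest_connected_component(g: Interactome) -> Interactome:
    """Induced subgraph on the largest component.

    Ties in component size are broken by the component containing the
    lexicographically smallest node, so the result is deterministic.
    """
    if len(g) == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(g.graph))
    max_size = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == max_size]
    best = min(candidates, key=lambda c: min(c))
    return Interactome(g.graph.subgraph(best))


# -- topological quantities -------------------------------------------------


def shortest_path_lengths(g: Interactome, sources: Iterable) -> dict:
    """BFS distances from each source to every reachable node.

    Returns a map ``(source, node) -> int``. Raises ``KeyError`` naming any
    source that is not in the network.
    """
    out: dict = {}
    for s in sources:
        if s not in g:
            raise KeyError(f"source node {s!r} not in the interactome")
        for v, d in nx.single_source_shortest_path_length(g.graph, s).items():
            out[(s, v)] = int(d)
    return out


def closeness_centrality(g: Interactome, within: Iterable | None = None) -> dict:
    """Standard closeness ``(n-1) / sum_v d(u, v)`` for each requested node.

    ``within`` restricts which nodes the centrality is computed *for*; the
    distance sum always runs over the whole (connected) network. On a
    disconnected graph a node's unreachable partners are excluded from the
    sum, matching the usual convention for the reachable part.
    """
    nodes = g.nodes if within is None else list(within)
    idx = g.indices(nodes)
    D = g.distance_matrix()
    out = {}
    for node, i in zip(nodes, idx):
        row = D[i]
        reachable = row >= 0
        total = int(row[reachable].sum())
        n_reach = int(reachable.sum())  # includes self (d=0)
        out[node] = (n_reach - 1) / total if total > 0 else 0.0
    return out


def build_degree_bins(g: Interactome, min_bin_size: int = 100) -> DegreeBins:
    """Group nodes into degree intervals with at least ``min_bin_size`` members.

    Bins grow greedily from the lowest unassigned degree upward, extending
    the upper bound minimally until the membership floor is met; an
    undersized tail is merged into its predecessor. With a floor larger
    than the network a single all-node bin is returned with a warning.
    """
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    degree = g.degree
    by_degree: dict[int, list] = {}
    for node, k in degree.items():
        by_degree.setdefault(k, []).append(node)
    degrees = sorted(by_degree)
    if min_bin_size > len(g):
        logger.warning(
            "min_bin_size=%d exceeds network size %d; using a single bin",
            min_bin_size, len(g),
        )
    bins: list[tuple[int, int, tuple]] = []
    current: list = []
    lo = degrees[0] if degrees else 0
    for k in degrees:
        if not current:
            lo = k
        current.extend(sorted(by_degree[k]))
        if len(current) >= min_bin_size:
            bins.append((lo, k + 1, tuple(current)))
            current = []
    if current:  # undersized tail
        if bins:
            plo, _, pmembers = bins.pop()
            bins.append((plo, degrees[-1] + 1, tuple(list(pmembers) + current)))
        else:
            bins.append((lo, degrees[-1] + 1, tuple(current)))
    return DegreeBins(bins=tuple(bins), min_bin_size=min_bin_size)


def sample_degree_matched(
    g: Interactome,
    template: Iterable,
    bins: DegreeBins,
    rng: np.random.Generator,
) -> set:
    """Draw a random node set matching the template's size and degree bins.

    Each template node is replaced by a node drawn uniformly from the
    degree bin containing the template node's degree; draws within the
    returned set are distinct (without replacement inside each bin).
    """
    template = list(template)
    degree = g.degree
    groups: dict[tuple[int, int], int] = {}
    for node in template:
        if node not in g:
            raise KeyError(f"template node {node!r} not in the interactome")
        lo, hi, _ = bins.bin_for_degree(degree[node])
        groups[(lo, hi)] = groups.get((lo, hi), 0) + 1
    sampled: list = []
    for (lo, hi), count in groups.items():
        members = bins.bin_for_degree(lo)[2]
        if count > len(members):
            raise ValueError(
                f"cannot sample {count} distinct nodes from degree bin "
                f"[{lo},{hi}) of size {len(members)}"
            )
        picks = rng.choice(len(members), size=count, replace=False)
        sampled.extend(members[int(i)] for i in picks)
    return set(sampled)
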