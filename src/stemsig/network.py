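"""Protein-association networks (PANs) from signature gene sets.

A PAN starts from the edges of a BioGRID-style interaction table that
touch at least one *seed* protein (a protein coded by a signature gene),
is reduced to the seeds plus the n most-connected interactors, and is
decomposed into communities by Girvan-Newman edge-betweenness clustering
with the maximum-modularity cut.

The graph algorithms here (Brandes edge betweenness, iterative
edge-removal clustering, Newman-Girvan modularity) are implemented
directly with deterministic lexicographic tie-breaking, so identical
input files always give identical removal sequences and memberships.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import pandas as pd

COL_SYM_A = "Official Symbol Interactor A"
COL_SYM_B = "Official Symbol Interactor B"
COL_ORG_A = "Organism Interactor A"
COL_ORG_B = "Organism Interactor B"

Edge = tuple[str, str]


class FormatError(ValueError):
    """Raised when an interaction file lacks required columns."""


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionGraph:
    """Simple undirected protein graph with seed flags.

    ``nodes`` maps protein symbol -> is_seed; ``edges`` holds deduplicated
    unordered symbol pairs (stored sorted) with no self-loops.
    """

    nodes: dict[str, bool] = field(default_factory=dict)
    edges: set[Edge] = field(default_factory=set)
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at {a}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) endpoint missing from nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {v: [] for v in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        for v in adj:
            adj[v].sort()
        return adj

    def degree(self) -> dict[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass
class AugmentConfig:
    """Settings for the top-interactor reduction."""

    n_interactors: int = 30
    taxid: int = 9606
    rank_by: str = "seed_partners"  # or "total_degree"
    seed_edges_only: bool = False

    def __post_init__(self) -> None:
        if self.n_interactors < 0:
            raise ValueError("n_interactors must be >= 0")
        if self.rank_by not in ("seed_partners", "total_degree"):
            raise ValueError(f"unknown ranking {self.rank_by!r}")


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    Q: float
    removal_sequence: list[Edge]


def parse_biogrid(path, taxid: int = 9606) -> tuple[set[Edge], dict[str, int]]:
    """Edges from a BioGRID TAB-style file, filtered to one taxonomy ID.

    Rows where both organism columns equal ``taxid`` are retained; symbols
    are uppercased; self-interactions are dropped and duplicate pairs
    collapsed.  Returns the edge set and a provenance dict counting rows
    kept, taxid-filtered, self-loops and duplicates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (COL_SYM_A, COL_SYM_B, COL_ORG_A, COL_ORG_B):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    n_rows = len(df)
    if n_rows == 0:
        return set(), {
            "rows": 0,
            "taxid_filtered": 0,
            "self_loops": 0,
            "duplicates": 0,
        }
    keep = (df[COL_ORG_A].astype(int) == taxid) & (
        df[COL_ORG_B].astype(int) == taxid
    )
    n_filtered = int((~keep).sum())
    edges: set[Edge] = set()
    n_self = 0
    n_dup = 0
    for a, b in zip(df.loc[keep, COL_SYM_A], df.loc[keep, COL_SYM_B]):
        a, b = str(a).upper(), str(b).upper()
        if a == b:
            n_self += 1
            continue
        e = _edge(a, b)
        if e in edges:
            n_dup += 1
        else:
            edges.add(e)
    return edges, {
        "rows": n_rows,
        "taxid_filtered": n_filtered,
        "self_loops": n_self,
        "duplicates": n_dup,
    }


def extract_signature_network(
    edges: set[Edge], seeds: set[str]
) -> InteractionGraph:
    """Keep exactly the edges with at least one endpoint in ``seeds``."""
    seeds = {s.upper() for s in seeds}
    kept = {e for e in edges if e[0] in seeds or e[1] in seeds}
    nodes: dict[str, bool] = {}
    for a, b in kept:
        nodes[a] = a in seeds
        nodes[b] = b in seeds
    return InteractionGraph(nodes=nodes, edges=kept)


def augment_top_interactors(
    graph: InteractionGraph,
    all_edges: set[Edge],
    seeds: set[str],
    config: AugmentConfig | None = None,
) -> InteractionGraph:
    """Reduce to seeds plus the n most-connected non-seed interactors.

    Non-seed proteins are ranked by their number of distinct seed
    interaction partners (or total degree over ``all_edges`` when
    ``rank_by="total_degree"``), ties broken lexicographically by symbol.
    The final node set is the seeds that carry edges plus the retained
    interactors; the final edge set is every edge of ``all_edges`` among
    those nodes, or only seed-touching edges if ``seed_edges_only``.
    """
    config = config or AugmentConfig()
    seeds = {s.upper() for s in seeds}
    counts: dict[str, set[str] | int] = {}
    if config.rank_by == "seed_partners":
        partners: dict[str, set[str]] = {}
        for a, b in graph.edges:
            if a in seeds and b not in seeds:
                partners.setdefault(b, set()).add(a)
            if b in seeds and a not in seeds:
                partners.setdefault(a, set()).add(b)
        scores = {v: len(p) for v, p in partners.items()}
    else:
        deg: dict[str, int] = {}
        for a, b in all_edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        scores = {v: deg.get(v, 0) for v in graph.nodes if v not in seeds}
    ranked = sorted(scores, key=lambda v: (-scores[v], v))
    retained = set(ranked[: config.n_interactors])
    seed_nodes = {v for v in graph.nodes if v in seeds}
    final_nodes = seed_nodes | retained
    final_edges = set()
    for e in all_edges:
        a, b = e
        if a in final_nodes and b in final_nodes:
            if config.seed_edges_only and not (a in seeds or b in seeds):
                continue
            final_edges.add(e)
    # seeds that end up isolated after reduction are dropped with the edges
    used = {v for e in final_edges for v in e}
    nodes = {v: v in seeds for v in final_nodes if v in used}
    return InteractionGraph(nodes=nodes, edges=final_edges)


def edge_betweenness(graph: InteractionGraph) -> dict[Edge, float]:
    """Brandes edge betweenness on an unweighted undirected graph.

    The value of an edge is the sum over unordered node pairs of the
    fraction of shortest paths between them that traverse the edge
    (pairs' endpoints included).
    """
    adj = graph.adjacency()
    bet = dict.fromkeys(graph.edges, 0.0)
    for s in sorted(graph.nodes):
        # BFS from s: shortest-path counts sigma and predecessor lists
        dist = {s: 0}
        sigma = {s: 1.0}
        preds: dict[str, list[str]] = {v: [] for v in graph.nodes}
        order: list[str] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation (Brandes), credited to edges
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                c = sigma[v] / sigma[w] * (1.0 + delta[w])
                bet[_edge(v, w)] += c
                delta[v] += c
    return {e: b / 2.0 for e, b in bet.items()}  # each pair counted twice


def modularity(graph: InteractionGraph, membership: dict[str, int]) -> float:
    """Newman-Girvan modularity Q = sum_c [m_c/m - (d_c/2m)^2]."""
    missing = set(graph.nodes) - set(membership)
    if missing:
        raise ValueError(f"nodes missing from membership: {sorted(missing)}")
    m = graph.n_edges
    if m == 0:
        return 0.0
    intra: dict[int, int] = {}
    deg_tot: dict[int, int] = {}
    deg = graph.degree()
    for v, c in membership.items():
        if v in deg:
            deg_tot[c] = deg_tot.get(c, 0) + deg[v]
    for a, b in graph.edges:
        if membership[a] == membership[b]:
            c = membership[a]
            intra[c] = intra.get(c, 0) + 1
    q = 0.0
    for c in deg_tot:
        q += intra.get(c, 0) / m - (deg_tot[c] / (2.0 * m)) ** 2
    return q


def _components(nodes: list[str], edges: set[Edge]) -> dict[str, int]:
    adj: dict[str, list[str]] = {v: [] for v in nodes}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    label: dict[str, int] = {}
    comp = 0
    for start in sorted(nodes):
        if start in label:
            continue
        stack = [start]
        label[start] = comp
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in label:
                    label[w] = comp
                    stack.append(w)
        comp += 1
    return label


def girvan_newman_communities(graph: InteractionGraph) -> CommunityPartition:
    """Edge-betweenness clustering with the maximum-modularity cut.

    Repeatedly removes the remaining edge of highest betweenness
    (recomputed after every removal; ties broken by lexicographic edge
    label) and tracks the connected components.  The returned partition
    is the one along the removal sequence whose Newman-Girvan modularity,
    evaluated on the original graph, is highest; the earliest such
    partition wins ties.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    nodes = list(graph.nodes)
    remaining = set(graph.edges)
    removal_sequence: list[Edge] = []

    best_membership = _components(nodes, remaining)
    best_q = modularity(graph, best_membership)
    while remaining:
        work = InteractionGraph(
            nodes={v: graph.nodes[v] for v in nodes}, edges=set(remaining)
        )
        bet = edge_betweenness(work)
        # ties: highest betweenness, then lexicographically smallest label
        top = max(bet.values())
        target = min(e for e, b in bet.items() if b == top)
        remaining.discard(target)
        removal_sequence.append(target)
        membership = _components(nodes, remaining)
        q = modularity(graph, membership)
        if q > best_q:
            best_q = q
            best_membership = membership
    return CommunityPartition(
        membership=best_membership, Q=best_q, removal_sequence=removal_sequence
    )


def write_membership_tsv(partition: CommunityPartition, path) -> None:
    pd.DataFrame(
        sorted(partition.membership.items()), columns=["protein", "community"]
    ).to_csv(path, sep="\t", index=False)


def write_edge_list_tsv(graph: InteractionGraph, path) -> None:
    pd.DataFrame(
        sorted(graph.edges), columns=["protein_a", "protein_b"]
    ).to_csv(path, sep="\t", index=False)


def to_graphml(graph: InteractionGraph, partition: CommunityPartition | None, path) -> None:
    """Minimal GraphML export with seed flags and community labels."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '<key id="seed" for="node" attr.name="is_seed" attr.type="boolean"/>',
        '<key id="community" for="node" attr.name="community" attr.type="int"/>',
        '<graph edgedefault="undirected">',
    ]
    for v in sorted(graph.nodes):
        comm = partition.membership.get(v, -1) if partition else -1
        lines.append(
            f'<node id="{v}"><data key="seed">{str(graph.nodes[v]).lower()}</data>'
            f'<data key="community">{comm}</data></node>'
        )
    for a, b in sorted(graph.edges):
        lines.append(f'<edge source="{a}" target="{b}"/>')
    lines += ["</graph>", "</graphml>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
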