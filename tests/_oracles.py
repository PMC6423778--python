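"""Independent brute-force oracles shared by the test modules."""

import itertools

import networkx as nx


def enumerate_edge_betweenness(gnx) -> dict:
    """Edge betweenness by explicit enumeration of every shortest path
    between every unordered node pair."""
    bet = {tuple(sorted(e)): 0.0 for e in gnx.edges()}
    for s, t in itertools.combinations(gnx.nodes(), 2):
        try:
            paths = list(nx.all_shortest_paths(gnx, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for a, b in zip(path, path[1:]):
                bet[tuple(sorted((a, b)))] += 1.0 / len(paths)
    return bet


def all_partitions(items):
    """Every partition of a collection into nonempty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part
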