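"""Independent brute-force / networkx oracles for the native metrics.

These deliberately take different code paths from the implementation:
shortest-path metrics go through networkx path enumeration, censuses and
clustering through exhaustive pair enumeration on the networkx graph.
"""

import itertools

import networkx as nx


def to_nx(net):
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.arcs)
    return g


def oracle_betweenness_raw(net):
    """Sum over ordered (s, t) pairs of the fraction of enumerated shortest
    s->t paths passing through each other node."""
    g = to_nx(net)
    cb = {v: 0.0 for v in net.nodes}
    for s, t in itertools.permutations(net.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                cb[v] += 1.0 / len(paths)
    return cb


def oracle_closeness_std(net, direction="out", unreachable="penalize"):
    g = to_nx(net)
    if direction == "in":
        g = g.reverse()
    n = len(net.nodes)
    out = {}
    for v in net.nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        reached = len(dist) - 1
        if reached == 0 or n == 1:
            out[v] = 0.0
        elif unreachable == "penalize":
            farness = sum(dist.values()) + n * (n - 1 - reached)
            out[v] = (n - 1) / farness
        else:
            out[v] = (reached / (n - 1)) * (reached / sum(dist.values()))
    return out


def oracle_local_clustering(net):
    g = to_nx(net)
    out = {}
    for v in net.nodes:
        nb = (set(g.successors(v)) | set(g.predecessors(v))) - {v}
        k = len(nb)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.permutations(nb, 2) if g.has_edge(a, b)
        )
        out[v] = links / (k * (k - 1))
    return out


def oracle_dyad_census(net):
    """(mutual, asymmetric, null) by exhaustive unordered-pair enumeration."""
    g = to_nx(net)
    m = a = nul = 0
    for u, v in itertools.combinations(sorted(net.nodes), 2):
        fwd, bwd = g.has_edge(u, v), g.has_edge(v, u)
        if fwd and bwd:
            m += 1
        elif fwd or bwd:
            a += 1
        else:
            nul += 1
    return m, a, nul
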