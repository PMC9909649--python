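"""Node- and network-level statistics of directed transfer networks.

All metrics follow the directed-network conventions of classical social
network analysis. Path-based metrics (betweenness, closeness) treat the
network as directed and UNWEIGHTED: a tie either exists or it does not, and
geodesics count hops. Degrees are binary counts of distinct partners, so a
hospital that sends 1,000 patients to one partner has out-degree 1.

Standardizations:

* betweenness: raw Brandes betweenness / ((N-1)(N-2)), the number of ordered
  pairs of other nodes — 1 means every geodesic between others passes here;
* closeness: (N-1) / farness, where farness is the sum of geodesic distances
  to the other nodes;
* in-degree centralization: sum_i (d_max - d_i) / (N-1)^2, which is exactly 1
  for the inward star (every node pointing at a single hub) and 0 for any
  in-regular network.

Distances to unreachable targets follow a documented, switchable convention
(see :func:`closeness`).
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import DyadCensus, Hospital, TransferNetwork, dyad_census, registry_index


@dataclass
class NodeMetrics:
    """Per-hospital network statistics."""

    hospital_id: str
    in_degree: int
    out_degree: int
    total_degree: int
    net_connectivity: int
    betweenness_std: float = float("nan")
    closeness_std: float = float("nan")
    clustering_local: float = float("nan")


@dataclass
class NetworkMetrics:
    """Whole-network statistics."""

    n_nodes: int
    n_arcs: int
    density: float
    in_degree_centralization: float
    avg_clustering: float
    reciprocity: float
    census: DyadCensus
    betweenness_mean_sd: tuple[float, float]
    closeness_mean_sd: tuple[float, float]


@dataclass
class RegressionFit:
    """OLS fit of in-degree on served population (millions)."""

    slope: float
    intercept: float
    p_value: float
    n_points: int
    slope_se: float = float("nan")
    r_value: float = float("nan")


@dataclass
class ProportionComparison:
    """Two-group comparison of a binary outcome proportion."""

    group_a_numerator: int
    group_a_denominator: int
    group_b_numerator: int
    group_b_denominator: int
    percent_a: float
    percent_b: float
    p_value: float
    group_a_hospitals: list[str] = field(default_factory=list)


@dataclass
class DegreeDistribution:
    """Histogram of a degree together with its median and IQR."""

    direction: str
    histogram: list[tuple[int, int]]
    median: float
    iqr: tuple[float, float]


# --------------------------------------------------------------------------
# Degrees
# --------------------------------------------------------------------------

def degree_metrics(net: TransferNetwork) -> list[NodeMetrics]:
    """Binary degrees per hospital: distinct in/out partners, their sum, and
    the net connectivity in-degree minus out-degree (positive = receiver,
    negative = distributor). Arc weights are ignored."""
    succ, pred = net.successors(), net.predecessors()
    out = []
    for vid in sorted(net.nodes):
        d_in, d_out = len(pred[vid]), len(succ[vid])
        out.append(
            NodeMetrics(
                hospital_id=vid,
                in_degree=d_in,
                out_degree=d_out,
                total_degree=d_in + d_out,
                net_connectivity=d_in - d_out,
            )
        )
    return out


# --------------------------------------------------------------------------
# Shortest-path metrics
# --------------------------------------------------------------------------

def betweenness(
    net: TransferNetwork, standardized: bool = True
) -> dict[str, float]:
    """Directed unweighted shortest-path betweenness (Brandes' accumulation).

    A node's raw betweenness sums, over ordered pairs (s, t) of *other*
    nodes, the fraction of s->t geodesics passing through it. Standardized
    betweenness divides by (N-1)(N-2) and needs N >= 3.
    """
    n = net.n_nodes
    if standardized and n < 3:
        raise ValueError("standardized betweenness needs at least 3 nodes")
    succ = net.successors()
    cb = {v: 0.0 for v in net.nodes}
    for s in net.nodes:
        # single-source shortest paths with path counts
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in net.nodes}
        sigma = {v: 0.0 for v in net.nodes}
        dist = {v: -1 for v in net.nodes}
        sigma[s], dist[s] = 1.0, 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in succ[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation
        delta = {v: 0.0 for v in net.nodes}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    if standardized:
        scale = (n - 1) * (n - 2)
        return {v: cb[v] / scale for v in cb}
    return cb


def _bfs_distances(start: str, neigh: Mapping[str, set[str]]) -> dict[str, int]:
    dist = {start: 0}
    queue = deque([start])
    while queue:
        v = queue.popleft()
        for w in neigh[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def closeness(
    net: TransferNetwork,
    direction: str = "out",
    standardized: bool = True,
    unreachable: str = "penalize",
) -> dict[str, float]:
    """Geodesic closeness: the inverse of farness, the sum of a node's
    distances to all other nodes (``direction="out"``) or from all other
    nodes (``"in"``). Standardized closeness multiplies by (N-1).

    Unreachable-target conventions:

    * ``"penalize"`` (default): a node reaching no other node scores 0;
      otherwise each unreachable target contributes distance N (one more
      than any possible geodesic).
    * ``"reachable_only"``: the Wasserman–Faust composite
      (k/(N-1)) * (k/farness_over_reached) for k reached nodes, which stays
      in [0, 1] and equals the plain standardization on strongly connected
      networks.
    """
    if direction not in ("out", "in"):
        raise ValueError("direction must be 'out' or 'in'")
    if unreachable not in ("penalize", "reachable_only"):
        raise ValueError("unknown unreachable convention")
    neigh = net.successors() if direction == "out" else net.predecessors()
    n = net.n_nodes
    out: dict[str, float] = {}
    for v in net.nodes:
        dist = _bfs_distances(v, neigh)
        reached = len(dist) - 1
        if reached == 0 or n == 1:
            out[v] = 0.0
            continue
        if unreachable == "penalize":
            farness = sum(dist.values()) + n * (n - 1 - reached)
            out[v] = (n - 1) / farness if standardized else 1.0 / farness
        else:
            farness = sum(dist.values())
            if standardized:
                out[v] = (reached / (n - 1)) * (reached / farness)
            else:
                out[v] = 1.0 / farness
    return out


def local_clustering(net: TransferNetwork) -> dict[str, float]:
    """Directed local clustering: arcs observed among a node's neighbors
    (union of in- and out-neighbors, binary) divided by the k(k-1) arcs
    possible among k neighbors. Nodes with fewer than 2 neighbors score 0."""
    succ, pred = net.successors(), net.predecessors()
    arcset = set(net.arcs)
    out: dict[str, float] = {}
    for v in net.nodes:
        nb = (succ[v] | pred[v]) - {v}
        k = len(nb)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a in nb for b in nb if a != b and (a, b) in arcset)
        out[v] = links / (k * (k - 1))
    return out


def compute_node_metrics(
    net: TransferNetwork,
    closeness_direction: str = "out",
    unreachable: str = "penalize",
) -> list[NodeMetrics]:
    """Full per-node statistic bundle (degrees + standardized centralities)."""
    nodes = degree_metrics(net)
    n = net.n_nodes
    bt = (
        betweenness(net, standardized=True)
        if n >= 3
        else {v: 0.0 for v in net.nodes}
    )
    cl = closeness(
        net, direction=closeness_direction, standardized=True,
        unreachable=unreachable,
    )
    cc = local_clustering(net)
    for nm in nodes:
        nm.betweenness_std = bt[nm.hospital_id]
        nm.closeness_std = cl[nm.hospital_id]
        nm.clustering_local = cc[nm.hospital_id]
    return nodes


# --------------------------------------------------------------------------
# Network-level statistics
# --------------------------------------------------------------------------

def in_degree_centralization(net: TransferNetwork) -> float:
    """Freeman-style in-degree centralization sum_i (d_max - d_i) / (N-1)^2;
    1 iff all arcs point at a single hub, 0 for in-regular networks."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("centralization needs at least 2 nodes")
    pred = net.predecessors()
    degs = [len(pred[v]) for v in net.nodes]
    d_max = max(degs)
    return sum(d_max - d for d in degs) / ((n - 1) ** 2)


def network_metrics(
    net: TransferNetwork,
    closeness_direction: str = "out",
    unreachable: str = "penalize",
) -> NetworkMetrics:
    """Whole-network statistic bundle: density, in-degree centralization,
    average local clustering, dyad census and dyadic reciprocity, and the
    mean/SD (sample SD) of the standardized betweenness and closeness."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("network metrics need at least 2 nodes")
    census = dyad_census(net)
    nodes = compute_node_metrics(
        net, closeness_direction=closeness_direction, unreachable=unreachable
    )
    bt = np.array([nm.betweenness_std for nm in nodes])
    cl = np.array([nm.closeness_std for nm in nodes])
    cc = np.array([nm.clustering_local for nm in nodes])
    return NetworkMetrics(
        n_nodes=n,
        n_arcs=net.n_arcs,
        density=net.n_arcs / (n * (n - 1)),
        in_degree_centralization=in_degree_centralization(net),
        avg_clustering=float(cc.mean()),
        reciprocity=census.reciprocity,
        census=census,
        betweenness_mean_sd=(float(bt.mean()), float(bt.std(ddof=1))),
        closeness_mean_sd=(float(cl.mean()), float(cl.std(ddof=1))),
    )


# --------------------------------------------------------------------------
# Secondary analyses
# --------------------------------------------------------------------------

def degree_population_regression(
    nodes: Sequence[NodeMetrics],
    registry: Iterable[Hospital] | Mapping[str, Hospital],
) -> RegressionFit:
    """OLS of in-degree on served population in millions.

    A positive slope quantifies regionalization: hubs serving larger
    populations accumulate more transfer-in partners.
    """
    idx = registry if isinstance(registry, Mapping) else registry_index(registry)
    xs, ys = [], []
    for nm in nodes:
        h = idx.get(nm.hospital_id)
        if h is not None and h.population_served is not None:
            xs.append(h.population_served / 1e6)
            ys.append(nm.in_degree)
    if len(xs) < 3:
        raise ValueError("need >= 3 hospitals with population_served")
    if np.ptp(xs) == 0:
        raise ValueError("population has zero variance")
    fit = stats.linregress(xs, ys)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_points=len(xs),
        slope_se=float(fit.stderr),
        r_value=float(fit.rvalue),
    )


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test, no continuity correction."""
    from statsmodels.stats.proportion import proportions_ztest

    if n1 <= 0 or n2 <= 0:
        raise ValueError("both groups must be non-empty")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0 if (k1 / n1 == k2 / n2) else 0.0
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


def distributor_discharge_comparison(
    records: pd.DataFrame,
    nodes: Sequence[NodeMetrics],
    quantile: float = 0.05,
) -> ProportionComparison:
    """Compare direct-discharge proportions for transfers sent by the
    strongest "distributor" hospitals versus all other transfers.

    Sender hospitals are ranked by net connectivity ascending (most negative
    = out-degree most in excess of in-degree); group A pools the transfers
    sent by the bottom-``quantile`` senders (ties at the boundary included),
    group B the rest. The outcome is disposition == discharged_outpatient
    among transfers with a non-missing disposition, compared by a two-sided
    two-proportion z-test.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    by_id = {nm.hospital_id: nm for nm in nodes}
    senders = sorted({nm.hospital_id for nm in nodes if nm.out_degree > 0})
    if not senders:
        raise ValueError("no sender hospitals in node metrics")
    values = np.array([by_id[s].net_connectivity for s in senders], dtype=float)
    cutoff = np.quantile(values, quantile)
    group_a_ids = [s for s, v in zip(senders, values) if v <= cutoff]

    df = records[records["disposition"].notna()]
    in_a = df["sender_id"].isin(group_a_ids)
    a, b = df[in_a], df[~in_a]
    if a.empty or b.empty:
        raise ValueError("one comparison group is empty")
    ka = int((a["disposition"] == "discharged_outpatient").sum())
    kb = int((b["disposition"] == "discharged_outpatient").sum())
    na, nb = len(a), len(b)
    return ProportionComparison(
        group_a_numerator=ka,
        group_a_denominator=na,
        group_b_numerator=kb,
        group_b_denominator=nb,
        percent_a=round(100.0 * ka / na, 1),
        percent_b=round(100.0 * kb / nb, 1),
        p_value=two_proportion_ztest(ka, na, kb, nb),
        group_a_hospitals=group_a_ids,
    )


def degree_distribution(
    nodes: Sequence[NodeMetrics], direction: str = "in"
) -> DegreeDistribution:
    """Histogram of in/out/total degree with its median and IQR."""
    attr = {"in": "in_degree", "out": "out_degree", "total": "total_degree"}
    if direction not in attr:
        raise ValueError("direction must be 'in', 'out' or 'total'")
    if not nodes:
        raise ValueError("empty node list")
    degs = np.array([getattr(nm, attr[direction]) for nm in nodes])
    values, counts = np.unique(degs, return_counts=True)
    q1, med, q3 = np.percentile(degs, [25, 50, 75])
    return DegreeDistribution(
        direction=direction,
        histogram=[(int(v), int(c)) for v, c in zip(values, counts)],
        median=float(med),
        iqr=(float(q1), float(q3)),
    )


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

NODE_METRIC_COLUMNS = (
    "hospital_id", "in_degree", "out_degree", "total_degree",
    "net_connectivity", "betweenness_std", "closeness_std", "clustering_local",
)


def node_metrics_frame(nodes: Sequence[NodeMetrics]) -> pd.DataFrame:
    """Per-node metrics as a DataFrame with stable column order."""
    return pd.DataFrame(
        [[getattr(nm, c) for c in NODE_METRIC_COLUMNS] for nm in nodes],
        columns=list(NODE_METRIC_COLUMNS),
    )


def network_metrics_dict(m: NetworkMetrics) -> dict:
    return {
        "n_nodes": m.n_nodes,
        "n_arcs": m.n_arcs,
        "density": m.density,
        "in_degree_centralization": m.in_degree_centralization,
        "avg_clustering": m.avg_clustering,
        "reciprocity": None if math.isnan(m.reciprocity) else m.reciprocity,
        "dyads_mutual": m.census.mutual,
        "dyads_asymmetric": m.census.asymmetric,
        "dyads_null": m.census.null_pairs,
        "betweenness_mean": m.betweenness_mean_sd[0],
        "betweenness_sd": m.betweenness_mean_sd[1],
        "closeness_mean": m.closeness_mean_sd[0],
        "closeness_sd": m.closeness_mean_sd[1],
    }


def write_network_metrics(m: NetworkMetrics, path: str | Path) -> None:
    """Write whole-network metrics as JSON (or CSV if the suffix is .csv)."""
    d = network_metrics_dict(m)
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame([d]).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")
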