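"""Directed valued transfer networks built from patient-level records.

Each hospital ED is a node; each distinct ordered sender->receiver pair is an
arc whose weight is the number of transfers it carried over the period. The
module also extracts skeleton networks (arc-weight thresholding), slices the
record stream into per-calendar-year networks, and computes the dyad census
that underlies dyadic reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class Hospital:
    """A hospital ED node with its region, hub designation and location."""

    hospital_id: str
    name: str = ""
    region_id: str = ""
    is_base: bool = False
    longitude: float = float("nan")
    latitude: float = float("nan")
    population_served: float | None = None

    def __post_init__(self):
        if not (-180.0 <= self.longitude <= 180.0) and self.longitude == self.longitude:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not (-90.0 <= self.latitude <= 90.0) and self.latitude == self.latitude:
            raise ValueError(f"latitude out of range: {self.latitude}")


@dataclass
class TransferNetwork:
    """A directed valued graph of transfer flows.

    ``arcs`` maps ordered (sender_id, receiver_id) pairs to transfer counts;
    ``nodes`` maps hospital_id to its :class:`Hospital` record. Self-loops are
    invalid and every arc endpoint must be a node.
    """

    nodes: dict[str, Hospital] = field(default_factory=dict)
    arcs: dict[tuple[str, str], int] = field(default_factory=dict)
    period_label: str = ""

    def __post_init__(self):
        for (s, r), w in self.arcs.items():
            if s == r:
                raise ValueError(f"self-loop arc {s}->{r}")
            if w < 1:
                raise ValueError(f"non-positive arc weight on {s}->{r}")
            if s not in self.nodes or r not in self.nodes:
                raise ValueError(f"arc endpoint not in node set: {s}->{r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @property
    def total_transfers(self) -> int:
        return sum(self.arcs.values())

    def successors(self) -> dict[str, set[str]]:
        """Out-neighbor sets (binary view, weights ignored)."""
        succ: dict[str, set[str]] = {v: set() for v in self.nodes}
        for s, r in self.arcs:
            succ[s].add(r)
        return succ

    def predecessors(self) -> dict[str, set[str]]:
        pred: dict[str, set[str]] = {v: set() for v in self.nodes}
        for s, r in self.arcs:
            pred[r].add(s)
        return pred

    def to_networkx(self):
        """Interop view as a networkx DiGraph (serialization/layout only)."""
        import networkx as nx

        g = nx.DiGraph()
        for vid, h in self.nodes.items():
            g.add_node(
                vid,
                name=h.name,
                region_id=h.region_id,
                is_base=h.is_base,
                longitude=h.longitude,
                latitude=h.latitude,
                population_served=(
                    float("nan") if h.population_served is None
                    else float(h.population_served)
                ),
            )
        for (s, r), w in self.arcs.items():
            g.add_edge(s, r, weight=int(w))
        return g


@dataclass(frozen=True)
class DyadCensus:
    """Counts of mutual / asymmetric / null unordered node pairs."""

    mutual: int
    asymmetric: int
    null_pairs: int

    @property
    def n_dyads(self) -> int:
        return self.mutual + self.asymmetric + self.null_pairs

    @property
    def n_arcs(self) -> int:
        """Arcs implied by the census: 2*mutual + asymmetric."""
        return 2 * self.mutual + self.asymmetric

    @property
    def reciprocity(self) -> float:
        """Dyadic reciprocity mutual/(mutual+asymmetric); NaN when no non-null dyads."""
        connected = self.mutual + self.asymmetric
        return self.mutual / connected if connected else float("nan")


# --------------------------------------------------------------------------
# Registry IO
# --------------------------------------------------------------------------

REGISTRY_COLUMNS = (
    "id", "name", "region_id", "is_base", "longitude", "latitude",
    "population_served",
)


def read_registry(path: str | Path) -> list[Hospital]:
    """Read a hospital registry CSV (columns: id, name, region_id, is_base,
    longitude, latitude, population_served)."""
    df = pd.read_csv(path, dtype={"id": "string", "region_id": "string"})
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry is missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate hospital ids in registry: {dups}")
    hospitals = []
    for row in df.itertuples(index=False):
        pop = row.population_served
        hospitals.append(
            Hospital(
                hospital_id=str(row.id),
                name="" if pd.isna(row.name) else str(row.name),
                region_id=str(row.region_id),
                is_base=bool(int(row.is_base)),
                longitude=float(row.longitude),
                latitude=float(row.latitude),
                population_served=None if pd.isna(pop) else float(pop),
            )
        )
    return hospitals


def write_registry(hospitals: Iterable[Hospital], path: str | Path) -> None:
    rows = [
        (
            h.hospital_id, h.name, h.region_id, int(h.is_base),
            h.longitude, h.latitude,
            "" if h.population_served is None else h.population_served,
        )
        for h in hospitals
    ]
    pd.DataFrame(rows, columns=list(REGISTRY_COLUMNS)).to_csv(path, index=False)


def registry_index(registry: Iterable[Hospital]) -> dict[str, Hospital]:
    idx: dict[str, Hospital] = {}
    for h in registry:
        if h.hospital_id in idx:
            raise ValueError(f"duplicate hospital id {h.hospital_id!r}")
        idx[h.hospital_id] = h
    return idx


# --------------------------------------------------------------------------
# Network construction
# --------------------------------------------------------------------------

def build_network(
    records: pd.DataFrame,
    registry: Iterable[Hospital] | Mapping[str, Hospital],
    period: tuple | None = None,
    *,
    include_isolates: bool = False,
    lenient: bool = False,
    period_label: str = "",
) -> TransferNetwork:
    """Aggregate transfer records into a directed valued network.

    Each distinct ordered sender->receiver pair becomes one arc with weight
    equal to the number of matching records. By default the node set keeps
    only hospitals incident to at least one arc; ``include_isolates=True``
    keeps the whole registry (density-denominator sensitivity checks).

    ``period`` is an optional (start, end) pair filtering on the departure
    timestamp (start inclusive, end exclusive). Unresolvable hospital ids
    raise unless ``lenient=True``, in which case those records are dropped.
    """
    idx = registry if isinstance(registry, Mapping) else registry_index(registry)
    df = records
    if period is not None:
        start, end = period
        depart = pd.to_datetime(df["depart_datetime"])
        mask = pd.Series(True, index=df.index)
        if start is not None:
            mask &= depart >= pd.Timestamp(start)
        if end is not None:
            mask &= depart < pd.Timestamp(end)
        df = df[mask]

    known = df["sender_id"].isin(idx) & df["receiver_id"].isin(idx)
    if not known.all():
        offenders = sorted(
            set(df.loc[~df["sender_id"].isin(idx), "sender_id"])
            | set(df.loc[~df["receiver_id"].isin(idx), "receiver_id"])
        )
        if not lenient:
            raise KeyError(f"hospital ids not in registry: {offenders}")
        df = df[known]

    pair_counts = df.groupby(["sender_id", "receiver_id"], sort=True).size()
    arcs = {(str(s), str(r)): int(w) for (s, r), w in pair_counts.items()}

    if include_isolates:
        nodes = dict(idx)
    else:
        incident = {v for pair in arcs for v in pair}
        nodes = {v: idx[v] for v in sorted(incident)}
    return TransferNetwork(nodes=nodes, arcs=arcs, period_label=period_label)


def extract_skeleton(
    net: TransferNetwork, min_weight: int, max_weight: int | None = None
) -> TransferNetwork:
    """Keep arcs with min_weight <= weight (<= max_weight when given).

    Nodes incident to at least one surviving arc are retained; isolates are
    dropped. The skeleton view at >= 36 transfers per 3 years (>= 1/month)
    separates robust referral relationships from incidental ones; a 36..365
    band gives "medium" ties and > 365 "strong" ties.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    if max_weight is not None and max_weight < min_weight:
        raise ValueError("max_weight must be >= min_weight")
    arcs = {
        pair: w
        for pair, w in net.arcs.items()
        if w >= min_weight and (max_weight is None or w <= max_weight)
    }
    incident = {v for pair in arcs for v in pair}
    nodes = {v: net.nodes[v] for v in sorted(incident)}
    label = f"{net.period_label} skeleton>={min_weight}".strip()
    if max_weight is not None:
        label += f"<={max_weight}"
    return TransferNetwork(nodes=nodes, arcs=arcs, period_label=label)


def dyad_census(net: TransferNetwork) -> DyadCensus:
    """Census of unordered node pairs: mutual (arcs both ways), asymmetric
    (exactly one arc), null (no arc). Satisfies mutual+asym+null = N(N-1)/2
    and 2*mutual+asym = number of arcs."""
    directions: dict[tuple[str, str], int] = {}
    for s, r in net.arcs:
        key = (s, r) if s < r else (r, s)
        directions[key] = directions.get(key, 0) + 1
    mutual = sum(1 for n in directions.values() if n == 2)
    asymmetric = sum(1 for n in directions.values() if n == 1)
    n = net.n_nodes
    null_pairs = n * (n - 1) // 2 - mutual - asymmetric
    return DyadCensus(mutual=mutual, asymmetric=asymmetric, null_pairs=null_pairs)


def slice_by_year(
    records: pd.DataFrame,
    registry: Iterable[Hospital] | Mapping[str, Hospital],
    **kwargs,
) -> dict[int, TransferNetwork]:
    """One network per calendar year of departure (temporal-trend layer)."""
    idx = registry if isinstance(registry, Mapping) else registry_index(registry)
    years = pd.to_datetime(records["depart_datetime"]).dt.year
    out: dict[int, TransferNetwork] = {}
    for year in sorted(years.dropna().unique()):
        out[int(year)] = build_network(
            records[years == year], idx, period_label=str(int(year)), **kwargs
        )
    return out


# --------------------------------------------------------------------------
# Network IO
# --------------------------------------------------------------------------

def write_edgelist(net: TransferNetwork, path: str | Path) -> None:
    """Weighted edge list CSV (sender, receiver, weight), sorted; bit-exact
    round trip with :func:`read_edgelist` for the same registry."""
    rows = sorted((s, r, w) for (s, r), w in net.arcs.items())
    pd.DataFrame(rows, columns=["sender", "receiver", "weight"]).to_csv(
        path, index=False
    )


def read_edgelist(
    path: str | Path,
    registry: Iterable[Hospital] | Mapping[str, Hospital] | None = None,
    period_label: str = "",
) -> TransferNetwork:
    """Read a weighted edge-list CSV. Without a registry, minimal Hospital
    stubs are created for each incident id."""
    df = pd.read_csv(path, dtype={"sender": "string", "receiver": "string"})
    missing = {"sender", "receiver", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    arcs = {
        (str(row.sender), str(row.receiver)): int(row.weight)
        for row in df.itertuples(index=False)
    }
    incident = sorted({v for pair in arcs for v in pair})
    if registry is None:
        nodes = {v: Hospital(hospital_id=v) for v in incident}
    else:
        idx = registry if isinstance(registry, Mapping) else registry_index(registry)
        nodes = {v: idx[v] for v in incident}
    return TransferNetwork(nodes=nodes, arcs=arcs, period_label=period_label)


def write_graphml(net: TransferNetwork, path: str | Path) -> None:
    """GraphML export with node attributes (networkx-backed)."""
    import networkx as nx

    nx.write_graphml(net.to_networkx(), str(path))


def read_graphml(path: str | Path, period_label: str = "") -> TransferNetwork:
    import networkx as nx

    g = nx.read_graphml(str(path))
    nodes = {}
    for vid, data in g.nodes(data=True):
        pop = data.get("population_served", float("nan"))
        nodes[str(vid)] = Hospital(
            hospital_id=str(vid),
            name=data.get("name", ""),
            region_id=data.get("region_id", ""),
            is_base=bool(data.get("is_base", False)),
            longitude=float(data.get("longitude", float("nan"))),
            latitude=float(data.get("latitude", float("nan"))),
            population_served=None if pop != pop else float(pop),
        )
    arcs = {
        (str(s), str(r)): int(d.get("weight", 1)) for s, r, d in g.edges(data=True)
    }
    return TransferNetwork(nodes=nodes, arcs=arcs, period_label=period_label)
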