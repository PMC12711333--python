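"""IBD-sharing network: construction, de-noising, communities, topology.

Per-pair IBD segment lists are condensed into summaries (segment counts
above length thresholds, longest segment, summed length of segments
> 12 cM).  The relatedness graph connects individuals sharing at least one
segment of ``min_edge_cM`` (default 9 cM), drops edges between individuals
whose dates differ by more than ``max_year_gap`` (default 600 years), then
drops nodes of degree < ``min_degree`` (default 2) in a single pass.  Edge
weight is the longest shared segment; the summed length of > 12 cM segments
is carried as an auxiliary weight for module-strength statistics.
Communities are found with the Leiden algorithm on the weighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import igraph as ig
import leidenalg

from .metadata import IndividualRecord
from .pedigree import IBDSegment

DEFAULT_THRESHOLDS = (8.0, 9.0, 12.0)

# Approximate expected sum of >12 cM IBD (cM) by meiotic distance, Monte-Carlo
# derived from the pedigree simulator on the default 3545.4 cM map
# (400 replicates per distance, ancestor-descendant chains; collateral
# relatives with two common ancestors share about twice these amounts, hence
# the class bounds below are geometric midpoints and the labels "approximate").
_EXPECTED_SUM_GT12 = {
    1: 3545.0, 2: 1748.0, 3: 851.0, 4: 408.0,
    5: 199.0, 6: 96.0, 7: 43.0, 8: 21.0,
}

DEGREE_CLASS_LABELS = {
    1: "1st", 2: "2nd", 3: "3rd", 4: "4th", 5: "5th", 6: "6th", 7: "7th", 8: "8th",
}


def degree_class(sum_gt12_cm: float) -> str:
    """Coarse relatedness-degree class from summed > 12 cM IBD (approximate).

    Degree here is meiotic distance minus one for ancestor-descendant chains
    (parent-child = 1st degree); boundaries are geometric midpoints between
    the expected sums of adjacent distances.
    """
    ms = sorted(_EXPECTED_SUM_GT12)
    for m in ms:
        lo = np.sqrt(
            _EXPECTED_SUM_GT12[m] * _EXPECTED_SUM_GT12.get(m + 1, _EXPECTED_SUM_GT12[m] / 4)
        )
        if sum_gt12_cm >= lo:
            return DEGREE_CLASS_LABELS[m]
    return "distant"


@dataclass
class PairIBDSummary:
    """Per-pair IBD aggregates."""

    pair: tuple[str, str]
    n_ge: dict[float, int]
    max_cm: float
    sum_gt12_cm: float

    def __post_init__(self) -> None:
        ts = sorted(self.n_ge)
        for lo, hi in zip(ts, ts[1:]):
            if self.n_ge[lo] < self.n_ge[hi]:
                raise ValueError("segment counts must be non-increasing in threshold")


@dataclass
class Partition:
    """Community assignment plus its quality (weighted modularity)."""

    membership: dict[str, int]
    quality: float
    resolution: float = 1.0
    seed: int = 0

    @property
    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, com in self.membership.items():
            out.setdefault(com, []).append(node)
        return {k: sorted(v) for k, v in out.items()}


def summarize_pairs(
    segments: list[IBDSegment],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> list[PairIBDSummary]:
    """Aggregate segments into one summary per unordered pair.

    Counts are of segments with length >= t for each threshold t; the sum is
    over segments strictly longer than 12 cM.
    """
    by_pair: dict[tuple[str, str], list[float]] = {}
    for s in segments:
        if s.length_cm <= 0:
            raise ValueError(
                f"non-positive segment length {s.length_cm} for pair ({s.iid1}, {s.iid2})"
            )
        key = tuple(sorted((s.iid1, s.iid2)))
        by_pair.setdefault(key, []).append(s.length_cm)
    out = []
    for pair in sorted(by_pair):
        lens = np.asarray(by_pair[pair])
        out.append(
            PairIBDSummary(
                pair=pair,
                n_ge={t: int((lens >= t).sum()) for t in thresholds},
                max_cm=float(lens.max()),
                sum_gt12_cm=float(lens[lens > 12.0].sum()),
            )
        )
    return out


def build_graph(
    pairs: list[PairIBDSummary],
    meta: list[IndividualRecord],
    min_edge_cm: float = 9.0,
    max_year_gap: float = 600.0,
    min_degree: int = 2,
    temporal_mode: str = "midpoint",
) -> nx.Graph:
    """De-noised IBD-sharing graph.

    Filters, in this fixed order: (1) an edge exists iff the pair shares at
    least one segment >= ``min_edge_cm``; (2) edges whose endpoints are
    separated in time by more than ``max_year_gap`` years are dropped
    (``temporal_mode`` = "midpoint": absolute difference of date-interval
    midpoints; "gap": gap between the intervals themselves); (3) nodes of
    degree < ``min_degree`` are dropped in a single pass.  All surviving
    components are retained; use :func:`largest_component` separately.
    """
    records = {r.id: r for r in meta}
    g = nx.Graph()
    counts = {"pairs_in": len(pairs)}
    for p in pairs:
        a, b = p.pair
        for iid in (a, b):
            if iid not in records:
                raise ValueError(f"individual {iid!r} in IBD pairs but not in metadata")
        if a == b:
            continue
        if p.max_cm < min_edge_cm:
            continue
        g.add_edge(
            a, b,
            weight=p.max_cm,
            max_cm=p.max_cm,
            sum_gt12_cm=p.sum_gt12_cm,
            n_ge12=p.n_ge.get(12.0, int(p.max_cm >= 12.0)),
        )
    counts["edges_after_segment_filter"] = g.number_of_edges()

    def year_gap(a: str, b: str) -> float:
        ra, rb = records[a], records[b]
        if temporal_mode == "midpoint":
            return abs(ra.date_mid - rb.date_mid)
        if temporal_mode == "gap":
            return max(ra.date_lo - rb.date_hi, rb.date_lo - ra.date_hi, 0)
        raise ValueError(f"unknown temporal_mode {temporal_mode!r}")

    too_far = [(a, b) for a, b in g.edges if year_gap(a, b) > max_year_gap]
    g.remove_edges_from(too_far)
    counts["edges_after_temporal_filter"] = g.number_of_edges()
    counts["nodes_after_temporal_filter"] = g.number_of_nodes()

    low = [n for n in g.nodes if g.degree(n) < min_degree]
    g.remove_nodes_from(low)
    counts["nodes_after_degree_filter"] = g.number_of_nodes()
    counts["edges_after_degree_filter"] = g.number_of_edges()

    for n in g.nodes:
        r = records[n]
        g.nodes[n]["group"] = r.group
        g.nodes[n]["date_mid"] = r.date_mid
        if r.latitude is not None:
            g.nodes[n]["lat"] = r.latitude
        if r.longitude is not None:
            g.nodes[n]["lon"] = r.longitude
    g.graph["filter_counts"] = counts
    g.graph["min_edge_cm"] = min_edge_cm
    g.graph["max_year_gap"] = max_year_gap
    g.graph["min_degree"] = min_degree
    return g


def largest_component(g: nx.Graph) -> nx.Graph:
    """Subgraph on the component with the most nodes.

    Ties break toward the component containing the lexicographically
    smallest node id.  An empty graph is returned unchanged.
    """
    if g.number_of_nodes() == 0:
        return g.copy()
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(comps[0]).copy()


def detect_communities(
    g: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> Partition:
    """Leiden communities on max-segment edge weights.

    Uses the RB-configuration quality function, which coincides with
    weighted modularity at resolution 1.0.  Deterministic given ``seed``.
    The reported quality is the weighted Newman modularity of the partition.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in g.edges]
    weights = [float(g.edges[a, b].get("weight", 1.0)) for a, b in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges)
    part = leidenalg.find_partition(
        h,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,  # iterate to convergence
    )
    membership = {nodes[i]: int(c) for i, c in enumerate(part.membership)}
    if g.number_of_edges() > 0:
        comms: dict[int, set] = {}
        for n, c in membership.items():
            comms.setdefault(c, set()).add(n)
        quality = nx.community.modularity(g, comms.values(), weight="weight")
    else:
        quality = 0.0
    return Partition(membership=membership, quality=float(quality),
                     resolution=resolution, seed=seed)


def node_metrics(g: nx.Graph, partition: Partition | dict[str, object]) -> pd.DataFrame:
    """Per-node degree split and clustering coefficient.

    k = unweighted degree; kW = edges to same-module nodes; kB = k - kW;
    clustering coefficient = unweighted local transitivity (0 for degree
    < 2).  ``partition`` may be a Partition or any node -> module mapping.
    """
    member = partition.membership if isinstance(partition, Partition) else dict(partition)
    for n in g.nodes:
        if n not in member:
            raise ValueError(f"node {n!r} missing from partition")
    cc = nx.clustering(g)  # unweighted
    rows = []
    for n in sorted(g.nodes):
        nbrs = list(g.neighbors(n))
        kw = sum(1 for m in nbrs if member[m] == member[n])
        rows.append(
            {
                "id": n, "module": member[n], "k": len(nbrs),
                "kW": kw, "kB": len(nbrs) - kw, "cc": cc[n],
            }
        )
    return pd.DataFrame(rows)


def module_metrics(
    g: nx.Graph,
    modules: Partition | dict[str, object],
    link_weight: str = "sum_gt12_cm",
) -> pd.DataFrame:
    """Per-module strength and clustering summaries.

    Within-strength sums ``link_weight`` over intra-module edges;
    between-strength over inter-module edges, attributed to both endpoint
    modules.  Average IBD per link is strength / link count, NaN when a
    module has no links of that kind.  Modules may come from a Partition or
    from predefined group labels.
    """
    member = modules.membership if isinstance(modules, Partition) else dict(modules)
    for n in g.nodes:
        if n not in member:
            raise ValueError(f"node {n!r} missing from module assignment")
    cc = nx.clustering(g)
    mods = sorted(set(member[n] for n in g.nodes), key=str)
    within_s = {m: 0.0 for m in mods}
    within_n = {m: 0 for m in mods}
    between_s = {m: 0.0 for m in mods}
    between_n = {m: 0 for m in mods}
    for a, b, data in g.edges(data=True):
        w = float(data.get(link_weight, 0.0))
        ma, mb = member[a], member[b]
        if ma == mb:
            within_s[ma] += w
            within_n[ma] += 1
        else:
            for m in (ma, mb):
                between_s[m] += w
                between_n[m] += 1
    rows = []
    for m in mods:
        members = [n for n in g.nodes if member[n] == m]
        rows.append(
            {
                "module": m,
                "size": len(members),
                "mean_cc": float(np.mean([cc[n] for n in members])),
                "within_strength": within_s[m],
                "between_strength": between_s[m],
                "n_within_links": within_n[m],
                "n_between_links": between_n[m],
                "avg_ibd_within": within_s[m] / within_n[m] if within_n[m] else np.nan,
                "avg_ibd_between": between_s[m] / between_n[m] if between_n[m] else np.nan,
            }
        )
    return pd.DataFrame(rows)


def flag_relative_pairs(
    pairs: list[PairIBDSummary],
    min_segments: int = 3,
    seg_threshold: float = 12.0,
) -> pd.DataFrame:
    """Flag pairs indicating close biological relatedness.

    Default rule: at least ``min_segments`` = 3 segments of length >=
    ``seg_threshold`` (i.e. strictly more than two 12 cM segments); set
    ``min_segments=2`` for the laxer variant.  Each flagged pair carries an
    approximate degree class looked up from the expected summed > 12 cM IBD
    per meiotic distance (simulator-derived constants).
    """
    if min_segments < 1 or seg_threshold <= 0:
        raise ValueError("thresholds must be positive")
    rows = []
    for p in pairs:
        if seg_threshold in p.n_ge:
            n_above = p.n_ge[seg_threshold]
        else:
            raise ValueError(
                f"pair summaries lack counts at threshold {seg_threshold}; "
                f"available: {sorted(p.n_ge)}"
            )
        if n_above >= min_segments:
            rows.append(
                {
                    "iid1": p.pair[0],
                    "iid2": p.pair[1],
                    "n_segments": n_above,
                    "max_cM": p.max_cm,
                    "sum_gt12_cM": p.sum_gt12_cm,
                    "degree_class": degree_class(p.sum_gt12_cm),
                }
            )
    return pd.DataFrame(
        rows, columns=["iid1", "iid2", "n_segments", "max_cM", "sum_gt12_cM", "degree_class"]
    )


# ---------------------------------------------------------------------------
# export / import


def export_graph(
    g: nx.Graph,
    partition: Partition | None,
    out_dir: str | Path,
    stem: str = "ibd_network",
) -> dict[str, Path]:
    """Write GEXF plus round-trippable node/edge CSVs.

    The GEXF carries group, date midpoint, community and edge weights for
    external force-directed layout tools.  Output bytes are deterministic
    (no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gg = g.copy()
    member = partition.membership if partition else {}
    for n in gg.nodes:
        gg.nodes[n]["community"] = int(member.get(n, -1))

    gexf_path = out_dir / f"{stem}.gexf"
    xml = "\n".join(nx.generate_gexf(gg))
    import re

    xml = re.sub(r'lastmodifieddate="[^"]*"', 'lastmodifieddate="1970-01-01"', xml)
    gexf_path.write_text(xml + "\n")

    nodes_path = out_dir / f"{stem}_nodes.csv"
    edges_path = out_dir / f"{stem}_edges.csv"
    nodes = pd.DataFrame(
        [
            {
                "id": n,
                "group": gg.nodes[n].get("group", ""),
                "date_mid": gg.nodes[n].get("date_mid", np.nan),
                "community": gg.nodes[n]["community"],
            }
            for n in sorted(gg.nodes)
        ]
    )
    nodes.to_csv(nodes_path, index=False)
    edges = pd.DataFrame(
        [
            {
                "iid1": min(a, b),
                "iid2": max(a, b),
                "max_cM": d.get("max_cm", d.get("weight", np.nan)),
                "sum_gt12_cM": d.get("sum_gt12_cm", 0.0),
                "n_ge12": d.get("n_ge12", 0),
            }
            for a, b, d in gg.edges(data=True)
        ],
        columns=["iid1", "iid2", "max_cM", "sum_gt12_cM", "n_ge12"],
    ).sort_values(["iid1", "iid2"])
    edges.to_csv(edges_path, index=False)
    return {"gexf": gexf_path, "nodes": nodes_path, "edges": edges_path}


def import_graph(nodes_csv: str | Path, edges_csv: str | Path) -> nx.Graph:
    """Rebuild a graph from the CSV pair written by :func:`export_graph`."""
    nodes = pd.read_csv(nodes_csv, dtype={"id": str, "group": str})
    edges = pd.read_csv(edges_csv, dtype={"iid1": str, "iid2": str})
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.id, group=row.group, date_mid=float(row.date_mid),
                   community=int(row.community))
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.iid1, row.iid2,
            weight=float(row.max_cM), max_cm=float(row.max_cM),
            sum_gt12_cm=float(row.sum_gt12_cM), n_ge12=int(row.n_ge12),
        )
    return g
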