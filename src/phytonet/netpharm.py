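"""Network-pharmacology core: target intersection, PPI construction,
centralities and the two-tier median hub screen.

The hub screen mirrors standard practice for STRING-derived PPI networks:
edges are kept above a confidence threshold, degree (DC), betweenness (BC)
and closeness (CC) centralities are computed on the unweighted simple graph,
a first filter keeps nodes with DC at least a multiple (default 2x) of the
median degree, and a second filter - run on centralities recomputed on the
surviving subnetwork - keeps nodes at or above the median of all three
metrics, ranked by degree.

Centrality conventions (fixed by the magnitudes such screens report):
betweenness is the raw Brandes pair count (each unordered pair counted once,
endpoints excluded, no normalization); closeness is normalized to [0, 1]
using the component-size correction, so it equals (n-1)/sum(d) on a
connected graph; shortest paths ignore edge confidence.
"""
from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParseError, ValidationError

__all__ = [
    "TargetMapping",
    "VennCounts",
    "intersect_targets",
    "build_network",
    "centralities",
    "Tier1Result",
    "HubScreenResult",
    "tier1_screen",
    "tier2_screen",
    "hub_screen",
    "apply_centrality_thresholds",
    "BipartiteCT",
    "CompoundRanking",
    "ct_degree_rank",
    "DEFAULT_MIN_CONFIDENCE",
]

#: STRING-style default interaction confidence threshold.
DEFAULT_MIN_CONFIDENCE = 0.4


# ---------------------------------------------------------------------------
# target mapping and intersection
# ---------------------------------------------------------------------------

@dataclass
class TargetMapping:
    """Compound -> predicted-target sets plus a disease gene set.

    Gene symbols are uppercased and deduplicated on construction.
    """

    compound_targets: dict[str, set[str]]
    disease_genes: set[str]

    def __post_init__(self):
        self.compound_targets = {
            c: {str(g).strip().upper() for g in genes}
            for c, genes in self.compound_targets.items()}
        self.disease_genes = {str(g).strip().upper()
                              for g in self.disease_genes}

    @property
    def compound_union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.compound_targets.values():
            out |= genes
        return out


@dataclass(frozen=True)
class VennCounts:
    compound_union: int
    disease: int
    overlap: int
    overlap_genes: frozenset[str]


def intersect_targets(mapping: TargetMapping) -> VennCounts:
    """Venn intersection of the pooled compound targets with the disease
    gene set."""
    union = mapping.compound_union
    disease = mapping.disease_genes
    if not union or not disease:
        raise ValidationError("compound union and disease set must be non-empty")
    overlap = union & disease
    return VennCounts(len(union), len(disease), len(overlap),
                      frozenset(overlap))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _iter_edges(edges) -> list[tuple[str, str, float]]:
    if isinstance(edges, (str, Path)):
        from .io import read_edge_list
        return read_edge_list(edges)
    if isinstance(edges, pd.DataFrame):
        if edges.shape[1] < 3:
            raise ParseError("edge table needs columns (node1, node2, score)")
        return [(str(u), str(v), float(s))
                for u, v, s in edges.iloc[:, :3].itertuples(index=False)]
    out = []
    for i, row in enumerate(edges, start=1):
        try:
            u, v, s = row
            out.append((str(u), str(v), float(s)))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed edge row {row!r}: {exc}", line=i)
    return out


def build_network(edges, min_confidence: float = DEFAULT_MIN_CONFIDENCE,
                  strict: bool = True, nodes: Iterable[str] | None = None,
                  largest_component: bool = False) -> nx.Graph:
    """Build a confidence-filtered, simple, undirected PPI graph.

    Scores on the STRING 0-1000 integer dialect are auto-detected (any score
    above 1) and rescaled to [0, 1]. Edges must exceed ``min_confidence``
    strictly (``strict=False`` switches to >=). Self-loops are dropped,
    parallel edges keep the highest confidence, and isolated nodes are
    removed; ``largest_component=True`` additionally restricts to the
    largest connected component.
    """
    rows = _iter_edges(edges)
    scores = [s for _, _, s in rows]
    string_dialect = any(s > 1.0 for s in scores)
    g = nx.Graph()
    for i, (u, v, s) in enumerate(rows, start=1):
        conf = s / 1000.0 if string_dialect else s
        if not 0.0 <= conf <= 1.0:
            raise ParseError(f"confidence {s} outside the [0, 1] / 0-1000 "
                             "conventions", line=i)
        if u == v:
            continue
        keep = conf > min_confidence if strict else conf >= min_confidence
        if not keep:
            continue
        if g.has_edge(u, v):
            g[u][v]["confidence"] = max(g[u][v]["confidence"], conf)
        else:
            g.add_edge(u, v, confidence=conf)
    if nodes is not None:
        g.add_nodes_from(str(n) for n in nodes)
    g.remove_nodes_from(list(nx.isolates(g)))
    if largest_component and g.number_of_nodes():
        keep = max(nx.connected_components(g), key=len)
        g = g.subgraph(keep).copy()
    return g


# ---------------------------------------------------------------------------
# centralities (from scratch; unweighted shortest paths)
# ---------------------------------------------------------------------------

def _bfs(adj: Mapping, s) -> tuple[list, dict, dict, dict]:
    """Single-source BFS returning visit order, predecessors on shortest
    paths, path counts and distances (Brandes' forward phase)."""
    order = []
    pred = {s: []}
    sigma = {s: 1.0}
    dist = {s: 0}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                pred[w] = []
                sigma[w] = 0.0
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                pred[w].append(v)
    return order, pred, sigma, dist


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness centralities of every node.

    Returns a DataFrame indexed by node with columns ``dc`` (integer
    degree), ``bc`` (raw shortest-path pair counts, Brandes accumulation,
    endpoints excluded, each unordered pair once) and ``cc`` (closeness in
    [0, 1], component-corrected). Edge confidence plays no role in path
    lengths.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    nodes = sorted(net.nodes)
    adj = {v: sorted(net.neighbors(v)) for v in nodes}
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    cc = {}
    for s in nodes:
        order, pred, sigma, dist = _bfs(adj, s)
        # closeness from this source's distances
        reach = len(dist) - 1
        total = sum(dist.values())
        if reach > 0 and total > 0:
            cc[s] = (reach / total) * (reach / (n - 1)) if n > 1 else 0.0
        else:
            cc[s] = 0.0
        # Brandes backward accumulation
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w is not s:
                bc[w] += delta[w]
    table = pd.DataFrame({
        "dc": [net.degree(v) for v in nodes],
        "bc": [bc[v] / 2.0 for v in nodes],  # unordered pairs counted once
        "cc": [cc[v] for v in nodes],
    }, index=pd.Index(nodes, name="node"))
    return table


# ---------------------------------------------------------------------------
# two-tier hub screen
# ---------------------------------------------------------------------------

@dataclass
class Tier1Result:
    """Degree pre-filter outcome: realized threshold and induced subnetwork."""

    multiplier: float
    median_dc: float
    threshold: float
    network: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.network.nodes)


def tier1_screen(net: nx.Graph, multiplier: float = 2.0,
                 table: pd.DataFrame | None = None) -> Tier1Result:
    """First filtration: keep nodes with DC >= multiplier * median(DC).

    The subgraph induced on the survivors is returned with nodes isolated by
    the induction removed. ``multiplier=0`` is the identity filter. If every
    node is filtered an empty network is returned with a warning.
    """
    if multiplier < 0:
        raise ConfigurationError("multiplier must be non-negative")
    if table is None:
        table = centralities(net)
    median_dc = float(np.median(table["dc"]))
    threshold = multiplier * median_dc
    keep = table.index[table["dc"] >= threshold]
    sub = net.subgraph(keep).copy()
    if multiplier > 0:
        sub.remove_nodes_from(list(nx.isolates(sub)))
    if sub.number_of_nodes() == 0:
        warnings.warn("tier-1 screen removed every node", stacklevel=2)
    return Tier1Result(multiplier=multiplier, median_dc=median_dc,
                       threshold=threshold, network=sub)


def _rank_core(table: pd.DataFrame) -> pd.DataFrame:
    # DC descending, ties by BC descending, then node name
    return table.sort_values(["dc", "bc", "node"],
                             ascending=[False, False, True],
                             kind="stable").set_index("node")


@dataclass
class HubScreenResult:
    """Two-tier hub-screen outcome.

    ``core`` is ranked by degree (ties by betweenness, then name); thresholds
    are recorded exactly as applied. Tier-1 fields are ``None`` when the
    second tier was run on an externally supplied subnetwork.
    """

    bc_min: float
    cc_min: float
    dc_min: float
    core: pd.DataFrame
    subnetwork: nx.Graph
    tier1: Tier1Result | None = None

    @property
    def core_nodes(self) -> list[str]:
        return list(self.core.index)


def apply_centrality_thresholds(table: pd.DataFrame, bc_min: float,
                                cc_min: float, dc_min: float) -> pd.DataFrame:
    """Retain rows with BC, CC and DC all at or above the given thresholds,
    ranked by DC descending (ties by BC, then node name)."""
    t = table.reset_index()
    if "node" not in t.columns:
        t = t.rename(columns={t.columns[0]: "node"})
    kept = t[(t["bc"] >= bc_min) & (t["cc"] >= cc_min) & (t["dc"] >= dc_min)]
    return _rank_core(kept)


def tier2_screen(subnet: nx.Graph,
                 tier1: Tier1Result | None = None) -> HubScreenResult:
    """Second filtration: recompute centralities on the subnetwork and keep
    nodes at or above the median of BC, CC and DC simultaneously."""
    if subnet.number_of_nodes() < 2:
        raise ValidationError("tier-2 screen needs at least 2 nodes")
    table = centralities(subnet)
    bc_min = float(np.median(table["bc"]))
    cc_min = float(np.median(table["cc"]))
    dc_min = float(np.median(table["dc"]))
    core = apply_centrality_thresholds(table, bc_min, cc_min, dc_min)
    return HubScreenResult(bc_min=bc_min, cc_min=cc_min, dc_min=dc_min,
                           core=core, subnetwork=subnet, tier1=tier1)


def hub_screen(net: nx.Graph, multiplier: float = 2.0) -> HubScreenResult:
    """Full two-tier screen: degree pre-filter, then the three-way median
    filter on centralities recomputed on the surviving subnetwork."""
    t1 = tier1_screen(net, multiplier=multiplier)
    return tier2_screen(t1.network, tier1=t1)


# ---------------------------------------------------------------------------
# compound-target bipartite ranking
# ---------------------------------------------------------------------------

@dataclass
class BipartiteCT:
    """Unweighted compound-target bipartite network."""

    compound_targets: dict[str, set[str]]

    def __post_init__(self):
        self.compound_targets = {str(c): {str(t) for t in ts}
                                 for c, ts in self.compound_targets.items()}

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "BipartiteCT":
        out: dict[str, set[str]] = {}
        for c, t in pairs:
            out.setdefault(str(c), set()).add(str(t))
        return cls(out)

    @property
    def degrees(self) -> dict[str, int]:
        return {c: len(ts) for c, ts in self.compound_targets.items()}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for c, ts in self.compound_targets.items():
            g.add_node(c, bipartite="compound")
            for t in ts:
                g.add_node(t, bipartite="target")
                g.add_edge(c, t)
        return g


@dataclass
class CompoundRanking:
    """Compound degree ranking with its median cutoff and core list."""

    ranked: pd.DataFrame
    cutoff: float

    @property
    def core(self) -> list[str]:
        return list(self.ranked.index[self.ranked["is_core"]])


def ct_degree_rank(bip: BipartiteCT | Mapping[str, int] | pd.Series,
                   ) -> CompoundRanking:
    """Rank compounds by target degree and keep those at or above the median.

    Accepts a :class:`BipartiteCT` (degree = number of distinct targets) or a
    precomputed name -> degree mapping. Ranking is degree descending with
    ties broken by name.
    """
    if isinstance(bip, BipartiteCT):
        degrees = bip.degrees
    elif isinstance(bip, pd.Series):
        degrees = bip.to_dict()
    else:
        degrees = dict(bip)
    if not degrees or sum(degrees.values()) == 0:
        raise ValidationError("bipartite network has no edges")
    cutoff = float(np.median(list(degrees.values())))
    df = (pd.DataFrame({"degree": pd.Series(degrees)})
          .rename_axis("compound")
          .reset_index()
          .sort_values(["degree", "compound"], ascending=[False, True],
                       kind="stable")
          .set_index("compound"))
    df["is_core"] = df["degree"] >= cutoff
    df["rank"] = np.arange(1, len(df) + 1)
    return CompoundRanking(ranked=df, cutoff=cutoff)
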