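"""Interaction-network construction, filtering and module detection.

Builds a gene network from a STRING-style scored edge table, prunes it by
evidence scores and pairwise co-expression, checks scale-free topology of
the largest connected component, extracts the top-degree hub neighbourhood
and detects overlapping communities by k-clique percolation at the highest
percolating k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedFitError, ValidationError
from .expression import ExpressionMatrix


def filter_string_edges(
    edge_table: pd.DataFrame,
    textmining_min: float = 200,
    combined_min: float = 400,
    gene_universe=None,
) -> nx.Graph:
    """Build a simple undirected graph from a scored edge table.

    Keeps edges with textmining score strictly above ``textmining_min`` AND
    combined score strictly above ``combined_min`` AND both endpoints inside
    ``gene_universe`` (when given).  Malformed rows (missing fields,
    non-numeric scores, self-loops) are skipped and counted in
    ``G.graph["n_malformed"]``.
    """
    required = ("geneA", "geneB", "textmining", "combined")
    missing = [c for c in required if c not in edge_table.columns]
    if missing:
        raise ValidationError(f"edge table missing column(s) {missing}")
    universe = set(gene_universe) if gene_universe is not None else None

    G = nx.Graph(n_malformed=0)
    if universe is not None:
        G.add_nodes_from(sorted(universe))
    for row in edge_table.itertuples(index=False):
        a, b = str(row.geneA), str(row.geneB)
        try:
            tm = float(row.textmining)
            comb = float(row.combined)
        except (TypeError, ValueError):
            G.graph["n_malformed"] += 1
            continue
        if not a or not b or a == b or np.isnan(tm) or np.isnan(comb):
            G.graph["n_malformed"] += 1
            continue
        if tm <= textmining_min or comb <= combined_min:
            continue
        if universe is not None and (a not in universe or b not in universe):
            continue
        G.add_edge(a, b, textmining=tm, combined=comb)
    return G


def filter_edges_by_coexpression(
    graph: nx.Graph,
    expr: ExpressionMatrix,
    rho_min: float = 0.5,
    missing: str = "error",
) -> nx.Graph:
    """Keep edges whose endpoint genes co-express with |Spearman rho| >= rho_min.

    The correlation is stored on each surviving edge as ``coexpression_rho``.
    ``missing`` controls nodes absent from the matrix: ``"error"`` raises,
    ``"drop"`` removes their edges.
    """
    if missing not in ("error", "drop"):
        raise ValidationError("missing must be 'error' or 'drop'")
    present = set(expr.gene_ids)
    absent = [n for n in graph.nodes if n not in present]
    if absent and missing == "error":
        raise ValidationError(f"nodes absent from expression matrix: {absent[:5]}")
    X = expr.values
    out = nx.Graph(**graph.graph)
    out.add_nodes_from(graph.nodes(data=True))
    for a, b, data in graph.edges(data=True):
        if a not in present or b not in present:
            continue
        rho = stats.spearmanr(X.loc[a], X.loc[b]).statistic
        if np.isnan(rho):
            continue
        if abs(rho) >= rho_min:
            out.add_edge(a, b, coexpression_rho=float(rho), **data)
    return out


def maximal_connected_subnetwork(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Equal-size components are disambiguated by the lexicographically
    smallest sorted node list.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    components = [sorted(c, key=str) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), [str(n) for n in c]))
    return graph.subgraph(components[0]).copy()


@dataclass
class ScaleFreeFit:
    """Goodness of the log-log degree-distribution straight-line fit."""

    r_squared: float
    exponent: float  # estimated power-law exponent (negated slope)
    n_points: int
    degenerate: bool = False  # only two fitted points: perfect by construction


def scale_free_fit(graph: nx.Graph, n_bins: int | None = None) -> ScaleFreeFit:
    """R^2 of log10(degree frequency) regressed on log10(degree).

    Zero-degree nodes are excluded.  With ``n_bins`` the degrees are pooled
    into logarithmic bins (bin count divided by bin width, placed at the
    geometric bin centre); otherwise raw occupied degrees are used.
    """
    if graph.number_of_nodes() < 10:
        raise ValidationError("need >= 10 nodes for a degree-distribution fit")
    degrees = np.array([d for _, d in graph.degree()])
    degrees = degrees[degrees > 0]
    if degrees.size == 0 or np.unique(degrees).size < 2:
        raise UndefinedFitError("fewer than 2 distinct positive degrees")

    if n_bins is None:
        vals, counts = np.unique(degrees, return_counts=True)
        x = np.log10(vals)
        y = np.log10(counts)
    else:
        edges = np.logspace(
            np.log10(degrees.min()), np.log10(degrees.max() + 1), n_bins + 1
        )
        counts, edges = np.histogram(degrees, bins=edges)
        widths = np.diff(edges)
        centres = np.sqrt(edges[:-1] * edges[1:])
        keep = counts > 0
        x = np.log10(centres[keep])
        y = np.log10(counts[keep] / widths[keep])
    if x.size < 2:
        raise UndefinedFitError("fewer than 2 occupied bins")
    fit = stats.linregress(x, y)
    return ScaleFreeFit(
        r_squared=float(fit.rvalue**2),
        exponent=float(-fit.slope),
        n_points=int(x.size),
        degenerate=x.size == 2,
    )


def hub_network(graph: nx.Graph, top_fraction: float = 0.05) -> nx.Graph:
    """Induced subgraph on the top-degree hubs and their first neighbours.

    Hubs are nodes at or above the (1 - top_fraction) degree quantile with
    ties included, so the hub count may differ from ceil(top_fraction * n).
    The hub list is stored in ``H.graph["hubs"]``.
    """
    if not (0 < top_fraction < 1):
        raise ValidationError("top_fraction must be in (0, 1)")
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if not nx.is_connected(graph):
        raise ValidationError("hub extraction expects a connected graph")
    deg = dict(graph.degree())
    threshold = np.quantile(list(deg.values()), 1.0 - top_fraction, method="higher")
    hubs = [n for n, d in deg.items() if d >= threshold]
    try:
        hubs.sort()
    except TypeError:
        hubs.sort(key=str)
    nodes = set(hubs)
    for h in hubs:
        nodes.update(graph.neighbors(h))
    H = graph.subgraph(nodes).copy()
    H.graph["hubs"] = hubs
    H.graph["degree_threshold"] = int(threshold)
    return H


def k_clique_communities(graph: nx.Graph, k: int) -> list[frozenset]:
    """Overlapping communities by k-clique percolation.

    A community is the union of all k-cliques reachable from one another
    through k-cliques sharing k - 1 nodes.  Implemented over the maximal
    cliques of the graph: maximal cliques of size >= k sharing >= k - 1
    nodes percolate into the same community.  Output is ordered by size
    descending, then lexicographic node list.
    """
    if k < 3:
        raise ValidationError(f"k must be >= 3, got {k}")
    cliques = [frozenset(c) for c in nx.find_cliques(graph) if len(c) >= k]
    parent = list(range(len(cliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) >= k - 1:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, set] = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    communities = [frozenset(g) for g in groups.values()]
    communities.sort(key=lambda c: (-len(c), sorted(map(str, c))))
    return communities


@dataclass
class CommunityResult:
    k: int | None
    communities: list[frozenset] = field(default_factory=list)
    selected_module: frozenset = frozenset()
    note: str = ""


def select_module(graph: nx.Graph, k_min: int = 3, k_max: int | None = None) -> CommunityResult:
    """Largest community at the highest k that still percolates.

    Scans k from ``k_min`` up to ``k_max`` (default: the size of the largest
    clique) and keeps the communities of the largest k with at least one
    community; the selected module is the first under the deterministic
    community order (size descending, then lexicographic).
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if k_max is None:
        sizes = [len(c) for c in nx.find_cliques(graph)]
        k_max = max(sizes) if sizes else 0
    best_k: int | None = None
    best: list[frozenset] = []
    for k in range(k_min, max(k_max, k_min - 1) + 1):
        comms = k_clique_communities(graph, k)
        if comms:
            best_k, best = k, comms
    if best_k is None:
        return CommunityResult(k=None, note="no k-clique community at any k")
    return CommunityResult(k=best_k, communities=best, selected_module=best[0])


def graph_to_edge_frame(graph: nx.Graph) -> pd.DataFrame:
    """Edge list with attributes as a deterministic, sorted frame."""
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((str(a), str(b)))
        rows.append({"geneA": a, "geneB": b, **data})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["geneA", "geneB"], kind="mergesort").reset_index(drop=True)
    return frame
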