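"""Co-occurrence graph construction, topology statistics, random-graph nulls,
hub identification, and habitat-class edge summaries.

The observed network is built from the significant signed MIC edge set.
Topology follows the conventions of interactive network-analysis tools:
the clustering coefficient C is the mean *local* clustering coefficient
(nodes of degree < 2 contribute 0) and the characteristic path length L is
the mean shortest-path length over all connected ordered node pairs (the
graph need not be connected). The observed (C, L) are compared against the
means (Cr, Lr) over random replicates: uniform G(n, m) graphs with the same
node and edge counts by default, or degree-preserving edge-swap
randomizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .mic import MicResult, edge_sign

logger = logging.getLogger(__name__)


def build_network(
    edges: list[MicResult],
    clam_classes: pd.Series | None = None,
    taxonomy: dict[str, str] | None = None,
    trophic: dict[str, str] | None = None,
    total_reads: pd.Series | None = None,
) -> nx.Graph:
    """Simple undirected graph from a significant edge set, with annotations.

    Nodes are the OTUs incident to at least one edge (isolated OTUs are
    excluded); unannotated OTUs get explicit ``"unknown"`` attributes.
    Repeated pairs with identical attributes are deduplicated with a
    warning; conflicting duplicates are an error.
    """
    g = nx.Graph()
    for e in edges:
        if e.otu_a == e.otu_b:
            raise ValueError(f"self-loop edge for {e.otu_a!r}")
        key = tuple(sorted((e.otu_a, e.otu_b)))
        attrs = {"mic": e.mic, "pearson_r": e.pearson_r,
                 "nonlinearity": e.nonlinearity, "sign": edge_sign(e),
                 "p_value": e.p_value}
        if g.has_edge(*key):
            prev = g.edges[key]
            if abs(prev["mic"] - e.mic) > 1e-12 or prev["sign"] != attrs["sign"]:
                raise ValueError(f"conflicting duplicate edge {key}")
            logger.warning("duplicate edge %s deduplicated", key)
            continue
        g.add_edge(*key, **attrs)
    if g.number_of_edges() == 0:
        logger.warning("build_network: empty edge set -> empty network")
    for node in g.nodes:
        g.nodes[node]["clam_class"] = (
            str(clam_classes.get(node, "unknown")) if clam_classes is not None else "unknown"
        )
        g.nodes[node]["lineage"] = (
            taxonomy.get(node, "unknown") if taxonomy else "unknown"
        )
        g.nodes[node]["trophic"] = (
            trophic.get(node, "unknown") if trophic else "unknown"
        )
        g.nodes[node]["total_reads"] = (
            int(total_reads.get(node, 0)) if total_reads is not None else 0
        )
    return g


@dataclass
class NetworkStats:
    """Observed topology, optionally with random-null counterparts."""

    n_nodes: int
    n_edges: int
    clustering_C: float
    path_length_L: float
    path_length_L_lcc: float
    degree: dict[str, int] = field(repr=False)
    n_excluded_pairs: int = 0
    random_C: float | None = None
    random_L: float | None = None
    n_random: int = 0
    random_C_values: list[float] = field(default_factory=list, repr=False)
    random_L_values: list[float] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "C": self.clustering_C,
            "L": self.path_length_L,
            "L_largest_component": self.path_length_L_lcc,
            "Cr": self.random_C,
            "Lr": self.random_L,
            "n_random": self.n_random,
        }


def _mean_shortest_path(g: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path length over connected ordered pairs; also the
    number of (ordered) disconnected pairs excluded."""
    n = g.number_of_nodes()
    total_pairs = n * (n - 1)
    if total_pairs == 0:
        return float("nan"), 0
    s = 0
    connected = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                s += d
                connected += 1
    if connected == 0:
        return float("nan"), total_pairs
    return s / connected, total_pairs - connected


def topology(g: nx.Graph) -> NetworkStats:
    """Degree, mean local clustering coefficient C, characteristic path length L."""
    if g.number_of_nodes() == 0:
        return NetworkStats(0, 0, float("nan"), float("nan"), float("nan"), {})
    c = nx.average_clustering(g)  # local clustering; degree<2 nodes count as 0
    l_all, excluded = _mean_shortest_path(g)
    comps = list(nx.connected_components(g))
    lcc = g.subgraph(max(comps, key=len))
    l_lcc, _ = _mean_shortest_path(lcc)
    if excluded:
        logger.info("topology: %d ordered node pairs disconnected (excluded from L)",
                    excluded)
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        clustering_C=c,
        path_length_L=l_all,
        path_length_L_lcc=l_lcc,
        degree={n: int(d) for n, d in g.degree()},
        n_excluded_pairs=excluded,
    )


def random_null(
    g: nx.Graph,
    n_random: int = 100,
    model: str = "same_n_m",
    seed: int = 0,
) -> tuple[float, float, list[float], list[float]]:
    """Mean clustering (Cr) and path length (Lr) over random replicates.

    ``same_n_m``: uniform random simple graphs with the same node and edge
    counts. ``degree_preserving``: double-edge-swap randomization (about
    10 * |E| successful swaps) keeping every node's degree.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    n, m = g.number_of_nodes(), g.number_of_edges()
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_random):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if model == "same_n_m":
            r = nx.gnm_random_graph(n, m, seed=rep_seed)
        elif model == "degree_preserving":
            r = g.copy()
            if m > 1 and max(d for _, d in g.degree()) < n - 1:
                nx.double_edge_swap(r, nswap=10 * m, max_tries=200 * m,
                                    seed=rep_seed)
            else:
                logger.warning("degree_preserving: no feasible swaps, replicate kept as-is")
        else:
            raise ValueError(f"unknown null model: {model!r}")
        cs.append(nx.average_clustering(r))
        ls.append(_mean_shortest_path(r)[0])
    return float(np.mean(cs)), float(np.nanmean(ls)), cs, ls


def identify_hubs(stats: NetworkStats, min_degree: int = 20) -> list[str]:
    """Nodes with degree >= min_degree, by descending degree then node id."""
    hubs = [n for n, d in stats.degree.items() if d >= min_degree]
    return sorted(hubs, key=lambda n: (-stats.degree[n], n))


def habitat_edge_summary(g: nx.Graph) -> pd.DataFrame:
    """Edge counts and negative-edge fractions by endpoint CLAM-class pair.

    Categories: A-A (both habitat-A specialists), B-B, A-B (cross-habitat),
    generalist (at least one generalist endpoint), other (any endpoint
    too-rare or unannotated).
    """
    rows: dict[str, list[int]] = {}
    for u, v, attrs in g.edges(data=True):
        cu = g.nodes[u].get("clam_class", "unknown")
        cv = g.nodes[v].get("clam_class", "unknown")
        pair = {cu, cv}
        if pair == {"specialist_A"}:
            cat = "A-A"
        elif pair == {"specialist_B"}:
            cat = "B-B"
        elif pair == {"specialist_A", "specialist_B"}:
            cat = "A-B"
        elif "generalist" in pair and pair <= {"generalist", "specialist_A",
                                               "specialist_B"}:
            cat = "generalist"
        else:
            cat = "other"
        neg = 1 if attrs.get("sign") == "negative" else 0
        rows.setdefault(cat, [0, 0])
        rows[cat][0] += 1
        rows[cat][1] += neg
    recs = []
    total_edges = sum(v[0] for v in rows.values())
    total_neg = sum(v[1] for v in rows.values())
    for cat in ("A-A", "B-B", "A-B", "generalist", "other"):
        if cat in rows:
            n_edges, n_neg = rows[cat]
            recs.append({"category": cat, "n_edges": n_edges,
                         "negative_fraction": n_neg / n_edges})
    recs.append({"category": "all", "n_edges": total_edges,
                 "negative_fraction": (total_neg / total_edges) if total_edges else 0.0})
    return pd.DataFrame(recs).set_index("category")


class MicNetworkModel:
    """End-to-end co-occurrence network model for a normalized OTU table.

    Runs the full inference: abundance filter, all-pairs MIC with
    permutation significance, sign assignment, graph construction with
    annotations, topology, random-null comparison and hub calling.

    Parameters
    ----------
    table : OtuTable
        Rarefied count table (the abundance filter is applied here).
    mic_params : MicParams
    clam_classes, taxonomy, trophic : optional node annotations.
    null_model : 'same_n_m' or 'degree_preserving'.
    n_random : number of random replicates for (Cr, Lr).
    min_hub_degree : degree threshold for hub calling.
    """

    def __init__(self, table, mic_params=None, clam_classes=None, taxonomy=None,
                 trophic=None, null_model: str = "same_n_m", n_random: int = 100,
                 min_hub_degree: int = 20):
        from .mic import MicParams

        self.table = table
        self.mic_params = mic_params or MicParams()
        self.clam_classes = clam_classes
        self.taxonomy = taxonomy
        self.trophic = trophic
        self.null_model = null_model
        self.n_random = n_random
        self.min_hub_degree = min_hub_degree

    def fit(self) -> "MicNetworkResults":
        from .mic import build_edge_set
        from .otu import filter_min_total

        filtered = filter_min_total(self.table, self.mic_params.min_total_reads)
        edges = build_edge_set(filtered, self.mic_params)
        g = build_network(
            edges,
            clam_classes=self.clam_classes,
            taxonomy=self.taxonomy,
            trophic=self.trophic,
            total_reads=filtered.counts.sum(axis=1),
        )
        stats = topology(g)
        if g.number_of_edges() > 0:
            cr, lr, cvals, lvals = random_null(
                g, n_random=self.n_random, model=self.null_model,
                seed=self.mic_params.seed + 1,
            )
            stats.random_C, stats.random_L = cr, lr
            stats.n_random = self.n_random
            stats.random_C_values, stats.random_L_values = cvals, lvals
        hubs = identify_hubs(stats, self.min_hub_degree)
        return MicNetworkResults(model=self, edges=edges, graph=g, stats=stats,
                                 hubs=hubs)


@dataclass
class MicNetworkResults:
    """Inferred network with topology, null comparison and hub calls."""

    model: MicNetworkModel
    edges: list
    graph: nx.Graph
    stats: NetworkStats
    hubs: list[str]

    def edge_frame(self) -> pd.DataFrame:
        recs = [{"otu_a": e.otu_a, "otu_b": e.otu_b, "mic": e.mic,
                 "pearson_r": e.pearson_r, "nonlinearity": e.nonlinearity,
                 "p_value": e.p_value, "sign": e.sign} for e in self.edges]
        return pd.DataFrame(
            recs, columns=["otu_a", "otu_b", "mic", "pearson_r",
                           "nonlinearity", "p_value", "sign"])

    def summary(self) -> str:
        s = self.stats
        neg = sum(1 for e in self.edges if e.sign == "negative")
        lines = [
            "MIC co-occurrence network",
            "=========================",
            f"nodes: {s.n_nodes}   edges: {s.n_edges}   "
            f"negative edges: {neg} ({neg / max(s.n_edges, 1):.1%})",
            f"C  = {s.clustering_C:.4f}   L  = {s.path_length_L:.4f} "
            f"(largest component: {s.path_length_L_lcc:.4f})",
        ]
        if s.n_random:
            lines.append(
                f"Cr = {s.random_C:.4f}   Lr = {s.random_L:.4f} "
                f"(mean over {s.n_random} {self.model.null_model} replicates)")
        lines.append(
            f"hubs (degree >= {self.model.min_hub_degree}): {len(self.hubs)}")
        for h in self.hubs[:10]:
            lines.append(f"  {h}  degree={s.degree[h]}")
        return "\n".join(lines)


def export_graphml(g: nx.Graph, path) -> None:
    h = g.copy()
    for _, _, attrs in h.edges(data=True):  # GraphML cannot store None
        if attrs.get("p_value") is None:
            attrs["p_value"] = float("nan")
    nx.write_graphml(h, path)


def export_edge_tsv(g: nx.Graph, path) -> None:
    recs = [
        {"otu_a": u, "otu_b": v, **attrs} for u, v, attrs in g.edges(data=True)
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
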