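"""Spearman co-expression networks, bootstrap formation-tendency test, hubs.

Edges link gene pairs whose Spearman rank correlation is significant at a
chosen p cutoff (either sign of rho).  Clusters are connected components.
The network-formation-tendency test records node and edge counts of a target
gene set across a sweep of p thresholds and contrasts them with random
same-size draws from a background pool, mirroring the random-transcript
negative control design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, _frame, _prediction_t_pvalue

#: decade-step significance sweep from 5.0E-02 down to 1.0E-08.
THRESHOLD_SWEEP = (
    5.0e-02, 1.0e-02, 1.0e-03, 1.0e-04, 1.0e-05, 1.0e-06, 1.0e-07, 1.0e-08,
)


@dataclass(frozen=True)
class CorrelationEdge:
    gene_a: str
    gene_b: str
    rho: float
    p: float
    n: int

    def __post_init__(self):
        if not self.gene_a < self.gene_b:
            raise ValueError("edges require gene_a < gene_b (no self-edges)")
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("|rho| must be <= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def _rank_matrix(values: np.ndarray) -> np.ndarray:
    """Average ranks along samples (axis 1), handling ties."""
    return np.apply_along_axis(stats.rankdata, 1, values)


def _spearman_pvalues(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p for a genes x samples array.

    rho is the Pearson correlation of average ranks (tie-corrected); p comes
    from the t transform ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees
    of freedom.  |rho| = 1 yields p = 0.
    """
    n = values.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for Spearman p-values")
    ranks = _rank_matrix(values)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    np.fill_diagonal(p, 0.0)
    return rho, p


def _drop_constant(df: pd.DataFrame) -> pd.DataFrame:
    variances = df.to_numpy(dtype=float).std(axis=1)
    constant = variances == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} zero-variance gene(s) "
            "before correlation",
            stacklevel=3,
        )
        df = df.loc[~constant]
    return df


def spearman_edges(m) -> list[CorrelationEdge]:
    """Score every unordered gene pair of the matrix as a correlation edge."""
    df = _drop_constant(_frame(m))
    n = df.shape[1]
    rho, p = _spearman_pvalues(df.to_numpy(dtype=float))
    genes = [str(g) for g in df.index]
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = sorted((genes[i], genes[j]))
            edges.append(CorrelationEdge(a, b, float(rho[i, j]), float(p[i, j]), n))
    return edges


@dataclass
class CoexpressionNetwork:
    threshold_p: float
    graph: nx.Graph
    clusters: list  # list of sorted node lists, ordered by smallest member

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def connectivity(self) -> dict:
        return dict(self.graph.degree)

    def cluster_ids(self) -> dict:
        return {f"C{i + 1:02d}": members for i, members in enumerate(self.clusters)}


def build_network(
    edges: Iterable[CorrelationEdge], threshold_p: float
) -> CoexpressionNetwork:
    """Retain edges with p <= threshold (any sign of rho) and component-cluster.

    Nodes are genes incident to at least one retained edge; clusters are the
    connected components, ordered deterministically by their smallest member
    gene id.
    """
    if not 0.0 < threshold_p <= 1.0:
        raise ValueError("threshold_p must be in (0, 1]")
    g = nx.Graph()
    for e in edges:
        if e.p <= threshold_p:
            g.add_edge(e.gene_a, e.gene_b, rho=e.rho, p=e.p)
    clusters = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return CoexpressionNetwork(threshold_p=threshold_p, graph=g, clusters=clusters)


@dataclass
class TendencyCurve:
    """Node/edge counts across the threshold sweep, target vs random draws."""

    thresholds: tuple
    target_nodes: np.ndarray
    target_edges: np.ndarray
    random_nodes: np.ndarray  # (n_boot, n_thresholds)
    random_edges: np.ndarray
    n_boot: int
    node_p: np.ndarray  # per-threshold significance of the target node count
    edge_p: np.ndarray
    alpha: float
    seed: int | None

    def significant(self) -> np.ndarray:
        """Thresholds where both node and edge counts beat random at alpha."""
        return (self.node_p <= self.alpha) & (self.edge_p <= self.alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_p": self.thresholds,
                "target_nodes": self.target_nodes,
                "target_edges": self.target_edges,
                "random_nodes_mean": self.random_nodes.mean(axis=0),
                "random_nodes_sd": self.random_nodes.std(axis=0, ddof=1),
                "random_edges_mean": self.random_edges.mean(axis=0),
                "random_edges_sd": self.random_edges.std(axis=0, ddof=1),
                "node_p": self.node_p,
                "edge_p": self.edge_p,
            }
        )

    def to_dict(self) -> dict:
        df = self.to_frame()
        return {
            "n_boot": self.n_boot,
            "alpha": self.alpha,
            "seed": self.seed,
            "curve": df.to_dict(orient="records"),
        }


def _network_counts(values: np.ndarray, thresholds) -> tuple[np.ndarray, np.ndarray]:
    """Node and edge counts at each threshold for one gene set's matrix."""
    n_genes = values.shape[0]
    nodes = np.zeros(len(thresholds), dtype=int)
    edges = np.zeros(len(thresholds), dtype=int)
    if n_genes < 2:
        return nodes, edges
    _, p = _spearman_pvalues(values)
    iu = np.triu_indices(n_genes, k=1)
    pv = p[iu]
    for t_i, thr in enumerate(thresholds):
        keep = pv <= thr
        edges[t_i] = int(keep.sum())
        if edges[t_i]:
            adj = np.zeros((n_genes, n_genes), dtype=bool)
            adj[iu[0][keep], iu[1][keep]] = True
            nodes[t_i] = int((adj.any(axis=0) | adj.any(axis=1)).sum())
    return nodes, edges


def tendency_test(
    target: Iterable[str],
    pool: Iterable[str],
    m,
    thresholds: Sequence[float] = THRESHOLD_SWEEP,
    n_boot: int = 20,
    seed: int | None = None,
    alpha: float = 1.0e-02,
) -> TendencyCurve:
    """Network-formation tendency of a gene set vs random same-size draws.

    For each threshold in the sweep, records the target set's node and edge
    counts and those of *n_boot* random draws of the same size from the pool
    (target genes excluded).  Per-threshold significance is a two-sided
    prediction-interval t-test of the target count against the bootstrap
    counts.  Constant (zero-variance) genes are dropped within each set
    before correlation.
    """
    df = _frame(m)
    thresholds = tuple(sorted(thresholds, reverse=True))
    target = sorted(set(target))
    pool = sorted(set(pool) - set(target))
    if len(pool) < len(target):
        raise ValueError("pool smaller than target after exclusion")
    missing = set(target) - set(df.index)
    if missing:
        raise ValueError(f"target genes absent from matrix: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)

    def counts(ids):
        sub = df.loc[ids].to_numpy(dtype=float)
        sub = sub[sub.std(axis=1) > 0]
        return _network_counts(sub, thresholds)

    t_nodes, t_edges = counts(target)
    r_nodes = np.empty((n_boot, len(thresholds)), dtype=int)
    r_edges = np.empty((n_boot, len(thresholds)), dtype=int)
    for b in range(n_boot):
        draw = list(rng.choice(pool, size=len(target), replace=False))
        r_nodes[b], r_edges[b] = counts(draw)
    frac = len(target) / len(pool)
    node_p = np.array(
        [_prediction_t_pvalue(t_nodes[i], r_nodes[:, i], frac)
         for i in range(len(thresholds))]
    )
    edge_p = np.array(
        [_prediction_t_pvalue(t_edges[i], r_edges[:, i], frac)
         for i in range(len(thresholds))]
    )
    return TendencyCurve(
        thresholds=thresholds,
        target_nodes=t_nodes,
        target_edges=t_edges,
        random_nodes=r_nodes,
        random_edges=r_edges,
        n_boot=n_boot,
        node_p=node_p,
        edge_p=edge_p,
        alpha=alpha,
        seed=seed,
    )


@dataclass(frozen=True)
class HubCall:
    gene_id: str
    degree: int
    min_connectivity: int
    network_id: str = ""


def find_hubs(net: CoexpressionNetwork, min_connectivity: int,
              network_id: str = "") -> list[HubCall]:
    """Nodes with degree strictly greater than *min_connectivity*.

    Sorted by degree descending, ties broken by gene id.
    """
    hubs = [
        HubCall(str(g), int(d), min_connectivity, network_id)
        for g, d in net.graph.degree
        if d > min_connectivity
    ]
    hubs.sort(key=lambda h: (-h.degree, h.gene_id))
    return hubs


# ---------------------------------------------------------------------------
# tabular / graph IO
# ---------------------------------------------------------------------------

def edges_to_frame(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [e.gene_a for e in edges],
            "gene_b": [e.gene_b for e in edges],
            "rho": [e.rho for e in edges],
            "p": [e.p for e in edges],
            "n": [e.n for e in edges],
        }
    )


def hubs_to_frame(hubs: Sequence[HubCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hubs],
            "degree": [h.degree for h in hubs],
            "min_connectivity": [h.min_connectivity for h in hubs],
            "network_id": [h.network_id for h in hubs],
        }
    )


def export_graphml(net: CoexpressionNetwork, path) -> None:
    """Write the thresholded network as GraphML for layout/visualization tools."""
    nx.write_graphml(net.graph, path)
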