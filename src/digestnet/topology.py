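"""Network topology: module detection, graph metrics, Erdos-Renyi baselines,
small-world assessment, and module-level abundance/environment analysis.

The study-level question these tools answer: is the empirical co-occurrence
network more modular, more clustered, and longer-pathed than size-matched
random graphs ("small world" organization), and which environmental
gradients (NH4+-N, pH, COD, phosphate) track each module's community
structure?
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .containers import SampleMetadata, ValidationError
from .cooccurrence import CoOccurrenceNetwork, spearman_matrix
from .ordination import PermutationTestResult, partial_mantel

logger = logging.getLogger(__name__)

__all__ = [
    "ModulePartition",
    "TopologyReport",
    "EnsembleNull",
    "EnsembleComparison",
    "detect_modules",
    "modularity",
    "topology_metrics",
    "er_ensemble",
    "small_world_assessment",
    "module_profiles",
    "module_module_correlation",
    "module_env_mantel",
    "shared_nodes",
]


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------
@dataclass
class ModulePartition:
    """Node -> module assignment with its modularity score.

    Module ids are integers ordered by decreasing module size (ties broken
    by smallest node id), so module 0 is always the largest.
    """

    assignment: dict
    modularity: float
    algorithm: str
    seed: int
    resolution: float

    @property
    def modules(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, m in self.assignment.items():
            out.setdefault(m, []).append(node)
        return {m: sorted(nodes, key=str) for m, nodes in sorted(out.items())}

    @property
    def sizes(self) -> dict[int, int]:
        return {m: len(nodes) for m, nodes in self.modules.items()}


def _positive_graph(net) -> nx.Graph:
    if isinstance(net, CoOccurrenceNetwork):
        return net.to_networkx()
    if isinstance(net, nx.Graph):
        return net
    raise TypeError("expected CoOccurrenceNetwork or networkx Graph")


def detect_modules(net, seed: int = 0, resolution: float = 1.0) -> ModulePartition:
    """Louvain-style greedy modularity maximization on the positive-edge
    graph, with Spearman rho as edge weight. Deterministic given *seed*."""
    g = _positive_graph(net)
    if g.number_of_edges() == 0:
        raise ValidationError("cannot detect modules in an edgeless network")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    q = nx.community.modularity(g, communities, weight="weight", resolution=resolution)
    assignment = {node: m for m, comm in enumerate(communities) for node in comm}
    return ModulePartition(
        assignment=assignment, modularity=float(q), algorithm="louvain",
        seed=seed, resolution=resolution,
    )


def modularity(net, partition, weight: str | None = "weight") -> float:
    """Newman modularity Q = sum_c (e_c - a_c^2) of a node partition."""
    g = _positive_graph(net)
    assignment = partition.assignment if isinstance(partition, ModulePartition) else dict(partition)
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValidationError(f"nodes missing from partition: {missing}")
    groups: dict = {}
    for node, m in assignment.items():
        groups.setdefault(m, set()).add(node)
    return float(nx.community.modularity(g, list(groups.values()), weight=weight))


# ---------------------------------------------------------------------------
# topology metrics
# ---------------------------------------------------------------------------
@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    modularity: float
    avg_clustering: float
    avg_path_length: float
    lcc_fraction: float
    degrees: dict

    def metric_dict(self) -> dict[str, float]:
        return {
            "modularity": self.modularity,
            "avg_clustering": self.avg_clustering,
            "avg_path_length": self.avg_path_length,
        }


def _igraph_metrics(g: ig.Graph) -> tuple[float, float, float, float]:
    """(modularity of multilevel partition, avg local clustering with
    degree<2 nodes counted as 0, avg shortest path on the largest
    component, LCC coverage fraction)."""
    if g.ecount() == 0:
        return 0.0, 0.0, float("nan"), 0.0
    part = g.community_multilevel()
    q = float(part.modularity)
    clustering = float(g.transitivity_avglocal_undirected(mode="zero"))
    comps = g.connected_components()
    giant = comps.giant()
    path = float(giant.average_path_length()) if giant.vcount() > 1 else float("nan")
    return q, clustering, path, giant.vcount() / g.vcount()


def topology_metrics(net, seed: int = 0) -> TopologyReport:
    """Unweighted topology metrics of a co-occurrence network.

    Clustering is the average local clustering coefficient over all nodes
    (degree < 2 counts as 0); average path length uses unweighted shortest
    paths on the largest connected component, with the component coverage
    fraction reported alongside. Modularity is the unweighted multilevel
    partition's score, matching what the random-graph ensemble computes.
    """
    gx = _positive_graph(net)
    nodes = list(gx.nodes)
    index = {n: k for k, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in gx.edges]
    random.seed(seed)
    g = ig.Graph(n=len(nodes), edges=edges)
    q, clustering, path, lcc = _igraph_metrics(g)
    if 0 < lcc < 1:
        logger.info("topology_metrics: path length computed on %.0f%% of nodes", 100 * lcc)
    return TopologyReport(
        n_nodes=len(nodes),
        n_edges=len(edges),
        modularity=q,
        avg_clustering=clustering,
        avg_path_length=path,
        lcc_fraction=lcc,
        degrees={n: gx.degree(n) for n in nodes},
    )


# ---------------------------------------------------------------------------
# Erdos-Renyi ensemble
# ---------------------------------------------------------------------------
@dataclass
class EnsembleNull:
    """Streaming G(n, m) ensemble: per-draw metrics only, no graphs kept."""

    n_nodes: int
    n_edges: int
    n_networks: int
    seed: int
    metrics: dict[str, np.ndarray]

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, vals in self.metrics.items():
            ok = vals[~np.isnan(vals)]
            rows[name] = {"mean": ok.mean(), "sd": ok.std(ddof=1)}
        return pd.DataFrame(rows).T


@dataclass
class EnsembleComparison:
    empirical: TopologyReport
    null: EnsembleNull
    quantiles: dict[str, float]
    verdicts: dict[str, bool]


def er_ensemble(
    n_nodes: int,
    n_edges: int,
    n_networks: int = 10000,
    seed: int = 0,
    check: bool = False,
) -> EnsembleNull:
    """Sample G(n, m) graphs uniformly over simple edge sets and stream
    per-graph metrics (multilevel modularity, average clustering, average
    path length on the largest component).

    Every draw has exactly *n_nodes* nodes and *n_edges* edges; with
    ``check=True`` this is asserted per draw.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValidationError(f"n_edges {n_edges} exceeds max {max_edges}")
    rng = np.random.default_rng(seed)
    random.seed(int(rng.integers(2**31 - 1)))  # igraph community detection RNG
    iu, ju = np.triu_indices(n_nodes, k=1)
    q = np.empty(n_networks)
    clustering = np.empty(n_networks)
    path = np.empty(n_networks)
    for k in range(n_networks):
        pick = rng.choice(max_edges, size=n_edges, replace=False)
        edges = list(zip(iu[pick].tolist(), ju[pick].tolist()))
        g = ig.Graph(n=n_nodes, edges=edges)
        if check:
            assert g.vcount() == n_nodes and g.ecount() == n_edges
            assert g.is_simple()
        q[k], clustering[k], path[k], _ = _igraph_metrics(g)
    return EnsembleNull(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_networks=n_networks,
        seed=seed,
        metrics={"modularity": q, "avg_clustering": clustering, "avg_path_length": path},
    )


def small_world_assessment(
    empirical: TopologyReport, ensemble: EnsembleNull, quantile: float = 0.95
) -> EnsembleComparison:
    """Compare empirical metrics with the matched-size random ensemble.

    For each metric the empirical quantile within the null distribution is
    reported; the 'higher than random' verdict is issued when the observed
    value exceeds the ensemble's *quantile* (default 0.95) threshold —
    jointly for modularity, clustering and path length this is the
    small-world pattern.
    """
    if empirical.n_nodes != ensemble.n_nodes or empirical.n_edges != ensemble.n_edges:
        raise ValidationError(
            "empirical network and ensemble differ in node or edge count"
        )
    quantiles = {}
    verdicts = {}
    for name, obs in empirical.metric_dict().items():
        vals = ensemble.metrics[name]
        vals = vals[~np.isnan(vals)]
        quantiles[name] = float((vals <= obs).mean())
        verdicts[name] = bool(obs > np.quantile(vals, quantile))
    return EnsembleComparison(
        empirical=empirical, null=ensemble, quantiles=quantiles, verdicts=verdicts
    )


# ---------------------------------------------------------------------------
# module-level analyses
# ---------------------------------------------------------------------------
def module_profiles(partition: ModulePartition, abundances: pd.DataFrame) -> pd.DataFrame:
    """Per-sample module abundance: the sum of member OTU relative
    abundances, one column per module (named M<id>)."""
    missing = [n for n in partition.assignment if n not in abundances.columns]
    if missing:
        raise ValidationError(f"partition OTUs missing from abundance table: {missing}")
    out = {}
    for m, members in partition.modules.items():
        out[f"M{m}"] = abundances[members].sum(axis=1)
    return pd.DataFrame(out, index=abundances.index)


def module_module_correlation(profiles: pd.DataFrame):
    """Signed Spearman correlation between module abundance profiles."""
    constant = [c for c in profiles.columns if profiles[c].std() == 0]
    if constant:
        raise ValidationError(f"constant module profile(s): {constant}")
    return spearman_matrix(profiles)


def module_env_mantel(
    partition: ModulePartition,
    abundances: pd.DataFrame,
    metadata: SampleMetadata,
    n_perm: int = 9999,
    seed: int = 0,
    covariates: tuple = ("pH", "phosphate", "NH4N", "COD"),
    method: str = "spearman",
    min_module_size: int = 2,
    include_whole_community: bool = True,
) -> pd.DataFrame:
    """Partial Mantel r of each module's community structure against each
    environmental gradient, controlling the remaining covariates.

    Community distance is Bray-Curtis on the module's member-OTU abundance
    sub-table; each covariate's distance is Euclidean, and the other
    covariates are controlled. Returns a modules x covariates table of r
    with significance tiers ('**' p < 0.01, '*' p < 0.05); modules smaller
    than *min_module_size* are skipped with a notice.
    """
    if len(set(covariates)) != len(covariates):
        raise ValidationError("duplicate covariate in control set")
    meta = metadata.frame.loc[abundances.index]
    ids = [str(s) for s in abundances.index]
    env_dms = {
        c: DistanceMatrix(squareform(pdist(meta[[c]].to_numpy(dtype=float))), ids)
        for c in covariates
    }
    rows = {}
    targets: list[tuple[str, list]] = []
    if include_whole_community:
        targets.append(("community", list(abundances.columns)))
    for m, members in partition.modules.items():
        if len(members) < min_module_size:
            logger.info("module_env_mantel: skipping module %s (<%d members)", m, min_module_size)
            continue
        targets.append((f"M{m}", members))
    rng = np.random.default_rng(seed)
    for name, members in targets:
        sub = abundances[members].to_numpy(dtype=float)
        bc = squareform(pdist(sub, metric="braycurtis"))
        bc = np.nan_to_num(bc, nan=0.0)  # identical all-zero rows
        d_comm = DistanceMatrix(bc, ids)
        rec = {}
        for cov in covariates:
            controls = [env_dms[c] for c in covariates if c != cov]
            res = partial_mantel(
                d_comm, env_dms[cov], controls,
                n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), method=method,
            )
            rec[cov] = res.statistic
            rec[f"{cov}_p"] = res.p_value
            rec[f"{cov}_tier"] = "**" if res.p_value < 0.01 else ("*" if res.p_value < 0.05 else "")
        rows[name] = rec
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# cross-network node sharing
# ---------------------------------------------------------------------------
@dataclass
class SharedNodesReport:
    shared: set
    only_a: set
    only_b: set
    cross_tab: pd.DataFrame | None = None

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def shared_nodes(
    net_a: CoOccurrenceNetwork,
    net_b: CoOccurrenceNetwork,
    partition_a: ModulePartition | None = None,
    partition_b: ModulePartition | None = None,
) -> SharedNodesReport:
    """Node overlap between two networks, with an optional module-by-module
    cross-tabulation of the shared nodes (symmetric up to transposition)."""
    a, b = set(net_a.nodes), set(net_b.nodes)
    shared = a & b
    cross = None
    if partition_a is not None and partition_b is not None and shared:
        recs = [
            {"module_a": partition_a.assignment.get(n, -1),
             "module_b": partition_b.assignment.get(n, -1)}
            for n in shared
        ]
        frame = pd.DataFrame(recs)
        cross = pd.crosstab(frame["module_a"], frame["module_b"])
    return SharedNodesReport(shared=shared, only_a=a - shared, only_b=b - shared,
                             cross_tab=cross)
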