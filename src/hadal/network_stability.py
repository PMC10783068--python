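"""Co-occurrence network construction, topology, and stability analysis.

Networks are built from Pearson correlations of log-transformed ASV
relative abundances.  An edge is kept when |r| meets a cutoff chosen
either directly (``threshold=0.8``) or by a random-matrix-theory (RMT)
scan: the smallest cutoff at which the nearest-neighbour spacing
distribution of the unfolded eigenvalues of the thresholded correlation
matrix follows Poisson statistics (uncorrelated, modular signal) rather
than the Wigner/GOE statistics of correlated noise.

Stability metrics follow the ecological-network literature:

robustness
    proportion of taxa that still have at least one link after a fixed
    fraction of nodes is removed, either uniformly at random or by
    targeting module hubs (within-module degree z-score >= 2.5).
fragmentation
    f = 1 - sum_i s_i (s_i - 1) / (N'(N'-1)) over component sizes s_i:
    the chance that two surviving taxa are NOT in the same component
    (0 = fully connected, 1 = fully atomised), tracked while the
    highest-betweenness node is removed ten times in a row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io_formats import AbundanceTable
from .table_ops import log_relative

logger = logging.getLogger(__name__)

RMT_GRID = np.round(np.arange(0.30, 0.9501, 0.01), 2)
RMT_FALLBACK = 0.80
MODULE_HUB_Z = 2.5


@dataclass
class CoNetwork:
    """Signed, weighted co-occurrence graph plus its build settings.

    Nodes carry ``domain`` and ``mean_abundance``; edges carry the
    Pearson ``r``, its ``sign`` and ``weight`` = |r|.
    """

    graph: nx.Graph
    threshold: float
    mode: str  # "rmt" | "fixed"
    min_prevalence: int = 0
    rmt_scan: pd.DataFrame | None = None  # cutoff, n_nodes, p_poisson

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def settings(self) -> tuple:
        return (self.mode, self.threshold, self.min_prevalence)


@dataclass
class StabilityProfile:
    """Robustness and/or fragmentation results for one network."""

    robustness_mode: str | None = None
    robustness_fraction: float | None = None
    robustness_values: np.ndarray | None = None  # one per repetition
    robustness_mean: float | None = None
    robustness_sd: float | None = None
    fragmentation: np.ndarray | None = None  # f_0 .. f_k
    removal_order: list = field(default_factory=list)
    reps: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# construction


def correlation_matrix(logrel: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlation of the (taxa x samples) rows."""
    values = logrel.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        raise ValueError(
            f"zero-variance rows: {logrel.index[sd == 0].tolist()[:5]} ..."
        )
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=logrel.index, columns=logrel.index)


def _unfolded_spacings(eigenvalues: np.ndarray) -> np.ndarray | None:
    """Nearest-neighbour spacings of spectrally unfolded eigenvalues.

    Unfolding maps the spectrum through a smooth (cubic-spline) fit of
    its cumulative density so that the mean level spacing is 1
    everywhere; only then are Poisson vs Wigner shapes comparable.
    """
    lam = np.sort(eigenvalues)
    lam = lam + 1e-9 * np.arange(lam.size)  # break exact degeneracies
    n = lam.size
    if n < 30:
        return None
    cdf = (np.arange(n) + 0.5) / n
    # knots thinned to keep the spline smooth (true "average" density)
    k = max(n // 15, 4)
    knots = lam[np.linspace(0, n - 1, k).astype(int)]
    vals = cdf[np.linspace(0, n - 1, k).astype(int)]
    spline = interpolate.PchipInterpolator(knots, vals, extrapolate=True)
    unfolded = n * spline(lam)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 20:
        return None
    return spacings / spacings.mean()


def nnsd_poisson_pvalue(eigenvalues: np.ndarray, n_bins: int = 30) -> float | None:
    """Chi-square goodness of fit of the NNSD to the Poisson form e^-s."""
    s = _unfolded_spacings(eigenvalues)
    if s is None:
        return None
    upper = max(3.0, float(np.quantile(s, 0.99)))
    edges = np.linspace(0.0, upper, n_bins + 1)
    observed, _ = np.histogram(np.clip(s, 0, upper - 1e-12), bins=edges)
    expected = (np.exp(-edges[:-1]) - np.exp(-edges[1:])) * s.size
    # merge sparse tail bins so the chi-square approximation holds
    obs_m, exp_m = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5.0:
            obs_m.append(acc_o)
            exp_m.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if obs_m:
            obs_m[-1] += acc_o
            exp_m[-1] += acc_e
        else:
            return None
    if len(obs_m) < 3:
        return None
    obs_arr = np.array(obs_m)
    exp_arr = np.array(exp_m) * obs_arr.sum() / sum(exp_m)
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    return float(stats.chi2.sf(chi2, len(obs_m) - 1))


def rmt_threshold(
    corr: np.ndarray, grid=RMT_GRID, stability: int = 2
) -> tuple[float | None, pd.DataFrame]:
    """Scan correlation cutoffs for the GOE -> Poisson NNSD transition.

    Returns the smallest cutoff at which the spacing distribution
    becomes and stays consistent with Poisson (chi-square p > 0.05 at
    ``stability`` consecutive cutoffs — a single marginal fit inside
    the GOE regime is not a transition), plus the scan table.
    """
    records = []
    chosen = None
    run = 0
    for r_c in grid:
        m = np.where(np.abs(corr) >= r_c, corr, 0.0)
        np.fill_diagonal(m, 1.0)
        deg = (m != 0).sum(axis=1) - 1
        active = deg > 0
        if active.sum() < 30:
            # spectrum too small for NNSD statistics: the matrix is so
            # fragmented that correlated noise is already rejected
            records.append((r_c, int(active.sum()), np.nan))
            chosen = float(grid[len(records) - 1 - run]) if run else float(r_c)
            break
        sub = m[np.ix_(active, active)]
        eig = np.linalg.eigvalsh(sub)
        p = nnsd_poisson_pvalue(eig)
        records.append((r_c, int(active.sum()), np.nan if p is None else p))
        run = run + 1 if (p is not None and p > 0.05) else 0
        if run >= stability:
            chosen = float(np.round(r_c - 0.01 * (stability - 1), 10))
            break
    scan = pd.DataFrame(records, columns=["cutoff", "n_nodes", "p_poisson"])
    return chosen, scan


def build_network(
    table: AbundanceTable,
    threshold: str | float = "rmt",
    min_prevalence: int = 5,
) -> CoNetwork:
    """Build the co-occurrence network of an ASV table.

    Taxa present in fewer than ``min_prevalence`` samples are excluded
    before correlation; isolated nodes are dropped from the final graph.
    ``threshold`` is either the string ``"rmt"`` or a fixed |r| cutoff.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate")
    if table.n_samples < 5:
        logger.warning("fewer than 5 samples: correlations are unstable")
    prevalence = (table.counts > 0).sum(axis=1)
    kept = table.counts.index[prevalence >= min_prevalence]
    if len(kept) < 10:
        raise ValueError("fewer than 10 taxa pass the prevalence filter")
    sub = table.subset_taxa(kept)
    logrel = log_relative(sub)
    corr = correlation_matrix(logrel)
    cmat = corr.to_numpy()

    scan = None
    if threshold == "rmt":
        r_c, scan = rmt_threshold(cmat)
        mode = "rmt"
        if r_c is None:
            warnings.warn(
                "RMT scan found no Poisson-consistent cutoff; "
                f"falling back to fixed |r| >= {RMT_FALLBACK}"
            )
            r_c = RMT_FALLBACK
    else:
        r_c = float(threshold)
        mode = "fixed"
        if not (0.0 < r_c < 1.0):
            raise ValueError("fixed correlation cutoff must be in (0, 1)")

    mean_rel = sub.relative().mean(axis=1)
    domains = sub.domains()
    graph = nx.Graph()
    taxa = list(corr.index)
    iu = np.triu_indices(len(taxa), k=1)
    keep_mask = np.abs(cmat[iu]) >= r_c
    for i, j in zip(iu[0][keep_mask], iu[1][keep_mask]):
        r = float(cmat[i, j])
        graph.add_edge(
            taxa[i], taxa[j], r=r, weight=abs(r), sign="+" if r >= 0 else "-"
        )
    for node in graph.nodes:
        graph.nodes[node]["mean_abundance"] = float(mean_rel[node])
        graph.nodes[node]["domain"] = (
            str(domains[node]) if domains is not None else "unknown"
        )
    return CoNetwork(graph, float(r_c), mode, min_prevalence, scan)


# ---------------------------------------------------------------------------
# topology


def betweenness(graph: nx.Graph, normalized: bool = True) -> dict:
    """Betweenness centrality on unweighted shortest paths.

    Uses igraph's C implementation when available (identical values to
    the Brandes algorithm in networkx, which remains the fallback).
    """
    n = graph.number_of_nodes()
    if n == 0:
        return {}
    try:
        import igraph
    except ImportError:  # pragma: no cover
        return nx.betweenness_centrality(graph, normalized=normalized)
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = igraph.Graph(
        n=n, edges=[(index[u], index[v]) for u, v in graph.edges], directed=False
    )
    raw = g.betweenness()
    scale = 2.0 / ((n - 1) * (n - 2)) if (normalized and n > 2) else 1.0
    return {v: raw[i] * scale for i, v in enumerate(nodes)}


def modules(graph: nx.Graph) -> dict:
    """Greedy (CNM) modularity-maximisation community assignment.

    Deterministic; igraph's C implementation with the pure-python
    networkx agglomeration as fallback.
    """
    if graph.number_of_edges() == 0:
        return {v: i for i, v in enumerate(graph.nodes)}
    try:
        import igraph
    except ImportError:  # pragma: no cover
        communities = nx.algorithms.community.greedy_modularity_communities(graph)
        return {v: mid for mid, members in enumerate(communities) for v in members}
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = igraph.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges]
    )
    clustering = g.community_fastgreedy().as_clustering()
    return {nodes[i]: mid for mid, cluster in enumerate(clustering) for i in cluster}


def topology(net: CoNetwork) -> tuple[dict, pd.DataFrame]:
    """Global and per-node topological properties.

    Side effect: per-node degree, betweenness, clustering and module id
    are stored as node attributes on the graph so that written GraphML
    carries them.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(g.degree)
    btw = betweenness(g)
    clust = nx.clustering(g)  # unweighted local clustering coefficient
    mods = modules(g)
    n, e = g.number_of_nodes(), g.number_of_edges()
    neg = sum(1 for _, _, d in g.edges(data=True) if d.get("r", 0.0) < 0)
    if e > 0:
        comm = {}
        for v, mid in mods.items():
            comm.setdefault(mid, set()).add(v)
        q = nx.algorithms.community.modularity(g, comm.values())
    else:
        q = np.nan
    node_table = pd.DataFrame(
        {
            "degree": pd.Series(deg),
            "betweenness": pd.Series(btw),
            "clustering": pd.Series(clust),
            "module": pd.Series(mods),
        }
    ).sort_index()
    for v in g.nodes:
        g.nodes[v]["degree"] = int(deg[v])
        g.nodes[v]["betweenness"] = float(btw[v])
        g.nodes[v]["module"] = int(mods[v])
    stats_out = {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2.0 * e / n,
        "modularity": float(q) if q == q else np.nan,
        "n_components": nx.number_connected_components(g),
        "negative_link_ratio": neg / e if e else np.nan,
        "average_clustering": float(np.mean(list(clust.values()))),
    }
    return stats_out, node_table


def rank_hubs(net: CoNetwork, k: int = 10, criterion: str = "degree") -> list[str]:
    """Top-k taxa by abundance, degree, or betweenness (ties by taxon id)."""
    g = net.graph
    if criterion == "degree":
        score = dict(g.degree)
    elif criterion == "betweenness":
        score = betweenness(g)
    elif criterion == "abundance":
        score = {v: g.nodes[v].get("mean_abundance", 0.0) for v in g.nodes}
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if k > g.number_of_nodes():
        logger.warning("k exceeds node count; returning all nodes ranked")
        k = g.number_of_nodes()
    ordered = sorted(score, key=lambda v: (-score[v], str(v)))
    return ordered[:k]


# ---------------------------------------------------------------------------
# stability


def module_hub_scores(graph: nx.Graph) -> pd.Series:
    """Within-module degree z-score Zi for every node."""
    mods = modules(graph)
    deg_in = {}
    for v in graph.nodes:
        deg_in[v] = sum(1 for u in graph.neighbors(v) if mods[u] == mods[v])
    z = pd.Series(index=list(graph.nodes), dtype=float)
    frame = pd.DataFrame({"module": pd.Series(mods), "k": pd.Series(deg_in)})
    for _, grp in frame.groupby("module"):
        sd = grp["k"].std(ddof=0)
        if sd > 0:
            z[grp.index] = (grp["k"] - grp["k"].mean()) / sd
        else:
            z[grp.index] = 0.0
    return z


def _targeted_order(graph: nx.Graph) -> list:
    """Module hubs (Zi >= 2.5) first, then by degree; ties by node id."""
    z = module_hub_scores(graph)
    deg = dict(graph.degree)
    hubs = sorted(
        z.index[z >= MODULE_HUB_Z], key=lambda v: (-z[v], -deg[v], str(v))
    )
    rest = sorted(
        (v for v in graph.nodes if v not in set(hubs)),
        key=lambda v: (-deg[v], str(v)),
    )
    return list(hubs) + rest


def _surviving_fraction(graph: nx.Graph, removed: set) -> float:
    """Share of the original nodes that keep >= 1 link after removal."""
    n0 = graph.number_of_nodes()
    remaining = [v for v in graph.nodes if v not in removed]
    sub = graph.subgraph(remaining)
    alive = sum(1 for v in remaining if sub.degree(v) > 0)
    return alive / n0


def robustness(
    net: CoNetwork,
    fraction: float = 0.5,
    mode: str = "random",
    reps: int = 100,
    seed: int | None = None,
) -> StabilityProfile:
    """Proportion of taxa still connected after removing ``fraction`` of nodes.

    ``random`` removes uniformly without replacement (``reps``
    repetitions, mean +/- SD reported); ``targeted`` removes module hubs
    (within-module degree z >= 2.5, then highest degree) once.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    n_remove = int(np.floor(fraction * n))
    if mode == "random":
        rng = np.random.default_rng(seed)
        nodes = np.array(list(g.nodes), dtype=object)
        values = np.array(
            [
                _surviving_fraction(
                    g, set(rng.choice(nodes, size=n_remove, replace=False))
                )
                for _ in range(reps)
            ]
        )
        order: list = []
    elif mode == "targeted":
        order = _targeted_order(g)[:n_remove]
        values = np.array([_surviving_fraction(g, set(order))])
        reps = 1
    else:
        raise ValueError(f"unknown removal mode {mode!r}")
    return StabilityProfile(
        robustness_mode=mode,
        robustness_fraction=fraction,
        robustness_values=values,
        robustness_mean=float(values.mean()),
        robustness_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        removal_order=list(order),
        reps=reps,
        seed=seed,
    )


def fragmentation(graph: nx.Graph) -> float:
    """f = 1 - sum s_i (s_i - 1) / (N (N - 1)) over component sizes."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    same = sum(s * (s - 1) for s in (len(c) for c in nx.connected_components(graph)))
    return 1.0 - same / (n * (n - 1))


def fragmentation_series(
    net: CoNetwork, k: int = 10, recompute: bool = True
) -> StabilityProfile:
    """Fragmentation after consecutive removal of top-betweenness nodes.

    After each removal the betweenness ranking is recomputed on the
    reduced graph (set ``recompute=False`` to remove by the initial
    ranking).  Ties break by degree, then node id.  Returns f_0 .. f_k.
    """
    g = net.graph.copy()
    if g.number_of_nodes() <= k:
        raise ValueError("network must have more than k nodes")
    series = [fragmentation(g)]
    order = []
    static_rank = None
    if not recompute:
        btw = betweenness(g)
        deg = dict(g.degree)
        static_rank = sorted(g.nodes, key=lambda v: (-btw[v], -deg[v], str(v)))
    for step in range(k):
        if recompute:
            btw = betweenness(g)
            deg = dict(g.degree)
            target = min(g.nodes, key=lambda v: (-btw[v], -deg[v], str(v)))
        else:
            target = static_rank[step]
        g.remove_node(target)
        order.append(target)
        series.append(fragmentation(g))
    f = np.array(series)
    if (np.diff(f) < -1e-12).any():
        logger.warning("fragmentation decreased after a removal (tie pathology)")
    return StabilityProfile(fragmentation=f, removal_order=order)


def compare_zones(
    net_a: CoNetwork,
    net_b: CoNetwork,
    labels: tuple[str, str] = ("UBW", "HW"),
    fraction: float = 0.5,
    reps: int = 100,
    seed: int | None = None,
) -> dict:
    """Side-by-side topology and stability of two zone networks.

    Both networks must have been built with identical settings.  The
    random-removal robustness repetitions are compared with a two-sample
    Mann-Whitney U test.
    """
    if net_a.settings() != net_b.settings():
        raise ValueError("networks were built with different settings")
    report: dict = {}
    rob = {}
    for label, net, sub_seed in zip(labels, (net_a, net_b), (seed, None if seed is None else seed + 1)):
        glob, _ = topology(net)
        rnd = robustness(net, fraction, "random", reps, sub_seed)
        tgt = robustness(net, fraction, "targeted", seed=sub_seed)
        glob["robustness_random_mean"] = rnd.robustness_mean
        glob["robustness_random_sd"] = rnd.robustness_sd
        glob["robustness_targeted"] = tgt.robustness_mean
        report[label] = glob
        rob[label] = rnd.robustness_values
    u, p = stats.mannwhitneyu(rob[labels[0]], rob[labels[1]], alternative="two-sided")
    report["robustness_test"] = {"statistic": float(u), "p_value": float(p)}
    return report


# keep the module import surface tidy for "from ... import *" users
__all__ = [
    "CoNetwork",
    "StabilityProfile",
    "betweenness",
    "build_network",
    "compare_zones",
    "correlation_matrix",
    "fragmentation",
    "fragmentation_series",
    "modules",
    "module_hub_scores",
    "nnsd_poisson_pvalue",
    "rank_hubs",
    "rmt_threshold",
    "robustness",
    "topology",
]
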