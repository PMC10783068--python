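"""Pairwise community dissimilarity, NMDS ordination, and ANOSIM.

Four metrics span presence/absence vs abundance and taxonomic vs
phylogenetic turnover: Jaccard, Bray-Curtis, unweighted UniFrac and
(normalized) weighted UniFrac.  All four live on [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity as _skbio_beta

from .io_formats import AbundanceTable

METRICS = ("jaccard", "braycurtis", "unweighted_unifrac", "weighted_unifrac")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities under a named metric."""

    data: np.ndarray
    sample_ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("negative dissimilarity")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.data, ids=self.sample_ids)


@dataclass
class OrdinationResult:
    """NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame  # samples x k
    stress: float
    n_iter: int
    converged: bool = True


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def distance_matrix(
    table: AbundanceTable, metric: str, tree: TreeNode | None = None
) -> DistanceMatrix:
    """Pairwise sample dissimilarities under one of the four metrics.

    Jaccard works on presence/absence; Bray-Curtis and weighted UniFrac
    on relative abundances; the UniFrac metrics additionally need a
    rooted tree covering every taxon in the table.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    samples = table.sample_ids
    if metric == "jaccard":
        presence = (table.counts.to_numpy() > 0).T
        d = squareform(pdist(presence, metric="jaccard"))
    elif metric == "braycurtis":
        rel = table.relative().to_numpy().T
        d = squareform(pdist(rel, metric="braycurtis"))
    else:
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxon_ids if t not in tips]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing}")
        counts = table.counts.to_numpy().T
        kwargs = {"taxa": table.taxon_ids, "tree": tree}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = True
        dm = _skbio_beta(metric, counts, ids=samples, **kwargs)
        d = dm.data
    return DistanceMatrix(d, list(samples), metric)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    restarts: int = 50,
    max_iter: int = 300,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling by isotonic regression.

    Best configuration over ``restarts`` random starts; reported stress
    is Kruskal stress-1.  A result that exhausts ``max_iter`` is
    returned with ``converged=False`` rather than discarded.
    """
    from sklearn.manifold import MDS

    if d.n < k + 2:
        raise ValueError("need at least k + 2 samples for a k-dimensional NMDS")
    model = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        n_init=restarts,
        max_iter=max_iter,
        init="random",
        eps=1e-7,
        normalized_stress=True,
        random_state=None if seed is None else int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(d.data)
    converged = model.n_iter_ < max_iter
    if not converged:
        warnings.warn("NMDS hit the iteration cap; returning best-so-far")
    frame = pd.DataFrame(
        coords, index=d.sample_ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(frame, float(model.stress_), int(model.n_iter_), converged)


def anosim(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Analysis of similarities on the ranked distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M / 2)
    with M = n(n-1)/2; the permutation p-value carries the +1
    correction and so never returns 0.
    """
    labels = pd.Series(groups).reindex(d.sample_ids)
    if labels.isna().any():
        raise ValueError("group label missing for some samples")
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (sizes < 2).any():
        raise ValueError(f"singleton group(s): {sizes[sizes < 2].index.tolist()}")
    ranks = stats.rankdata(d.condensed())
    n = d.n
    iu = np.triu_indices(n, k=1)
    codes = pd.factorize(labels)[0]

    def _r(codes_vec: np.ndarray) -> float:
        within = codes_vec[iu[0]] == codes_vec[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2.0)

    r_obs = _r(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _r(rng.permutation(codes)) >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(float(r_obs), (hits + 1) / (n_perm + 1), n_perm)
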