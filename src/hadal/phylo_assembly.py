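"""Phylogenetic community structure and assembly-process null models.

Within-sample statistics: mean pairwise distance (MPD) and mean
nearest-taxon distance (MNTD), plus the standardized effect size
SES.MNTD = (MNTD_obs - mean_null) / sd_null under whole-tree tip-label
shuffling.  Negative SES.MNTD means co-occurring taxa are more closely
related than chance - phylogenetic clustering, the signature of
environmental filtering.

Between-sample statistics: beta-MNTD (the abundance-weighted mean
distance from each taxon to its nearest neighbour in the other sample)
and its standardized effect size betaNTI under the same null.
|betaNTI| <= 2 is conventionally read as stochastic assembly, > 2 as
variable selection, < -2 as homogeneous selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)

MIN_RANDOMIZATIONS = 99


@dataclass
class NullModelResult:
    """Observed statistic vs its tip-shuffle null, per sample or pair."""

    frame: pd.DataFrame
    statistic: str  # "ses_mntd" | "bnti"
    n_randomizations: int
    seed: int | None


def patristic_matrix(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    """Tip-to-tip path-length matrix aligned to ``taxa`` order."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    dm = tree.tip_tip_distances(endpoints=list(taxa))
    order = [dm.index(t) for t in taxa]
    return dm.data[np.ix_(order, order)]


def _degenerate_null(null_sd: np.ndarray, null_mean: np.ndarray) -> np.ndarray:
    """A null with spread at float-noise level cannot standardize anything."""
    return null_sd <= 1e-10 * np.maximum(1.0, np.abs(null_mean))


def _check_nrand(n_rand: int) -> int:
    if n_rand < MIN_RANDOMIZATIONS:
        raise ValueError(f"need at least {MIN_RANDOMIZATIONS} randomizations")
    return int(n_rand)


# ---------------------------------------------------------------------------
# within-sample statistics


def mntd_from_matrix(
    dist: np.ndarray, abundances: np.ndarray | None = None
) -> float:
    """Mean nearest-taxon distance over the taxa of one sample.

    ``dist`` is the patristic submatrix of the present taxa.  With
    ``abundances`` the nearest-neighbour distances are weighted by
    relative abundance; otherwise the plain mean is used.  Undefined
    (nan) for fewer than 2 taxa.
    """
    n = dist.shape[0]
    if n < 2:
        return np.nan
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    if abundances is None:
        return float(nearest.mean())
    w = np.asarray(abundances, dtype=float)
    w = w / w.sum()
    return float((nearest * w).sum())


def mpd_from_matrix(dist: np.ndarray, abundances: np.ndarray | None = None) -> float:
    """Mean pairwise patristic distance over the taxa of one sample."""
    n = dist.shape[0]
    if n < 2:
        return np.nan
    iu = np.triu_indices(n, k=1)
    if abundances is None:
        return float(dist[iu].mean())
    w = np.asarray(abundances, dtype=float)
    w = w / w.sum()
    weights = (w[iu[0]] * w[iu[1]])
    return float((dist[iu] * weights).sum() / weights.sum())


def mntd(
    sample: pd.Series, tree: TreeNode, weighted: bool = False
) -> float:
    """MNTD of a single sample (a taxon -> count Series)."""
    present = sample[sample > 0]
    if len(present) < 2:
        logger.warning("MNTD undefined for < 2 taxa")
        return np.nan
    d = patristic_matrix(tree, list(present.index))
    return mntd_from_matrix(d, present.to_numpy() if weighted else None)


def mean_pairwise_distance(
    sample: pd.Series, tree: TreeNode, weighted: bool = False
) -> float:
    """MPD of a single sample."""
    present = sample[sample > 0]
    if len(present) < 2:
        logger.warning("MPD undefined for < 2 taxa")
        return np.nan
    d = patristic_matrix(tree, list(present.index))
    return mpd_from_matrix(d, present.to_numpy() if weighted else None)


def phylogenetic_distance_summary(
    table: AbundanceTable, tree: TreeNode, weighted: bool = False
) -> pd.DataFrame:
    """Per-sample MPD, MNTD and mean pooled pairwise distance."""
    dist = patristic_matrix(tree, table.taxon_ids)
    rows = {}
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        idx = np.flatnonzero(counts)
        sub = dist[np.ix_(idx, idx)]
        w = counts[idx] if weighted else None
        rows[sample] = {
            "mpd": mpd_from_matrix(sub, w),
            "mntd": mntd_from_matrix(sub, w),
            "mean_pairwise": mpd_from_matrix(sub, None),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# SES.MNTD


def ses_mntd(
    table: AbundanceTable,
    tree: TreeNode,
    n_rand: int = 999,
    weighted: bool = False,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> NullModelResult:
    """Standardized effect size of MNTD under tip-label shuffling.

    The null shuffles tip labels across the whole tree (equivalently,
    permutes rows/columns of the patristic matrix) ``n_rand`` times.
    Samples whose null has zero spread get SES nan with a warning.
    An explicit ``permutations`` array (n_rand x n_taxa) replaces the
    random draws, e.g. for exhaustive enumeration on tiny trees.
    """
    rng = np.random.default_rng(seed)
    dist = patristic_matrix(tree, table.taxon_ids)
    n_taxa = len(table.taxon_ids)
    if permutations is not None:
        permutations = np.asarray(permutations)
        n_rand = permutations.shape[0]
    else:
        n_rand = _check_nrand(n_rand)
    counts = table.counts.to_numpy()
    sample_idx = [np.flatnonzero(counts[:, j]) for j in range(counts.shape[1])]
    obs = np.array(
        [
            mntd_from_matrix(
                dist[np.ix_(idx, idx)],
                counts[idx, j] if weighted else None,
            )
            for j, idx in enumerate(sample_idx)
        ]
    )
    nulls = np.empty((n_rand, counts.shape[1]))
    for r in range(n_rand):
        perm = permutations[r] if permutations is not None else rng.permutation(n_taxa)
        for j, idx in enumerate(sample_idx):
            pidx = perm[idx]
            nulls[r, j] = mntd_from_matrix(
                dist[np.ix_(pidx, pidx)], counts[idx, j] if weighted else None
            )
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    degenerate = _degenerate_null(null_sd, null_mean)
    null_sd[degenerate] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = (obs - null_mean) / null_sd
    if degenerate.any():
        logger.warning("degenerate null (sd = 0) for %d sample(s)", degenerate.sum())
        ses[degenerate] = np.nan
    frame = pd.DataFrame(
        {
            "mntd_obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses_mntd": ses,
        },
        index=table.sample_ids,
    )
    return NullModelResult(frame, "ses_mntd", n_rand, seed)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def _bmntd_pair(
    dist: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    w_a: np.ndarray | None,
    w_b: np.ndarray | None,
) -> float:
    """betaMNTD between two samples given index sets into ``dist``."""
    cross = dist[np.ix_(idx_a, idx_b)]
    near_a = cross.min(axis=1)  # each taxon in A to nearest taxon in B
    near_b = cross.min(axis=0)
    if w_a is None:
        return 0.5 * (near_a.mean() + near_b.mean())
    return 0.5 * (float(near_a @ w_a) + float(near_b @ w_b))


def beta_mntd(
    table: AbundanceTable, tree: TreeNode, weighted: bool = True
) -> pd.DataFrame:
    """Observed betaMNTD for every sample pair (long format)."""
    dist = patristic_matrix(tree, table.taxon_ids)
    return _bnti_core(table, dist, n_rand=0, weighted=weighted, rng=None)[0]


def _pair_data(counts: np.ndarray, weighted: bool):
    idx = [np.flatnonzero(counts[:, j]) for j in range(counts.shape[1])]
    weights = None
    if weighted:
        rel = counts / counts.sum(axis=0, keepdims=True)
        weights = [rel[idx[j], j] / rel[idx[j], j].sum() for j in range(counts.shape[1])]
    return idx, weights


def _bnti_core(table, dist, n_rand, weighted, rng, seed=None):
    counts = table.counts.to_numpy()
    n_taxa, n_samples = counts.shape
    idx, weights = _pair_data(counts, weighted)
    pairs = [
        (a, b)
        for a, b in combinations(range(n_samples), 2)
        if len(idx[a]) >= 2 and len(idx[b]) >= 2
    ]
    obs = np.array(
        [
            _bmntd_pair(
                dist,
                idx[a],
                idx[b],
                None if not weighted else weights[a],
                None if not weighted else weights[b],
            )
            for a, b in pairs
        ]
    )
    ids = table.sample_ids
    frame = pd.DataFrame(
        {
            "sample_a": [ids[a] for a, _ in pairs],
            "sample_b": [ids[b] for _, b in pairs],
            "bmntd_obs": obs,
        }
    )
    if n_rand == 0:
        return frame, None
    nulls = np.empty((n_rand, len(pairs)))
    for r in range(n_rand):
        perm = rng.permutation(n_taxa)
        for k, (a, b) in enumerate(pairs):
            nulls[r, k] = _bmntd_pair(
                dist,
                perm[idx[a]],
                perm[idx[b]],
                None if not weighted else weights[a],
                None if not weighted else weights[b],
            )
    return frame, nulls


def classify_bnti(bnti: float) -> str:
    if np.isnan(bnti):
        return "undefined"
    if bnti > 2.0:
        return "variable_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    return "stochastic"


def beta_nti(
    table: AbundanceTable,
    tree: TreeNode,
    n_rand: int = 999,
    weighted: bool = True,
    seed: int | None = None,
) -> NullModelResult:
    """betaNTI for every sample pair under tip-label shuffling.

    Weights are relative abundances within each sample; pairs sharing
    no taxa are still defined because nearest neighbours are found
    through the tree.  Each pair is classified as stochastic
    (|betaNTI| <= 2), variable_selection (> 2) or
    homogeneous_selection (< -2).
    """
    n_rand = _check_nrand(n_rand)
    rng = np.random.default_rng(seed)
    dist = patristic_matrix(tree, table.taxon_ids)
    frame, nulls = _bnti_core(table, dist, n_rand, weighted, rng)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    degenerate = _degenerate_null(null_sd, null_mean)
    null_sd[degenerate] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (frame["bmntd_obs"].to_numpy() - null_mean) / null_sd
    if degenerate.any():
        logger.warning("degenerate null (sd = 0) for %d pair(s)", degenerate.sum())
        bnti[degenerate] = np.nan
    frame["null_mean"] = null_mean
    frame["null_sd"] = null_sd
    frame["bnti"] = bnti
    frame["process"] = [classify_bnti(v) for v in bnti]
    return NullModelResult(frame, "bnti", n_rand, seed)
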