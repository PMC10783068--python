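"""Synthetic multi-domain communities with known assembly processes.

The generator emulates the structure of a rarefied trench amplicon data
set — three domains (bacteria, archaea, microeukaryotes) sampled along a
vertical depth profile at two filter pore sizes — while the assembly
process that produced every table is known exactly:

``neutral``
    Each sample is an independent local community of ``local_size``
    individuals evolved by zero-sum Hubbell/Sloan dynamics: at every
    step one random individual dies and is replaced, with probability
    ``m``, by an immigrant drawn from the metacommunity relative
    abundances ``p`` and otherwise by the offspring of a random local
    individual.

``niche``
    Taxon environmental optima evolve on the phylogeny by Brownian
    motion (phylogenetic conservatism ``conservatism`` in [0, 1]); the
    expected abundance of taxon *i* in sample *j* is proportional to
    ``p_i * exp(-(E_j - o_i)^2 / (2 sigma^2))`` where ``E_j`` is the
    sample's position on the standardized (log-depth) gradient.

``mixed``
    A convex blend of the two expected compositions with weight
    ``mix_weight`` on the niche component.

All modes finish with multinomial sequencing sampling to
``sequencing_depth`` reads, so column sums are exact and tables are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import random as _pyrandom
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from numba import njit
from skbio import TreeNode

from .io_formats import AbundanceTable, SampleMetadata, tree_from_newick

#: sampling depths (m) of the vertical profile being emulated
DEFAULT_DEPTHS = (2.0, 500.0, 1000.0, 1759.0, 3699.0, 5367.0, 7200.0, 8727.0)

#: filter pore sizes (µm): free-living and particle-associated fractions
DEFAULT_PORE_SIZES = (0.22, 3.0)

#: ASV richness per domain at study scale
STUDY_TAXA: Mapping[str, int] = {
    "bacteria": 1219,
    "archaea": 638,
    "microeukaryote": 1039,
}


@dataclass
class SimulationConfig:
    """Parameters of one single-domain community simulation."""

    n_taxa: int = 1000
    depths: tuple = DEFAULT_DEPTHS
    pore_sizes: tuple = DEFAULT_PORE_SIZES
    mode: str = "neutral"  # neutral | niche | mixed
    m: float = 0.1  # immigration (migration) rate, (0, 1]
    sigma: float = 1.0  # niche filter width, gradient-SD units
    conservatism: float = 1.0  # phylogenetic signal of optima, [0, 1]
    mix_weight: float = 0.5  # niche share in mixed mode, [0, 1]
    local_size: int = 10_000  # local community size N_L
    generations: int = 30  # Moran generations (N_L steps each) simulated
    sequencing_depth: int = 20_000
    logseries_x: float = 0.999  # shape of the metacommunity log-series
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not (0.0 < self.m <= 1.0):
            raise ValueError("m must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.conservatism <= 1.0):
            raise ValueError("conservatism must be in [0, 1]")
        if not (0.0 <= self.mix_weight <= 1.0):
            raise ValueError("mix_weight must be in [0, 1]")
        if self.mode not in ("neutral", "niche", "mixed"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.generations < 10:
            raise ValueError("generations must be >= 10 for equilibration")

    @property
    def n_samples(self) -> int:
        return len(self.depths) * len(self.pore_sizes)


@dataclass
class GroundTruth:
    """What the simulator actually did; never altered downstream."""

    mode: str
    m: float
    metacommunity: pd.Series  # taxon -> relative abundance p_i
    tree: TreeNode
    optima: pd.Series | None  # taxon -> environmental optimum (niche/mixed)
    gradient: pd.Series  # sample -> standardized environment E_j
    config: SimulationConfig


# ---------------------------------------------------------------------------
# phylogeny


def simulate_tree(n_tips: int, seed: int | None = None) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree, unit birth rate, tips ASV_1..n."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = _pyrandom.Random(None if seed is None else int(seed))
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = tree_from_newick(newick)
    width = len(str(n_tips))
    for i, tip in enumerate(tree.tips(), start=1):
        tip.name = f"ASV_{i:0{width}d}"
    return tree


def brownian_optima(
    tree: TreeNode, conservatism: float = 1.0, seed: int | None = None
) -> pd.Series:
    """Evolve a trait along the tree by Brownian motion.

    ``conservatism`` interpolates between fully heritable optima
    (1: pure Brownian motion, close relatives share habitat preference)
    and phylogeny-free optima (0: iid normal).  The returned trait is
    standardized to zero mean and unit variance across tips.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(max(node.length, 0.0)))
        values[id(node)] = values[id(node.parent)] + step
    tips = [t.name for t in tree.tips()]
    z = np.array([values[id(t)] for t in tree.tips()])
    if z.std() > 0:
        z = (z - z.mean()) / z.std()
    noise = rng.standard_normal(len(tips))
    lam = float(conservatism)
    trait = np.sqrt(lam) * z + np.sqrt(1.0 - lam) * noise
    if trait.std() > 0:
        trait = (trait - trait.mean()) / trait.std()
    return pd.Series(trait, index=tips, name="optimum")


# ---------------------------------------------------------------------------
# metacommunity and environment


def logseries_metacommunity(
    n_taxa: int, x: float = 0.999, seed: int | None = None
) -> np.ndarray:
    """Metacommunity relative abundances with a Fisher log-series shape."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    counts = stats.logser.rvs(x, size=n_taxa, random_state=rng).astype(float)
    return counts / counts.sum()


def depth_gradient(depths) -> np.ndarray:
    """Standardized log10-depth: the one-dimensional vertical gradient."""
    e = np.log10(np.asarray(depths, dtype=float) + 1.0)
    return (e - e.mean()) / e.std()


def simulate_metadata(
    depths=DEFAULT_DEPTHS, pore_sizes=DEFAULT_PORE_SIZES, seed: int | None = None
) -> SampleMetadata:
    """Plausible water-column covariates for each (depth, pore size) sample.

    Profiles are smooth monotone-ish functions of depth (warm oxygenated
    surface, oxygen minimum near 1000 m, nutrient accumulation at depth)
    with a few percent of multiplicative noise; they exist to exercise
    the regression-tree and ordination machinery, not to reproduce any
    particular hydrography.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        z = float(depth)
        env = {
            "depth": z,
            "temperature": 1.5 + 26.5 * np.exp(-z / 350.0),
            "salinity": 34.6 - 0.35 * np.exp(-z / 150.0),
            "DO": 210.0 - 150.0 * np.exp(-((np.log10(z + 1) - 3.0) ** 2) / 0.5),
            "pH": 8.1 - 0.35 * np.exp(-((np.log10(z + 1) - 3.0) ** 2) / 0.8),
            "PO4": 0.1 + 2.9 * (1.0 - np.exp(-z / 800.0)),
            "NO3": 1.0 + 38.0 * (1.0 - np.exp(-z / 700.0)),
            "NO2": 0.02 + 0.4 * np.exp(-((np.log10(z + 1) - 2.3) ** 2) / 0.3),
            "NH4": 0.05 + 0.6 * np.exp(-((np.log10(z + 1) - 2.0) ** 2) / 0.4),
            "SiO3": 2.0 + 148.0 * (1.0 - np.exp(-z / 1500.0)),
        }
        for pore in pore_sizes:
            row = {
                k: (v if k == "depth" else v * rng.lognormal(0.0, 0.02))
                for k, v in env.items()
            }
            row["pore_size"] = pore
            rows.append((_sample_id(z, pore), row))
    frame = pd.DataFrame({sid: row for sid, row in rows}).T
    frame.index.name = "sample_id"
    return SampleMetadata(frame)


def _sample_id(depth: float, pore: float) -> str:
    d = int(round(depth))
    return f"D{d}m_{pore}um"


# ---------------------------------------------------------------------------
# neutral (Moran/Sloan) dynamics


@njit(cache=True)
def _moran_kernel(individuals, cum_p, m, n_steps, seed):  # pragma: no cover
    np.random.seed(seed)
    n = individuals.shape[0]
    for _ in range(n_steps):
        die = np.random.randint(0, n)
        if np.random.random() < m:
            taxon = np.searchsorted(cum_p, np.random.random())
        else:
            taxon = individuals[np.random.randint(0, n)]
        individuals[die] = taxon
    return individuals


def _local_community(p: np.ndarray, cfg: SimulationConfig, rng) -> np.ndarray:
    """One sample's local composition after zero-sum Moran dynamics."""
    individuals = rng.choice(len(p), size=cfg.local_size, p=p).astype(np.int64)
    cum_p = np.cumsum(p)
    cum_p[-1] = 1.0
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    _moran_kernel(
        individuals, cum_p, cfg.m, cfg.generations * cfg.local_size, kernel_seed
    )
    counts = np.bincount(individuals, minlength=len(p))
    return counts / counts.sum()


def _sequence(composition: np.ndarray, depth: int, rng) -> np.ndarray:
    return rng.multinomial(depth, composition)


def _finalize_table(
    matrix: np.ndarray, taxa, sample_ids, domain: str | None
) -> AbundanceTable:
    taxonomy = None
    if domain is not None:
        taxonomy = pd.DataFrame(
            {"domain": domain, "taxonomy": domain}, index=pd.Index(taxa)
        )
    frame = pd.DataFrame(matrix, index=pd.Index(taxa), columns=list(sample_ids))
    return AbundanceTable(frame, taxonomy)


def simulate_neutral(
    cfg: SimulationConfig, domain: str | None = None
) -> tuple[AbundanceTable, GroundTruth]:
    """Neutral-assembly ASV table plus the exact generating process."""
    if cfg.mode != "neutral":
        cfg = replace(cfg, mode="neutral")
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_taxa, seed=int(rng.integers(0, 2**31 - 1)))
    taxa = [t.name for t in tree.tips()]
    p = logseries_metacommunity(
        cfg.n_taxa, cfg.logseries_x, seed=int(rng.integers(0, 2**31 - 1))
    )
    sample_ids = [_sample_id(d, s) for d in cfg.depths for s in cfg.pore_sizes]
    cols = np.empty((cfg.n_taxa, len(sample_ids)), dtype=np.int64)
    for j in range(len(sample_ids)):
        composition = _local_community(p, cfg, rng)
        cols[:, j] = _sequence(composition, cfg.sequencing_depth, rng)
    gradient = pd.Series(
        np.repeat(depth_gradient(cfg.depths), len(cfg.pore_sizes)),
        index=sample_ids,
        name="E",
    )
    truth = GroundTruth(
        mode="neutral",
        m=cfg.m,
        metacommunity=pd.Series(p, index=taxa, name="p"),
        tree=tree,
        optima=None,
        gradient=gradient,
        config=cfg,
    )
    return _finalize_table(cols, taxa, sample_ids, domain), truth


def _niche_weights(
    p: np.ndarray, optima: np.ndarray, gradient: np.ndarray, sigma: float
) -> np.ndarray:
    """Expected composition per sample under Gaussian environmental filtering."""
    # (taxa, samples) Gaussian match between optimum and environment
    match = np.exp(-((gradient[None, :] - optima[:, None]) ** 2) / (2.0 * sigma**2))
    w = p[:, None] * match
    return w / w.sum(axis=0, keepdims=True)


def simulate_niche(
    cfg: SimulationConfig, tree: TreeNode | None = None, domain: str | None = None
) -> tuple[AbundanceTable, GroundTruth]:
    """Niche-assembly table: phylogenetically conserved optima, Gaussian filter."""
    rng = np.random.default_rng(cfg.seed)
    if tree is None:
        tree = simulate_tree(cfg.n_taxa, seed=int(rng.integers(0, 2**31 - 1)))
    taxa = [t.name for t in tree.tips()]
    if len(taxa) != cfg.n_taxa:
        raise ValueError("tree tip count does not match cfg.n_taxa")
    p = logseries_metacommunity(
        cfg.n_taxa, cfg.logseries_x, seed=int(rng.integers(0, 2**31 - 1))
    )
    optima = brownian_optima(
        tree, cfg.conservatism, seed=int(rng.integers(0, 2**31 - 1))
    )
    sample_ids = [_sample_id(d, s) for d in cfg.depths for s in cfg.pore_sizes]
    gradient = np.repeat(depth_gradient(cfg.depths), len(cfg.pore_sizes))
    expected = _niche_weights(p, optima.to_numpy(), gradient, cfg.sigma)
    if cfg.mode == "mixed":
        expected = (1.0 - cfg.mix_weight) * p[:, None] + cfg.mix_weight * expected
        expected = expected / expected.sum(axis=0, keepdims=True)
    cols = np.empty((cfg.n_taxa, len(sample_ids)), dtype=np.int64)
    for j in range(len(sample_ids)):
        cols[:, j] = _sequence(expected[:, j], cfg.sequencing_depth, rng)
    truth = GroundTruth(
        mode=cfg.mode if cfg.mode in ("niche", "mixed") else "niche",
        m=cfg.m,
        metacommunity=pd.Series(p, index=taxa, name="p"),
        tree=tree,
        optima=optima,
        gradient=pd.Series(gradient, index=sample_ids, name="E"),
        config=cfg,
    )
    return _finalize_table(cols, taxa, sample_ids, domain), truth


def simulate_community(cfg: SimulationConfig, domain: str | None = None):
    """Dispatch on ``cfg.mode``."""
    if cfg.mode == "neutral":
        return simulate_neutral(cfg, domain=domain)
    return simulate_niche(cfg, domain=domain)


# ---------------------------------------------------------------------------
# multi-domain study-scale data set


@dataclass
class StudyCommunity:
    """A full synthetic data set: pooled table, metadata, per-domain truth."""

    table: AbundanceTable
    metadata: SampleMetadata
    truths: dict[str, GroundTruth] = field(default_factory=dict)


def simulate_study(
    seed: int = 0,
    mode: str = "neutral",
    n_taxa: Mapping[str, int] = STUDY_TAXA,
    **overrides,
) -> StudyCommunity:
    """Simulate bacteria + archaea + microeukaryotes over the depth profile.

    Each domain gets its own phylogeny and metacommunity; tables are
    concatenated with domain-prefixed taxon ids so the pooled table can
    feed cross-domain networks while per-domain slices remain exact.
    """
    root = np.random.SeedSequence(seed)
    tables, truths = [], {}
    for domain, child in zip(sorted(n_taxa), root.spawn(len(n_taxa))):
        cfg = SimulationConfig(
            n_taxa=n_taxa[domain],
            mode=mode,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            **overrides,
        )
        table, truth = simulate_community(cfg, domain=domain)
        prefix = domain[:3]
        renamer = {t: f"{prefix}_{t}" for t in table.taxon_ids}
        table.counts.index = [renamer[t] for t in table.counts.index]
        table.taxonomy.index = table.counts.index
        for tip in truth.tree.tips():
            tip.name = renamer[tip.name]
        truth.metacommunity.index = table.counts.index
        if truth.optima is not None:
            truth.optima.index = table.counts.index
        tables.append(table)
        truths[domain] = truth
    counts = pd.concat([t.counts for t in tables])
    taxonomy = pd.concat([t.taxonomy for t in tables])
    any_cfg = next(iter(truths.values())).config
    meta = simulate_metadata(
        any_cfg.depths, any_cfg.pore_sizes, seed=int(root.generate_state(1)[0] % 2**31)
    )
    return StudyCommunity(AbundanceTable(counts, taxonomy), meta, truths)
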