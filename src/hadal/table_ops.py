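"""Deterministic preprocessing of ASV count tables.

Covers the standard amplicon-pipeline steps applied before any
statistics: removal of low-prevalence / low-count ASVs, rarefaction to a
common depth, relative-abundance and log transforms, partitioning of
taxa into abundant / intermediate / rare classes, and assignment of
water-column zone labels (upper bathypelagic vs hadal) from depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)

#: depth (m) at or below which a sample is called hadal (HW)
HADAL_CUTOFF_M = 6000.0

#: default rarefaction depth (reads per sample)
RAREFACTION_DEPTH = 16_000


@dataclass
class RarefiedTable(AbundanceTable):
    """An :class:`AbundanceTable` whose columns all sum to ``depth``."""

    depth: int = 0
    seed: int | None = None


@dataclass
class AbundancePartition:
    """Per-taxon abundance class with the thresholds that produced it."""

    classes: pd.Series  # taxon -> {"abundant", "intermediate", "rare"}
    abundant_cut: float
    rare_cut: float

    def taxa(self, cls: str) -> list[str]:
        return list(self.classes.index[self.classes == cls])


def filter_asvs(
    table: AbundanceTable, min_samples: int = 2, min_total: int = 5
) -> AbundanceTable:
    """Drop ASVs seen in fewer than ``min_samples`` samples or with fewer
    than ``min_total`` reads in total.

    Both conditions must hold for a taxon to be retained.  Idempotent;
    the sample set is unchanged.
    """
    prevalence = (table.counts > 0).sum(axis=1)
    totals = table.counts.sum(axis=1)
    keep = (prevalence >= min_samples) & (totals >= min_total)
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("ASV filtering removed every taxon")
    if removed:
        logger.info("filter_asvs removed %d of %d taxa", removed, table.n_taxa)
    return table.subset_taxa(table.counts.index[keep])


def rarefy(
    table: AbundanceTable, depth: int = RAREFACTION_DEPTH, seed: int | None = None
) -> RarefiedTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Uses multivariate hypergeometric draws, so rarefied counts never
    exceed the originals and zeros stay zero.  Samples with fewer than
    ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums.index[sums >= depth]
    dropped = set(table.sample_ids) - set(keep)
    if dropped:
        logger.warning("dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, sorted(dropped))
    if len(keep) == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = {}
    for sample in keep:
        col = table.counts[sample].to_numpy()
        if col.sum() == depth:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    frame = pd.DataFrame(out, index=table.counts.index)
    return RarefiedTable(frame, table.taxonomy, depth=depth, seed=seed)


def partition_abundance(
    table: AbundanceTable, abundant_cut: float = 0.01, rare_cut: float = 1e-4
) -> AbundancePartition:
    """Classify taxa by mean relative abundance.

    ``>= abundant_cut`` -> abundant, ``< rare_cut`` -> rare, otherwise
    intermediate.  Defaults follow the common 1% / 0.01% convention.
    """
    if rare_cut >= abundant_cut:
        raise ValueError("rare_cut must be below abundant_cut")
    mean_rel = table.relative().mean(axis=1)
    classes = pd.Series("intermediate", index=mean_rel.index, name="class")
    classes[mean_rel >= abundant_cut] = "abundant"
    classes[mean_rel < rare_cut] = "rare"
    return AbundancePartition(classes, abundant_cut, rare_cut)


def zone_samples(meta: SampleMetadata, hadal_cutoff: float = HADAL_CUTOFF_M) -> pd.Series:
    """Label each sample UBW (above the cutoff) or HW (at or below it).

    Depths exactly at the cutoff are hadal.
    """
    if "depth" not in meta.data.columns:
        raise ValueError("metadata has no depth column")
    depth = meta.data["depth"]
    if depth.isna().any():
        bad = meta.data.index[depth.isna()].tolist()
        raise ValueError(f"missing depth for sample(s): {bad}")
    return pd.Series(
        np.where(depth >= hadal_cutoff, "HW", "UBW"), index=meta.data.index, name="zone"
    )


def log_relative(table: AbundanceTable) -> pd.DataFrame:
    """ln(relative abundance + pseudocount), the input to Pearson networks.

    The pseudocount is half the smallest nonzero relative abundance in
    the whole table, so the transform is defined at 0 without dwarfing
    genuine low abundances.  Scaling all counts in a sample leaves its
    transformed column unchanged (compositional invariance).
    """
    rel = table.relative().to_numpy(dtype=float)
    nonzero = rel[rel > 0]
    if nonzero.size == 0:
        raise ValueError("table has no nonzero counts")
    eps = nonzero.min() / 2.0
    return pd.DataFrame(
        np.log(rel + eps), index=table.counts.index, columns=table.counts.columns
    )
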