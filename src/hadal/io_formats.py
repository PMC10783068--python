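"""Reading and writing the external representations of the pipeline.

Everything downstream operates on in-memory domain objects: an
:class:`AbundanceTable` (taxon x sample integer counts with optional
taxonomy), a :class:`SampleMetadata` table (the environmental context of
each water sample), a rooted phylogeny (a ``skbio.TreeNode``), and
co-occurrence networks (``networkx.Graph``).  This module is the only
place where files are touched.

Formats supported: tab-delimited tables (UTF-8, header row), Newick
trees, GraphML and edge-list TSV for networks.  Identifiers are opaque,
case-sensitive strings throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

DOMAINS = ("bacteria", "archaea", "microeukaryote")

#: metadata columns interpreted as numeric environmental measurements
ENV_COLUMNS = (
    "depth",
    "temperature",
    "salinity",
    "DO",
    "pH",
    "PO4",
    "NO3",
    "NO2",
    "NH4",
    "SiO3",
)


class FormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {kind} identifier(s): {dup}")


@dataclass
class AbundanceTable:
    """Taxon-by-sample count matrix with optional taxonomy labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, taxa as rows and samples as
        columns.  Row and column labels are the taxon and sample ids.
    taxonomy
        Optional DataFrame indexed by taxon id with columns ``domain``
        (one of ``bacteria``/``archaea``/``microeukaryote``) and
        ``taxonomy`` (a lineage string).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "taxon")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at taxon {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values)):
            raise FormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.counts.sum(axis=0)
        if (sums == 0).any():
            bad = sums.index[sums == 0].tolist()
            raise FormatError(f"all-zero sample column(s): {bad}")
        return self.counts / sums

    def domains(self) -> pd.Series | None:
        if self.taxonomy is None or "domain" not in self.taxonomy:
            return None
        return self.taxonomy["domain"].reindex(self.counts.index)

    def subset_taxa(self, taxa) -> "AbundanceTable":
        taxonomy = None
        if self.taxonomy is not None:
            taxonomy = self.taxonomy.loc[self.taxonomy.index.intersection(taxa)]
        return AbundanceTable(self.counts.loc[list(taxa)].copy(), taxonomy)

    def subset_samples(self, samples) -> "AbundanceTable":
        return AbundanceTable(self.counts[list(samples)].copy(), self.taxonomy)


@dataclass
class SampleMetadata:
    """Per-sample environmental context.

    ``data`` is indexed by sample id; expected columns are the numeric
    environmental measurements in :data:`ENV_COLUMNS` plus ``pore_size``
    (µm, 0.22 = free-living, 3.0 = particle-associated) and, once
    assigned, a ``zone`` label (``UBW`` upper-bathypelagic-and-above,
    ``HW`` hadal).  Only ``depth`` is strictly required.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        self.data.index = self.data.index.astype(str)
        if "depth" in self.data.columns:
            depth = pd.to_numeric(self.data["depth"], errors="coerce")
            if depth.isna().any():
                bad = self.data.index[depth.isna()].tolist()
                raise FormatError(f"non-numeric depth for sample(s): {bad}")
            if (depth <= 0).any():
                bad = self.data.index[depth <= 0].tolist()
                raise FormatError(f"non-positive depth for sample(s): {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, samples) -> None:
        missing = set(map(str, samples)) - set(self.data.index)
        if missing:
            raise FormatError(f"samples without metadata rows: {sorted(missing)}")


# ---------------------------------------------------------------------------
# abundance tables


def read_abundance_table(path, orientation: str = "taxa-rows") -> AbundanceTable:
    """Read a tab-delimited count table.

    ``orientation`` must be declared by the caller (``taxa-rows`` or
    ``samples-rows``); no auto-detection is attempted because square
    tables are ambiguous.  Columns named ``domain`` or ``taxonomy`` are
    split off into the taxonomy mapping.
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise FormatError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index.name = None
    _check_unique(frame.index, "row")
    _check_unique(frame.columns, "column")
    if orientation == "samples-rows":
        frame = frame.T
    taxonomy = None
    tax_cols = [c for c in ("domain", "taxonomy") if c in frame.columns]
    if tax_cols:
        taxonomy = frame[tax_cols].copy()
        frame = frame.drop(columns=tax_cols)
    try:
        numeric = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count cell in {path}: {exc}") from exc
    return AbundanceTable(numeric, taxonomy)


def write_abundance_table(table: AbundanceTable, path) -> None:
    out = table.counts.copy()
    if table.taxonomy is not None:
        out = out.join(table.taxonomy)
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# trees


def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if any(name is None for name in tips):
        raise FormatError("tree contains unnamed tips")
    _check_unique(tips, "tip")
    tree.length = None  # a stem edge above the root carries no information
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError(f"negative branch length on node {node.name!r}")
    if n_missing:
        warnings.warn(
            f"{n_missing} branch length(s) missing; treated as 0", stacklevel=3
        )
    return tree


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def tree_from_newick(newick: str) -> TreeNode:
    import io

    tree = TreeNode.read(io.StringIO(newick), format="newick")
    return _validate_tree(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# networks


def write_network(net: nx.Graph, path, format: str = "edgelist") -> None:
    """Write a co-occurrence network.

    ``edgelist`` emits a TSV with columns source/target/correlation/sign;
    ``graphml`` preserves node attributes (domain, degree, betweenness,
    module) for import into network viewers.
    """
    if net.number_of_nodes() == 0:
        raise FormatError("empty network")
    if format == "edgelist":
        rows = [
            {
                "source": u,
                "target": v,
                "correlation": data.get("r", np.nan),
                "sign": "+" if data.get("r", 0.0) >= 0 else "-",
            }
            for u, v, data in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "correlation", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        nx.write_graphml(net, str(path))
    else:
        raise FormatError(f"unknown network format {format!r}")


def read_network(path) -> nx.Graph:
    return nx.read_graphml(str(path))
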