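"""Bacterial community tables: rarefaction, alpha diversity, dissimilarity.

The pipeline starts from an ASV (amplicon sequence variant) count table with
taxonomy strings and a rooted phylogeny; upstream read processing is out of
scope.  Samples are rarefied to a common depth (7,000 reads by default, the
smallest library in the study design this emulates) by exact subsampling
without replacement; richness and Faith's phylogenetic diversity are offered
on both rarefied and raw counts, and Bray-Curtis dissimilarity serves both
the community and the molecular occurrence matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class CommunityTable:
    """Taxa x samples counts with optional taxonomy and sample metadata link."""

    counts: pd.DataFrame  # taxa rows, sample columns, non-negative ints
    taxonomy: pd.Series | None = None  # taxon -> lineage string
    sample_sites: pd.Series | None = None  # sample -> site
    rarefied_depth: int | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts / totals


@dataclass
class Phylogeny:
    """Rooted tree whose tips are taxon ids; branch lengths non-negative."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, path: str | Path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    @classmethod
    def from_string(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def tip_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}


def rarefy(t: CommunityTable, depth: int = 7000, seed: int = 0) -> CommunityTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning
    rather than scaled.  Reproducible under a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for sample in t.samples:
        col = t.counts[sample].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            logger.warning("sample %s has %d < %d reads; dropped", sample, total, depth)
            continue
        if total == depth:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    if not out:
        raise ValueError("no sample reaches the rarefaction depth")
    counts = pd.DataFrame(out, index=t.counts.index)
    return CommunityTable(
        counts=counts,
        taxonomy=t.taxonomy,
        sample_sites=None if t.sample_sites is None else t.sample_sites.loc[list(out)],
        rarefied_depth=depth,
    )


def richness(t: CommunityTable) -> pd.Series:
    """Observed taxa per sample (count > 0)."""
    return (t.counts > 0).sum(axis=0).rename("richness")


def faith_pd(t: CommunityTable, phylogeny: Phylogeny) -> pd.Series:
    """Faith's phylogenetic diversity ("PD whole tree") per sample.

    The total branch length of the minimal rooted subtree spanning the
    sample's observed taxa, including the connection to the root: an edge
    contributes iff the subtree below it contains at least one observed
    taxon.  Errors if any table taxon is missing from the tree.
    """
    tree = phylogeny.tree
    tips = phylogeny.tip_labels()
    missing = [tx for tx in t.taxa if tx not in tips]
    if missing:
        raise KeyError(f"taxa absent from the tree: {missing[:10]}")

    # Postorder once: per node, the set of table-taxon row indices below it.
    taxon_row = {tx: i for i, tx in enumerate(t.taxa)}
    present = t.counts.to_numpy() > 0  # taxa x samples
    n_samples = present.shape[1]
    pd_values = np.zeros(n_samples)
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(n_samples, dtype=bool)
            row = taxon_row.get(node.taxon.label)
            if row is not None:
                mask = present[row]
        else:
            mask = np.zeros(n_samples, dtype=bool)
            for ch in node.child_nodes():
                mask |= below[id(ch)]
        below[id(node)] = mask
        if node.parent_node is not None and node.edge.length:
            pd_values += np.where(mask, node.edge.length, 0.0)
    return pd.Series(pd_values, index=t.samples, name="faith_pd")


def bray_curtis(data: pd.DataFrame | CommunityTable, presence: bool = False) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); with ``presence=True`` the
    data are binarized first (Sorensen form).  Errors on a pair of all-zero
    samples, for which the quotient is undefined.
    """
    if isinstance(data, CommunityTable):
        data = data.counts
    if data.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = data.to_numpy(dtype=float).T  # samples x features
    if presence:
        x = (x > 0).astype(float)
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [c for c, z in zip(data.columns, zero) if z]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=data.columns, columns=data.columns)


def read_asv_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a taxa-rows x sample-columns count TSV."""
    return pd.read_csv(path, sep=sep, index_col=0)
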