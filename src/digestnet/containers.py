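"""Central data containers: OTU table, taxonomy map, sample metadata.

The OTU table is the pipeline's central object: an integer count matrix with
samples on rows and OTUs (97 %-identity 16S clusters, acting as species
proxies) on columns.  All downstream stages — rarefaction, diversity,
prevalence classification, correlation networks — consume this container or a
row-stochastic relative-abundance view of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")

#: Numeric covariates every metadata table must carry (units: pH unitless,
#: the rest mg per litre).
REQUIRED_COVARIATES = ("pH", "COD", "NH4N", "phosphate")

UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when an input object violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class OtuTable:
    """Samples x OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with OTU ids as columns. Values must
        be non-negative integers; order of rows and columns is preserved
        from input and never silently changed.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "OTU")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                    bad = np.argwhere(values != np.floor(values))
                    if bad.size:
                        i, j = bad[0]
                        raise ValidationError(
                            "non-integer count at sample "
                            f"{self.counts.index[i]!r}, OTU {self.counts.columns[j]!r}"
                        )
                    raise ValidationError("non-finite counts in table")
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at sample {self.counts.index[i]!r}, "
                    f"OTU {self.counts.columns[j]!r}"
                )

    # -- basic views ----------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def filter_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)].copy())

    def filter_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(self.counts[list(otu_ids)].copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage (phylum..genus), with explicit placeholders.

    Missing ranks are stored as ``"unclassified"``; :func:`digestnet.transforms.
    aggregate_taxa` pools those under ``unclassified_<parent>`` labels.
    """

    lineages: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, str]] = {}
        for otu, lin in self.lineages.items():
            entry = {}
            for rank in RANKS:
                label = lin.get(rank, UNCLASSIFIED)
                if label is None or str(label).strip() == "":
                    label = UNCLASSIFIED
                entry[rank] = str(label)
            clean[otu] = entry
        self.lineages = clean

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def rank_of(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineages[otu_id][rank]

    def missing_from(self, table: OtuTable) -> list[str]:
        """OTUs present in *table* but absent from this map."""
        return [o for o in table.otu_ids if o not in self.lineages]


@dataclass
class SampleMetadata:
    """Per-sample environmental and design covariates.

    Required numeric columns: pH, COD, NH4N, phosphate. Optional label
    columns: location, substrate, cluster.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COVARIATES if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        _check_unique(self.frame.index, "sample")
        for col in REQUIRED_COVARIATES:
            vals = pd.to_numeric(self.frame[col], errors="coerce")
            self.frame[col] = vals
        if (self.frame["pH"].dropna() < 0).any() or (self.frame["pH"].dropna() > 14).any():
            raise ValidationError("pH outside [0, 14]")
        for col in ("COD", "NH4N", "phosphate"):
            if (self.frame[col].dropna() < 0).any():
                raise ValidationError(f"negative values in {col}")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def covariates(self) -> pd.DataFrame:
        return self.frame[list(REQUIRED_COVARIATES)].copy()

    def cluster_labels(self) -> pd.Series:
        if "cluster" not in self.frame.columns:
            raise ValidationError("metadata has no 'cluster' column")
        return self.frame["cluster"]

    def align_to(self, table: OtuTable) -> "SampleMetadata":
        """Restrict to the table's samples; unmatched ids raise, never drop."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing}")
        return SampleMetadata(self.frame.loc[table.sample_ids].copy())


def validate_tree(tree, table: OtuTable | None = None):
    """Validate a rooted skbio TreeNode as an OTU phylogeny.

    Checks leaf-name uniqueness and non-negative branch lengths; when a table
    is given, checks that every OTU is a leaf of the tree.
    """
    names = [t.name for t in tree.tips()]
    _check_unique(names, "tree leaf")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    if table is not None:
        leaf_set = set(names)
        missing = [o for o in table.otu_ids if o not in leaf_set]
        if missing:
            raise ValidationError(f"OTUs missing from tree: {missing}")
    return tree
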