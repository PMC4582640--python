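"""Table transforms: rarefaction, relative abundance, taxonomic aggregation."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import RANKS, UNCLASSIFIED, OtuTable, TaxonomyMap, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "relative_abundance", "aggregate_taxa"]


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly *depth* reads without replacement.

    Each retained sample's counts are drawn from a multivariate
    hypergeometric distribution conditional on its original counts, so the
    expected rarefied count of an OTU is ``depth * original proportion``.
    Samples with fewer than *depth* total reads are dropped with a logged
    warning (never padded). Column identity and order are preserved.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    if len(keep) == 0:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds every sample total (max {totals.max()})"
        )
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    rows = []
    for s in keep:
        row = table.counts.loc[s].to_numpy(dtype=np.int64)
        rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(np.array(rows, dtype=np.int64), index=list(keep), columns=table.otu_ids)
    return OtuTable(out)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Row-stochastic relative-abundance view (rows sum to 1).

    Returned as a plain DataFrame: abundances are a read-only product and
    are never written back into an :class:`OtuTable`.
    """
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
    return table.counts.div(totals, axis=0)


def aggregate_taxa(
    table: OtuTable,
    tax: TaxonomyMap,
    rank: str,
    permissive: bool = False,
) -> OtuTable:
    """Sum counts over OTUs sharing a taxon label at *rank*.

    Unclassified OTUs are pooled under ``unclassified_<parent>`` where
    parent is the most resolved classified rank above *rank*. OTUs absent
    from the taxonomy raise unless *permissive* pools them as unclassified.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    missing = tax.missing_from(table)
    if missing and not permissive:
        raise ValidationError(f"OTUs absent from taxonomy: {missing}")
    rank_idx = RANKS.index(rank)
    labels = []
    for otu in table.otu_ids:
        if otu not in tax:
            labels.append(f"{UNCLASSIFIED}_unknown")
            continue
        lin = tax.lineages[otu]
        label = lin[rank]
        if label == UNCLASSIFIED:
            parent = "root"
            for r in RANKS[:rank_idx][::-1]:
                if lin[r] != UNCLASSIFIED:
                    parent = lin[r]
                    break
            label = f"{UNCLASSIFIED}_{parent}"
        labels.append(label)
    grouped = table.counts.T.groupby(pd.Index(labels, name=rank), sort=False).sum().T
    return OtuTable(grouped)
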