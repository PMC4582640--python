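"""Alpha diversity (observed OTUs, Chao1, Shannon, Simpson) and weighted
UniFrac beta diversity.

Alpha indices use the standard estimators:

* Chao1: ``S_obs + F1^2 / (2 F2)`` where F1/F2 are singleton/doubleton
  counts, with the bias-corrected ``S_obs + F1 (F1 - 1) / 2`` fallback when
  no doubletons are observed.
* Shannon: ``-sum p_i log p_i`` (base recorded in the output; natural log by
  default, base 2 available for comparison with older toolchains).
* Simpson: reported as the Gini–Simpson form ``1 - sum p_i^2``; the raw
  ``sum p_i^2`` is also exposed.

Weighted UniFrac weights every branch of the OTU phylogeny by the absolute
difference in the fraction of each community's reads descending from it; the
normalized variant divides by the abundance-weighted maximum so distances
lie in [0, 1].  Computation is delegated to scikit-bio.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix

from .containers import OtuTable, ValidationError, validate_tree

logger = logging.getLogger(__name__)

__all__ = ["alpha_diversity", "weighted_unifrac"]


def _chao1(row: np.ndarray) -> float:
    s_obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(table: OtuTable, shannon_base: float = np.e) -> pd.DataFrame:
    """Per-sample diversity profile.

    Returns a DataFrame indexed by sample with columns ``observed_otus``,
    ``chao1``, ``shannon``, ``shannon_base``, ``simpson`` (Gini–Simpson) and
    ``dominance`` (raw ``sum p_i^2``). Warns when sample depths are unequal
    (a rarefied table is the intended input).
    """
    totals = table.sample_totals()
    if (totals == 0).any():
        raise ValidationError(f"empty sample(s): {list(totals[totals == 0].index)}")
    if totals.nunique() > 1:
        warnings.warn(
            "alpha_diversity: sample depths are unequal; indices are depth-sensitive, "
            "consider rarefying first",
            stacklevel=2,
        )
    records = []
    for s in table.sample_ids:
        row = table.counts.loc[s].to_numpy(dtype=np.int64)
        p = row[row > 0] / row.sum()
        shannon = float(-(p * (np.log(p) / np.log(shannon_base))).sum())
        dominance = float((p**2).sum())
        records.append(
            {
                "observed_otus": int((row > 0).sum()),
                "chao1": _chao1(row),
                "shannon": shannon,
                "shannon_base": shannon_base,
                "simpson": 1.0 - dominance,
                "dominance": dominance,
            }
        )
    return pd.DataFrame(records, index=table.sample_ids)


def weighted_unifrac(table: OtuTable, tree, normalized: bool = True) -> DistanceMatrix:
    """Pairwise weighted UniFrac distances between all samples.

    Parameters
    ----------
    tree
        Rooted skbio ``TreeNode`` whose leaves cover every OTU in *table*.
        Unrooted (multifurcating at root with > 2 children) input is
        accepted; a notice is logged since the root placement is recorded
        with the result.
    normalized
        Divide by the abundance-weighted maximum distance so values lie in
        [0, 1] (default, matching the common toolchain default).
    """
    validate_tree(tree, table)
    if len(tree.children) > 2:
        logger.info("weighted_unifrac: input tree root is multifurcating; using it as-is")
    metric = "weighted_unifrac"
    counts = table.counts.to_numpy(dtype=np.int64)
    dm = skbio.diversity.beta_diversity(
        metric,
        counts,
        ids=[str(s) for s in table.sample_ids],
        taxa=[str(o) for o in table.otu_ids],
        tree=tree,
        normalized=normalized,
    )
    return dm
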