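"""Prevalence-based population classification.

Definitions (all prevalence comparisons are STRICT inequalities on the
exact fraction, never on a rounded sample count):

* core — present in more than 90 % of all samples (43 samples => at least
  40, since 39/43 = 0.907 > 0.9 requires >38.7, i.e. >= 39);
* sub-core (per cluster) — exceeds the 90 % rule within one sample cluster
  but is not globally core;
* cosmopolitan — present in more than half of the samples; the node pool
  for co-occurrence networks;
* dominant — pooled mean relative abundance above 1 %;
* specific — present in exactly one cluster.

Presence means count >= 1 (override via ``min_count``) in whichever table
is supplied; the rarefied table is the intended default input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OtuTable, ValidationError

__all__ = [
    "prevalence",
    "classify_core",
    "classify_subcore",
    "classify_cosmopolitan",
    "classify_dominant",
    "classify_specific",
    "cluster_summary",
    "pool_cluster_means",
    "prevalence_report",
]


def prevalence(table: OtuTable, min_count: int = 1) -> pd.DataFrame:
    """Per-OTU presence count and prevalence fraction."""
    present = (table.counts >= min_count).sum(axis=0)
    return pd.DataFrame(
        {"n_present": present.astype(int), "prevalence": present / table.n_samples}
    )


def classify_core(table: OtuTable, threshold: float = 0.90, min_count: int = 1) -> set:
    """OTUs (or taxa, after aggregation) strictly above *threshold* prevalence."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    prev = prevalence(table, min_count)["prevalence"]
    return set(prev.index[prev > threshold])


def classify_subcore(
    table: OtuTable,
    cluster_labels,
    threshold: float = 0.90,
    min_count: int = 1,
) -> dict[str, set]:
    """Per-cluster sub-core sets: above-threshold prevalence within the
    cluster, global core members excluded by construction."""
    labels = pd.Series(list(cluster_labels), index=table.sample_ids)
    if labels.isna().any():
        raise ValidationError(
            f"unlabeled sample(s): {list(labels.index[labels.isna()])}"
        )
    core = classify_core(table, threshold, min_count)
    out: dict[str, set] = {}
    for cluster in labels.unique():
        sub = table.filter_samples(labels.index[labels == cluster])
        out[cluster] = classify_core(sub, threshold, min_count) - core
    return out


def classify_cosmopolitan(table: OtuTable, threshold: float = 0.5, min_count: int = 1) -> set:
    """OTUs present in strictly more than *threshold* of the sample group."""
    prev = prevalence(table, min_count)["prevalence"]
    return set(prev.index[prev > threshold])


def classify_dominant(abundances: pd.DataFrame, threshold: float = 0.01) -> set:
    """Taxa whose pooled mean relative abundance strictly exceeds *threshold*."""
    means = abundances.mean(axis=0)
    return set(means.index[means > threshold])


def classify_specific(table: OtuTable, cluster_labels, min_count: int = 1) -> dict[str, set]:
    """Cluster-exclusive OTUs: present in one cluster, absent from all others."""
    labels = pd.Series(list(cluster_labels), index=table.sample_ids)
    present_by_cluster = {}
    for cluster in labels.unique():
        sub = table.filter_samples(labels.index[labels == cluster])
        present_by_cluster[cluster] = set(
            prevalence(sub, min_count).index[prevalence(sub, min_count)["n_present"] > 0]
        )
    out = {}
    for cluster, present in present_by_cluster.items():
        others = set().union(
            *(v for k, v in present_by_cluster.items() if k != cluster)
        ) if len(present_by_cluster) > 1 else set()
        out[cluster] = present - others
    return out


def pool_cluster_means(means, ns) -> float:
    """Sample-size-weighted pooled mean of per-cluster means:
    ``(n_1 m_1 + ... + n_k m_k) / sum(n)``. The pooled mean of per-sample
    values equals this weighted combination exactly."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    return float((means * ns).sum() / ns.sum())


def cluster_summary(abundances: pd.DataFrame, cluster_labels) -> pd.DataFrame:
    """Per-taxon mean +/- SEM within each cluster and pooled over all samples.

    Means are arithmetic means of per-sample relative abundances; SEM is
    sd/sqrt(n) (ddof=1). The pooled mean equals the sample-size-weighted
    mean of the cluster means by construction.
    """
    labels = pd.Series(list(cluster_labels), index=abundances.index)
    if labels.isna().any():
        raise ValidationError("every sample needs a cluster label")
    clusters = list(labels.unique())
    if any((labels == c).sum() < 1 for c in clusters):
        raise ValidationError("each cluster needs at least one sample")
    out = pd.DataFrame(index=abundances.columns)
    for c in clusters:
        sub = abundances.loc[labels == c]
        out[f"mean_{c}"] = sub.mean(axis=0)
        out[f"sem_{c}"] = sub.std(axis=0, ddof=1) / np.sqrt(len(sub))
    out["mean_pooled"] = abundances.mean(axis=0)
    out["sem_pooled"] = abundances.std(axis=0, ddof=1) / np.sqrt(len(abundances))
    return out


@dataclass
class PrevalenceReport:
    """Table-1-style classification report (one row per OTU/taxon)."""

    frame: pd.DataFrame


def prevalence_report(
    table: OtuTable,
    abundances: pd.DataFrame,
    cluster_labels,
    core_threshold: float = 0.90,
    cosmopolitan_threshold: float = 0.5,
    dominant_threshold: float = 0.01,
) -> PrevalenceReport:
    """Classify every OTU and summarise abundance per cluster and pooled.

    Class precedence: ``core`` (implies cosmopolitan) > ``sub-core:<c>`` >
    ``specific:<c>`` > ``cosmopolitan`` > ``none``.
    """
    prev = prevalence(table)
    core = classify_core(table, core_threshold)
    subcore = classify_subcore(table, cluster_labels, core_threshold)
    cosmo = classify_cosmopolitan(table, cosmopolitan_threshold)
    dominant = classify_dominant(abundances, dominant_threshold)
    specific = classify_specific(table, cluster_labels)
    summary = cluster_summary(abundances, cluster_labels)

    def classify(otu) -> str:
        if otu in core:
            return "core"
        for c, members in subcore.items():
            if otu in members:
                return f"sub-core:{c}"
        for c, members in specific.items():
            if otu in members:
                return f"specific:{c}"
        if otu in cosmo:
            return "cosmopolitan"
        return "none"

    frame = summary.copy()
    frame.insert(0, "n_present", prev["n_present"])
    frame.insert(1, "prevalence", prev["prevalence"])
    frame.insert(2, "class", [classify(o) for o in frame.index])
    frame.insert(3, "dominant", [o in dominant for o in frame.index])
    return PrevalenceReport(frame)
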