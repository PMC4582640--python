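"""Ordination and inference: PCoA, jackknifed UPGMA clustering, PerMANOVA,
partial Mantel tests, RDA-based variance partitioning, and per-taxon
environment/group tests.

Permutation tests all use the (count + 1) / (n_perm + 1) p-value estimator,
so reported p-values are never exactly zero, and accept an explicit seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import OtuTable, ValidationError
from .diversity import weighted_unifrac
from .transforms import rarefy

__all__ = [
    "Ordination",
    "PermutationTestResult",
    "VPAResult",
    "pcoa",
    "permanova",
    "partial_mantel",
    "variance_partitioning",
    "taxon_env_correlation",
    "compare_groups",
    "upgma_jackknife",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------
@dataclass
class Ordination:
    """PCoA result: coordinates scaled by sqrt(eigenvalue), axes ordered by
    decreasing eigenvalue. Negative eigenvalues (non-Euclidean input) are
    reported, never hidden; proportions explained are taken over the
    positive eigenvalues only."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str
    extras: dict = field(default_factory=dict)


@dataclass
class VPAResult:
    """Variance partitioning over named predictor sets.

    ``fractions`` maps each Venn region (frozenset of set names) to its
    adjusted-R^2 share; negative adjusted fractions are legitimate and
    listed in ``negative_fractions``. All fractions sum to
    ``total_adjusted_r2`` by construction (inclusion-exclusion identity).
    """

    fractions: dict[frozenset, float]
    total_adjusted_r2: float
    residual: float
    adjusted_r2_by_union: dict[frozenset, float]
    raw_r2_by_union: dict[frozenset, float]

    @property
    def negative_fractions(self) -> dict[frozenset, float]:
        return {k: v for k, v in self.fractions.items() if v < 0}

    def unique(self, name: str) -> float:
        return self.fractions[frozenset([name])]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------
def pcoa(d: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centered matrix ``-1/2 J D^2 J`` with
    ``J = I - 11'/n``; coordinates are eigenvectors scaled by the square
    root of their (positive) eigenvalues.
    """
    dm = np.asarray(d.data, dtype=float)
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValidationError("distance matrix is not symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-12 if eigvals.max() > 0 else eigvals > 0
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    proportion = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


# ---------------------------------------------------------------------------
# PerMANOVA
# ---------------------------------------------------------------------------
def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    groups, inverse = np.unique(labels, return_inverse=True)
    g = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for k in range(g):
        idx = np.flatnonzero(inverse == k)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def permanova(
    d: DistanceMatrix,
    grouping,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
    use_pcoa_scores: bool = False,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F follows Anderson's distance-based formulation computed
    directly from squared inter-sample distances; *use_pcoa_scores* instead
    computes Euclidean distances on the positive-eigenvalue PCoA scores
    first (the two agree whenever the input is fully Euclidean).
    With ``exhaustive=True`` the null is enumerated over all ``n!`` sample
    relabelings and the p-value is the exact proportion with
    ``F_perm >= F_obs`` (observed ordering included).
    """
    labels = np.asarray(list(grouping))
    if d.shape[0] != labels.size:
        raise ValidationError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("PerMANOVA needs at least two groups")
    if counts.max() == labels.size:
        raise ValidationError("a single group covers all samples")
    if use_pcoa_scores:
        ordn = pcoa(d)
        pts = ordn.coordinates.to_numpy()
        diff = pts[:, None, :] - pts[None, :, :]
        d2 = (diff**2).sum(axis=2)
    else:
        d2 = np.asarray(d.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels)
    if exhaustive:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(labels.size)):
            total += 1
            if _pseudo_f(d2, labels[list(perm)]) >= f_obs - 1e-12:
                hits += 1
        return PermutationTestResult(
            statistic=f_obs, p_value=hits / total, n_permutations=total, seed=None,
            method="permanova-exhaustive",
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(labels)) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(
        statistic=f_obs, p_value=p, n_permutations=n_perm, seed=seed, method="permanova"
    )


# ---------------------------------------------------------------------------
# partial Mantel
# ---------------------------------------------------------------------------
def _upper(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    return mat[np.triu_indices(n, k=1)]


def _residualize(y: np.ndarray, controls: np.ndarray | None) -> np.ndarray:
    """Residuals of y on [1, controls] (matrix-regression convention)."""
    n = y.shape[0]
    x = np.ones((n, 1)) if controls is None else np.column_stack([np.ones(n), controls])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_mantel(
    d_comm: DistanceMatrix,
    d_focal: DistanceMatrix,
    d_controls: list[DistanceMatrix] | tuple = (),
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "pearson",
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Partial Mantel correlation between two distance matrices.

    The upper triangles of community and focal matrices are residualized on
    the control triangles (Legendre's matrix-regression convention), and r
    is the Pearson correlation of the residuals; ``method="spearman"``
    ranks all triangles first.  The permutation unit is whole samples: the
    focal matrix's rows/columns are permuted jointly, preserving its
    internal structure, and the p-value is upper-tailed on r.  An empty
    control list reduces to the simple Mantel test.
    """
    mats = [d_comm, d_focal, *d_controls]
    ids0 = tuple(d_comm.ids)
    for m in mats[1:]:
        if tuple(m.ids) != ids0:
            raise ValidationError("all distance matrices must share the same sample order")
    arrs = [np.asarray(m.data, dtype=float) for m in mats]
    n = arrs[0].shape[0]
    tri = [_upper(a) for a in arrs]
    if method == "spearman":
        tri = [ss.rankdata(t) for t in tri]
        focal_full = _square_from_upper(tri[1], n)
    elif method == "pearson":
        focal_full = arrs[1]
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    for k, t in enumerate(tri[:2]):
        if np.std(t) == 0:
            raise ValidationError(f"distance matrix {k} has zero variance")
    controls = np.column_stack(tri[2:]) if len(tri) > 2 else None
    if controls is not None:
        design = np.column_stack([np.ones(controls.shape[0]), controls])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError("singular control set (duplicate or constant controls)")
    res_comm = _residualize(tri[0], controls)
    # projection applied to permuted focal triangles is identical, so build it once
    x = (
        np.ones((res_comm.size, 1))
        if controls is None
        else np.column_stack([np.ones(res_comm.size), controls])
    )
    proj = np.eye(res_comm.size) - x @ np.linalg.pinv(x)

    iu = np.triu_indices(n, k=1)

    def stat(order: np.ndarray) -> float:
        focal_tri = focal_full[np.ix_(order, order)][iu]
        res_focal = proj @ focal_tri
        denom = np.linalg.norm(res_comm) * np.linalg.norm(res_focal)
        if denom == 0:
            return 0.0
        return float(res_comm @ res_focal / denom)

    identity = np.arange(n)
    r_obs = stat(identity)
    if exhaustive:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if stat(np.asarray(perm)) >= r_obs - 1e-12:
                hits += 1
        return PermutationTestResult(
            statistic=r_obs, p_value=hits / total, n_permutations=total, seed=None,
            method=f"partial-mantel-exhaustive-{method}",
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(n)) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(
        statistic=r_obs, p_value=p, n_permutations=n_perm, seed=seed,
        method=f"partial-mantel-{method}",
        extras={"n_controls": len(d_controls)},
    )


def _square_from_upper(tri: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = tri
    return out + out.T


# ---------------------------------------------------------------------------
# variance partitioning (RDA)
# ---------------------------------------------------------------------------
def _rda_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Redundancy-analysis R^2: share of total response variance captured by
    the linear fit on x (columns centered on both sides)."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    sst = (yc**2).sum()
    if sst == 0:
        raise ValidationError("response has zero variance")
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    return float((fitted**2).sum() / sst)


def _adjust(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValidationError(f"too few samples ({n}) for {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partitioning(abundances, env_sets: dict[str, pd.DataFrame]) -> VPAResult:
    """Partition community variation among named predictor sets via RDA.

    R^2 is computed for every union of predictor sets, adjusted with
    Ezekiel's formula, and decomposed into unique and shared Venn-region
    fractions by inclusion-exclusion.  Negative adjusted fractions are kept
    and flagged, never clipped.
    """
    if not env_sets:
        raise ValidationError("need at least one predictor set")
    y = np.asarray(abundances, dtype=float)
    n = y.shape[0]
    names = list(env_sets)
    blocks = {}
    for name, x in env_sets.items():
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            raise ValidationError(f"predictor set {name!r} has wrong sample count")
        blocks[name] = arr
    full = np.column_stack([blocks[name] for name in names])
    fullc = full - full.mean(axis=0)
    if np.linalg.matrix_rank(fullc) < fullc.shape[1]:
        raise ValidationError(
            f"collinear predictors within machine tolerance in sets {names}"
        )
    if n < full.shape[1] + 2:
        raise ValidationError("need at least n_predictors + 2 samples")

    raw: dict[frozenset, float] = {frozenset(): 0.0}
    adj: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            x = np.column_stack([blocks[c] for c in combo])
            key = frozenset(combo)
            raw[key] = _rda_r2(y, x)
            adj[key] = _adjust(raw[key], n, x.shape[1])

    all_names = frozenset(names)
    fractions: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            s = frozenset(combo)
            comp = all_names - s
            val = 0.0
            for t_size in range(0, len(s) + 1):
                for t in itertools.combinations(sorted(s), t_size):
                    val += (-1) ** (len(t) + 1) * adj[comp | frozenset(t)]
            fractions[s] = val
    total = adj[all_names]
    return VPAResult(
        fractions=fractions,
        total_adjusted_r2=total,
        residual=1.0 - total,
        adjusted_r2_by_union=adj,
        raw_r2_by_union=raw,
    )


# ---------------------------------------------------------------------------
# per-taxon tests
# ---------------------------------------------------------------------------
def taxon_env_correlation(
    abundances: pd.DataFrame,
    metadata,
    method: str = "pearson",
    covariates: list[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Correlate each taxon's relative abundance with each numeric covariate.

    Two-sided p-values use the t-approximation.  No multiplicity correction
    by default; ``bh_correct=True`` appends Benjamini-Hochberg q-values.
    Zero-variance taxa or covariates yield an undefined (NaN) r, flagged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    meta = metadata.frame if hasattr(metadata, "frame") else metadata
    if covariates is None:
        covariates = [c for c in meta.columns if pd.api.types.is_numeric_dtype(meta[c])]
    meta = meta.loc[abundances.index, covariates]
    rows = []
    for taxon in abundances.columns:
        tv = abundances[taxon].to_numpy(dtype=float)
        for cov in covariates:
            cv = meta[cov].to_numpy(dtype=float)
            if np.std(tv) == 0 or np.std(cv) == 0:
                rows.append({"taxon": taxon, "covariate": cov, "r": np.nan,
                             "p": np.nan, "undefined": True})
                continue
            if method == "pearson":
                r, p = ss.pearsonr(tv, cv)
            else:
                r, p = ss.spearmanr(tv, cv)
            rows.append({"taxon": taxon, "covariate": cov, "r": float(r),
                         "p": float(p), "undefined": False})
    out = pd.DataFrame(rows)
    if bh_correct:
        mask = ~out["undefined"]
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["q"] = q
    return out


def _tier(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(abundances: pd.DataFrame, grouping) -> pd.DataFrame:
    """One-way ANOVA per taxon across groups, with group means +/- SEM.

    Returns a DataFrame indexed by taxon with F, p, a significance tier
    ('**' p<0.01, '*' p<0.05) and mean/sem columns per group. Taxa are
    flagged untestable when any group has fewer than two samples.
    """
    labels = pd.Series(list(grouping), index=abundances.index)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    sizes = labels.value_counts()
    testable = (sizes >= 2).all()
    rows = []
    for taxon in abundances.columns:
        vals = [abundances.loc[labels == g, taxon].to_numpy(dtype=float) for g in groups]
        rec = {"taxon": taxon, "untestable": not testable}
        for g, v in zip(groups, vals):
            rec[f"mean_{g}"] = float(v.mean())
            rec[f"sem_{g}"] = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
        if testable:
            if all(np.ptp(v) == 0 for v in vals) and np.ptp(np.concatenate(vals)) == 0:
                f_stat, p = np.nan, np.nan
                rec["untestable"] = True
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    f_stat, p = ss.f_oneway(*vals)
                f_stat, p = float(f_stat), float(p)
        else:
            f_stat, p = np.nan, np.nan
        rec["F"] = f_stat
        rec["p"] = p
        rec["tier"] = _tier(p) if not rec["untestable"] else ""
        rows.append(rec)
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# jackknifed UPGMA
# ---------------------------------------------------------------------------
@dataclass
class JackknifeDendrogram:
    """UPGMA dendrogram on the full table plus jackknife node support.

    ``linkage`` is a scipy linkage matrix over ``sample_ids``;
    ``node_clusters`` lists, per internal node (linkage row), the frozenset
    of sample ids it joins; ``support`` is the fraction of jackknife
    replicates (re-rarefied to a reduced depth) whose UPGMA tree contains
    the same sample bipartition.
    """

    linkage: np.ndarray
    sample_ids: list
    node_clusters: list[frozenset]
    support: list[float]
    n_replicates: int
    subsample_fraction: float
    seed: int


def _upgma_clusters(z: np.ndarray, ids: list) -> list[frozenset]:
    n = len(ids)
    clusters: dict[int, frozenset] = {i: frozenset([ids[i]]) for i in range(n)}
    out = []
    for row_idx, (a, b, _, _) in enumerate(z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + row_idx] = merged
        out.append(merged)
    return out


def upgma_jackknife(
    table: OtuTable,
    tree,
    n_replicates: int = 100,
    subsample_fraction: float = 0.75,
    seed: int = 0,
    normalized: bool = True,
) -> JackknifeDendrogram:
    """UPGMA clustering of samples on weighted UniFrac with jackknife support.

    The full-table distance matrix gives the reported dendrogram. Each
    replicate re-rarefies the table to ``floor(fraction * depth)`` reads
    (depth = the table's minimum sample total), recomputes weighted UniFrac
    and UPGMA, and each internal node's support is the fraction of
    replicate trees containing the same sample cluster.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    dm = weighted_unifrac(table, tree, normalized=normalized)
    z = sch.linkage(dm.condensed_form(), method="average")
    ids = [str(s) for s in table.sample_ids]
    clusters = _upgma_clusters(z, ids)
    depth = int(table.sample_totals().min())
    sub_depth = max(1, int(subsample_fraction * depth))
    hits = np.zeros(len(clusters))
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = rarefy(table, sub_depth, seed=int(rng.integers(2**31 - 1)))
        dm_rep = weighted_unifrac(rep, tree, normalized=normalized)
        z_rep = sch.linkage(dm_rep.condensed_form(), method="average")
        rep_clusters = set(_upgma_clusters(z_rep, [str(s) for s in rep.sample_ids]))
        for k, c in enumerate(clusters):
            if c in rep_clusters:
                hits[k] += 1
    return JackknifeDendrogram(
        linkage=z,
        sample_ids=ids,
        node_clusters=clusters,
        support=list(hits / n_replicates),
        n_replicates=n_replicates,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )
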