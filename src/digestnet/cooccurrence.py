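"""Checkerboard (C-score) null-model testing and Spearman co-occurrence
networks over cosmopolitan OTUs.

The C-score is the Stone-Roberts checkerboard statistic: the mean over
species pairs (i, j) of ``(r_i - S_ij)(r_j - S_ij)`` where ``r_i`` is
species i's site total and ``S_ij`` the number of shared sites. Higher
values mean segregation; the null model is the fixed-fixed sequential-swap
randomization (sim9): repeated 2x2 checkerboard submatrix swaps that
preserve every row and column sum exactly.

Network construction follows the study convention: a valid co-occurrence
edge requires Spearman rho > 0.6 with p < 0.01; strong negative pairs
(rho < -0.6, p < 0.01) are recorded in a separate ledger and never enter
the edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
from numba import njit

from .containers import OtuTable, ValidationError

__all__ = [
    "presence_matrix",
    "c_score",
    "null_model_test",
    "NullModelResult",
    "spearman_matrix",
    "spearman_exact",
    "CorrelationMatrix",
    "build_network",
    "CoOccurrenceNetwork",
    "count_signed_pairs",
]


# ---------------------------------------------------------------------------
# C-score
# ---------------------------------------------------------------------------
def presence_matrix(table: OtuTable, min_count: int = 1) -> pd.DataFrame:
    """Binary species-by-sites matrix (OTUs on rows) from a count table."""
    return (table.counts.T >= min_count).astype(np.int8)


def _as_binary(presence) -> np.ndarray:
    mat = np.asarray(presence)
    if not np.isin(mat, (0, 1)).all():
        raise ValidationError("presence matrix must be binary (0/1)")
    return mat.astype(np.int64)


def c_score(presence) -> float:
    """Stone-Roberts C-score of a binary species (rows) x sites matrix."""
    mat = _as_binary(presence)
    if mat.shape[0] < 2:
        raise ValidationError("C-score needs at least two species")
    r = mat.sum(axis=1)
    shared = mat @ mat.T
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    iu = np.triu_indices(mat.shape[0], k=1)
    return float(cu[iu].mean())


# ---------------------------------------------------------------------------
# sim9 fixed-fixed null model
# ---------------------------------------------------------------------------
@njit(cache=True)
def _sim9_seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _sim9_advance(mat, n_steps):
    """Advance the swap chain by *n_steps* attempted swaps, in place.

    Each step picks two distinct rows and two distinct columns uniformly;
    if the 2x2 submatrix is a checkerboard ([[1,0],[0,1]] or its mirror)
    it is swapped, otherwise the chain stays put (trial-swap convention:
    counting attempts rather than successes makes the chain's stationary
    distribution exactly uniform over all fixed-margin matrices). Returns
    the number of accepted swaps.
    """
    n_r, n_c = mat.shape
    accepted = 0
    steps = 0
    while steps < n_steps:
        r1 = np.random.randint(0, n_r)
        r2 = np.random.randint(0, n_r)
        if r1 == r2:
            continue
        c1 = np.random.randint(0, n_c)
        c2 = np.random.randint(0, n_c)
        if c1 == c2:
            continue
        steps += 1
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            accepted += 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1
            mat[r2, c2] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0
            accepted += 1
    return accepted


def has_checkerboard(presence) -> bool:
    """Whether the matrix admits at least one 2x2 checkerboard swap."""
    mat = _as_binary(presence).astype(bool)
    n_r = mat.shape[0]
    for i in range(n_r - 1):
        only_i = mat[i] & ~mat[i + 1 :]
        only_j = ~mat[i] & mat[i + 1 :]
        if (only_i.any(axis=1) & only_j.any(axis=1)).any():
            return True
    return False


@dataclass
class NullModelResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_null: int
    burn_in_swaps: int
    thin_swaps: int
    seed: int
    degenerate: bool = False
    null_scores: np.ndarray | None = field(default=None, repr=False)


def null_model_test(
    presence,
    n_null: int = 10000,
    burn_in_swaps: int = 30000,
    thin_swaps: int = 1000,
    seed: int = 0,
    keep_null_scores: bool = False,
    check_margins: bool = False,
) -> NullModelResult:
    """Upper-tail C-score test under the sim9 fixed-fixed null.

    After a burn-in of *burn_in_swaps* attempted swaps, one null matrix is
    recorded every *thin_swaps* attempted swaps (trial-swap counting: the
    attempt, not the success, is the Markov step, which keeps the null
    exactly uniform over fixed-margin matrices). Every null matrix
    preserves all row and column sums exactly (optionally asserted per
    draw with ``check_margins=True``). p is the (+1)/(+1) upper-tail
    estimator, so a frozen (unswappable) matrix returns a flagged
    degenerate result with SES = 0 rather than raising.
    """
    mat = _as_binary(presence)
    obs = c_score(mat)
    if not has_checkerboard(mat):
        return NullModelResult(
            observed=obs, null_mean=obs, null_sd=0.0, ses=0.0, p_value=1.0,
            n_null=0, burn_in_swaps=burn_in_swaps, thin_swaps=thin_swaps,
            seed=seed, degenerate=True,
        )
    work = mat.astype(np.int8).copy()
    row_sums = work.sum(axis=1).copy()
    col_sums = work.sum(axis=0).copy()
    _sim9_seed(int(np.random.default_rng(seed).integers(2**31 - 1)))
    _sim9_advance(work, burn_in_swaps)
    nulls = np.empty(n_null)
    for k in range(n_null):
        _sim9_advance(work, thin_swaps)
        if check_margins:
            assert (work.sum(axis=1) == row_sums).all()
            assert (work.sum(axis=0) == col_sums).all()
        nulls[k] = c_score(work)
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if n_null > 1 else 0.0
    ses = (obs - mean) / sd if sd > 0 else 0.0
    p = (int((nulls >= obs - 1e-12).sum()) + 1) / (n_null + 1)
    return NullModelResult(
        observed=obs, null_mean=mean, null_sd=sd, ses=float(ses), p_value=float(p),
        n_null=n_null, burn_in_swaps=burn_in_swaps, thin_swaps=thin_swaps, seed=seed,
        null_scores=nulls if keep_null_scores else None,
    )


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------
@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho and p matrices over a set of OTUs.

    Ties get average (mid) ranks; p-values are two-sided from the
    t-approximation. Zero-variance columns are flagged undefined (NaN rho
    off-diagonal) rather than dropped.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    undefined: pd.Series

    @property
    def ids(self) -> list:
        return list(self.rho.index)


def spearman_matrix(abundances: pd.DataFrame) -> CorrelationMatrix:
    """All-pairs Spearman rank correlation of abundance columns."""
    if abundances.shape[0] < 4:
        raise ValidationError("need at least 4 samples for Spearman correlation")
    arr = abundances.to_numpy(dtype=float)
    ids = list(abundances.columns)
    undefined = pd.Series(arr.std(axis=0) == 0, index=ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, p = ss.spearmanr(arr)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        undefined=undefined,
    )


def spearman_exact(x, y) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman rho (n <= 10).

    Enumerates all n! orderings of y; p is the proportion of permutations
    with |rho_perm| >= |rho_obs|. Used as a small-n oracle for the
    t-approximation.
    """
    import itertools

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 10:
        raise ValueError("exact mode is for n <= 10")
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float(a @ b / denom) if denom > 0 else np.nan

    obs = _rho(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_rho(rx, ry[list(perm)])) >= abs(obs) - 1e-12:
            hits += 1
    return obs, hits / total


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------
@dataclass
class CoOccurrenceNetwork:
    """Positive co-occurrence network plus a negative-pair ledger.

    ``edges`` holds (u, v, rho) with rho > rho_min and p < alpha;
    ``negative_pairs`` holds the strong negative correlations, which are
    counted but never drawn as edges. Isolated candidate nodes are dropped
    from ``nodes`` but reported in ``n_isolated``.
    """

    nodes: list
    edges: list[tuple]
    negative_pairs: list[tuple]
    rho_min: float
    alpha: float
    n_isolated: int
    node_metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, rho in self.edges:
            g.add_edge(u, v, weight=float(rho))
        for node, meta in self.node_metadata.items():
            if node in g:
                g.nodes[node].update(meta)
        return g

    def write_edge_list(self, path) -> None:
        rows = [
            {"source": u, "target": v, "rho": rho, "sign": "positive"}
            for u, v, rho in self.edges
        ] + [
            {"source": u, "target": v, "rho": rho, "sign": "negative"}
            for u, v, rho in self.negative_pairs
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def build_network(
    corr: CorrelationMatrix,
    rho_min: float = 0.6,
    alpha: float = 0.01,
    node_metadata: dict | None = None,
) -> CoOccurrenceNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    Positive edges require rho > rho_min AND p < alpha (both strict);
    pairs with rho < -rho_min AND p < alpha go to the negative ledger.
    """
    ids = corr.ids
    edges = []
    negatives = []
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isnan(rho[i, j]):
                continue
            if p[i, j] < alpha:
                if rho[i, j] > rho_min:
                    edges.append((ids[i], ids[j], float(rho[i, j])))
                elif rho[i, j] < -rho_min:
                    negatives.append((ids[i], ids[j], float(rho[i, j])))
    connected = sorted({u for u, v, _ in edges} | {v for u, v, _ in edges},
                       key=lambda x: ids.index(x))
    n_isolated = len(ids) - len(connected)
    meta = node_metadata or {}
    return CoOccurrenceNetwork(
        nodes=connected,
        edges=edges,
        negative_pairs=negatives,
        rho_min=rho_min,
        alpha=alpha,
        n_isolated=n_isolated,
        node_metadata={k: v for k, v in meta.items() if k in set(connected)},
    )


def count_signed_pairs(
    corr: CorrelationMatrix, rho_min: float = 0.6, alpha: float = 0.01
) -> tuple[int, int]:
    """(n_positive, n_negative) unordered pairs meeting each signed threshold."""
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    iu = np.triu_indices(rho.shape[0], k=1)
    sig = (p[iu] < alpha) & ~np.isnan(rho[iu])
    n_pos = int((sig & (rho[iu] > rho_min)).sum())
    n_neg = int((sig & (rho[iu] < -rho_min)).sum())
    return n_pos, n_neg
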