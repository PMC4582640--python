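"""PCoA, PerMANOVA, partial Mantel, VPA, taxon tests and jackknife UPGMA."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
import skbio.stats.distance as skbio_distance
import skbio.stats.ordination as skbio_ordination
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from digestnet import (
    ValidationError,
    compare_groups,
    partial_mantel,
    pcoa,
    permanova,
    taxon_env_correlation,
    upgma_jackknife,
    variance_partitioning,
)


def _dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(points.shape[0])]
    return DistanceMatrix(squareform(pdist(points)), ids)


class TestPcoa:
    def test_two_samples_forced_geometry(self):
        d = DistanceMatrix([[0, 3], [3, 0]], ["a", "b"])
        coords = pcoa(d).coordinates.to_numpy().ravel()
        assert sorted(coords) == pytest.approx([-1.5, 1.5])

    def test_three_equidistant_samples(self):
        d = DistanceMatrix((np.ones((3, 3)) - np.eye(3)) * 2.0, list("abc"))
        ordn = pcoa(d)
        assert ordn.eigenvalues[0] == pytest.approx(ordn.eigenvalues[1])
        rec = squareform(pdist(ordn.coordinates.to_numpy()))
        assert np.allclose(rec, d.data, atol=1e-10)

    def test_planted_configuration_recovered(self, rng):
        pts = rng.normal(size=(8, 2))
        ordn = pcoa(_dm(pts))
        rec = squareform(pdist(ordn.coordinates.to_numpy()[:, :2]))
        assert np.abs(rec - squareform(pdist(pts))).max() < 1e-8

    def test_matches_skbio_proportions(self, rng):
        pts = rng.normal(size=(7, 3))
        d = _dm(pts)
        ours = pcoa(d)
        ref = skbio_ordination.pcoa(d)
        assert ours.proportion_explained[:3] == pytest.approx(
            ref.proportion_explained.to_numpy()[:3], abs=1e-9
        )

    def test_non_symmetric_rejected(self):
        with pytest.raises(Exception):
            pcoa(DistanceMatrix(np.array([[0, 1.0], [2.0, 0]]), list("ab")))

    def test_negative_eigenvalues_reported(self):
        # a non-Euclidean metric configuration
        d = DistanceMatrix(
            np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 2], [1, 1, 2, 0]], float),
            list("abcd"),
        )
        ordn = pcoa(d)
        assert ordn.negative_eigenvalues.size > 0


def _pseudo_f_oracle(dmat, labels):
    """Anderson's pseudo-F computed with explicit double loops."""
    n = len(labels)
    ss_t = sum(dmat[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    groups = sorted(set(labels))
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(
            dmat[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    a = len(groups)
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    def test_perfect_separation(self):
        # zero within-group distance, positive between: maximal pseudo-F;
        # no sampled permutation can tie it (groups large enough that the
        # exact partition is essentially never redrawn)
        pts = np.vstack([np.zeros((8, 2)), np.ones((8, 2)) * 9])
        res = permanova(_dm(pts), ["a"] * 8 + ["b"] * 8, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.statistic == np.inf

    def test_statistic_matches_skbio(self, rng):
        pts = rng.normal(size=(12, 3))
        d = _dm(pts)
        grp = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, grp, n_perm=9, seed=0)
        ref = skbio_distance.permanova(d, grouping=grp, permutations=9)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        pts = rng.normal(size=(5, 2))
        d = _dm(pts)
        labels = np.array(["a", "a", "b", "b", "b"])
        res = permanova(d, labels, exhaustive=True)
        f_obs = _pseudo_f_oracle(d.data, list(labels))
        hits = sum(
            _pseudo_f_oracle(d.data, list(labels[list(p)])) >= f_obs - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert res.n_permutations == 120
        assert res.p_value == pytest.approx(hits / 120)
        assert res.statistic == pytest.approx(f_obs)

    def test_score_based_variant_agrees_on_euclidean_input(self, rng):
        pts = rng.normal(size=(10, 3))
        d = _dm(pts)
        grp = ["a"] * 5 + ["b"] * 5
        direct = permanova(d, grp, n_perm=9, seed=0)
        scores = permanova(d, grp, n_perm=9, seed=0, use_pcoa_scores=True)
        assert direct.statistic == pytest.approx(scores.statistic, rel=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            permanova(_dm(np.eye(4)), ["a"] * 4, n_perm=9, seed=0)


def _partial_mantel_oracle(dc, df_, controls, perm):
    """Residualize-and-correlate with an independent OLS implementation."""
    n = dc.shape[0]
    iu = np.triu_indices(n, k=1)
    yc = dc[iu]
    yf = df_[np.ix_(perm, perm)][iu]
    if controls:
        x = np.column_stack([np.ones(yc.size)] + [c[iu] for c in controls])
        yc = yc - x @ np.linalg.lstsq(x, yc, rcond=None)[0]
        yf = yf - x @ np.linalg.lstsq(x, yf, rcond=None)[0]
    return float(np.corrcoef(yc, yf)[0, 1])


class TestPartialMantel:
    def test_reduces_to_simple_mantel(self, rng):
        d1, d2 = _dm(rng.normal(size=(10, 2))), _dm(rng.normal(size=(10, 2)))
        ours = partial_mantel(d1, d2, n_perm=9, seed=0)
        r_ref = skbio_distance.mantel(d1, d2, permutations=0)[0]
        assert ours.statistic == pytest.approx(r_ref)

    def test_identity_gives_r_one(self, rng):
        d = _dm(rng.normal(size=(8, 2)))
        assert partial_mantel(d, d, n_perm=9, seed=0).statistic == pytest.approx(1.0)

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        dc = _dm(rng.normal(size=(5, 2)))
        df_ = _dm(rng.normal(size=(5, 2)))
        ctrl = _dm(rng.normal(size=(5, 2)))
        res = partial_mantel(dc, df_, [ctrl], exhaustive=True)
        r_obs = _partial_mantel_oracle(dc.data, df_.data, [ctrl.data], np.arange(5))
        hits = sum(
            _partial_mantel_oracle(dc.data, df_.data, [ctrl.data], np.array(p))
            >= r_obs - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert res.statistic == pytest.approx(r_obs)
        assert res.p_value == pytest.approx(hits / 120)

    def test_zero_variance_rejected(self):
        flat = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        d = _dm(np.random.default_rng(1).normal(size=(4, 2)), ids=list("abcd"))
        with pytest.raises(ValidationError, match="variance"):
            partial_mantel(flat, d)

    def test_duplicate_controls_rejected(self, rng):
        dc = _dm(rng.normal(size=(6, 2)))
        df_ = _dm(rng.normal(size=(6, 2)))
        ctrl = _dm(rng.normal(size=(6, 2)))
        with pytest.raises(ValidationError, match="singular"):
            partial_mantel(dc, df_, [ctrl, ctrl])


class TestVariancePartitioning:
    def test_single_set_reduction(self, rng):
        y = rng.normal(size=(20, 4))
        x = rng.normal(size=(20, 2))
        res = variance_partitioning(y, {"A": x})
        assert res.unique("A") == pytest.approx(res.total_adjusted_r2)
        assert res.residual == pytest.approx(1 - res.total_adjusted_r2)

    def test_inclusion_exclusion_identity(self, rng):
        y = rng.normal(size=(25, 3))
        sets = {k: rng.normal(size=(25, 2)) for k in "ABC"}
        res = variance_partitioning(y, sets)
        assert sum(res.fractions.values()) == pytest.approx(res.total_adjusted_r2, abs=1e-10)

    def test_orthogonal_predictors_share_nothing(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(40, 4)))
        x1, x2 = q[:, :2], q[:, 2:4]
        y = x1 @ rng.normal(size=(2, 3)) + x2 @ rng.normal(size=(2, 3)) + 0.1 * rng.normal(size=(40, 3))
        res = variance_partitioning(y, {"A": x1, "B": x2})
        assert abs(res.fractions[frozenset("AB")]) < 0.05

    def test_null_fractions_near_zero(self, rng):
        vals = []
        for _ in range(200):
            y = rng.normal(size=(30, 2))
            res = variance_partitioning(
                y, {"A": rng.normal(size=(30, 1)), "B": rng.normal(size=(30, 1))}
            )
            vals.append(list(res.fractions.values()))
        assert np.abs(np.mean(vals, axis=0)).max() < 0.03

    def test_collinear_predictors_rejected(self, rng):
        y = rng.normal(size=(15, 2))
        x = rng.normal(size=(15, 1))
        with pytest.raises(ValidationError, match="collinear"):
            variance_partitioning(y, {"A": x, "B": 2 * x})


class TestTaxonEnvCorrelation:
    def _meta(self, frame):
        return frame

    def test_perfect_correlations(self, rng):
        cov = rng.normal(size=12)
        ab = pd.DataFrame({"t1": cov, "t2": -cov}, index=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame({"NH4N": cov}, index=ab.index)
        out = taxon_env_correlation(ab, meta).set_index("taxon")
        assert out.loc["t1", "r"] == pytest.approx(1.0)
        assert out.loc["t2", "r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        ab = pd.DataFrame({"t": x}, index=[f"s{i}" for i in range(20)])
        meta = pd.DataFrame({"COD": y}, index=ab.index)
        r = taxon_env_correlation(ab, meta)["r"].iloc[0]
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        ab = pd.DataFrame({"t": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        meta = pd.DataFrame({"pH": [7, 7.5, 6.9, 7.2]}, index=list("abcd"))
        out = taxon_env_correlation(ab, meta)
        assert out["undefined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])

    def test_bh_flag_appends_q(self, rng):
        ab = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("xyz"),
                          index=[f"s{i}" for i in range(15)])
        meta = pd.DataFrame({"pH": rng.normal(size=15)}, index=ab.index)
        out = taxon_env_correlation(ab, meta, bh_correct=True)
        assert "q" in out.columns
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestCompareGroups:
    def test_zero_between_variance_gives_f_zero(self):
        ab = pd.DataFrame({"t": [1.0, 2.0, 1.0, 2.0]}, index=list("abcd"))
        out = compare_groups(ab, ["g1", "g1", "g2", "g2"])
        assert out.loc["t", "F"] == pytest.approx(0.0)

    def test_hand_computed_f(self):
        ab = pd.DataFrame({"t": [1.0, 2, 3, 2, 3, 4]}, index=list("abcdef"))
        out = compare_groups(ab, ["x"] * 3 + ["y"] * 3)
        assert out.loc["t", "F"] == pytest.approx(1.5)
        assert out.loc["t", "mean_x"] == pytest.approx(2.0)
        assert out.loc["t", "sem_x"] == pytest.approx(1.0 / np.sqrt(3))

    def test_type_one_error_near_nominal(self, rng):
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            ab = pd.DataFrame({"t": rng.normal(size=16)},
                              index=[f"s{i}" for i in range(16)])
            out = compare_groups(ab, ["a"] * 8 + ["b"] * 8)
            hits += out.loc["t", "p"] < 0.05
        rate = hits / n_rep
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < band

    def test_small_group_flagged_untestable(self):
        ab = pd.DataFrame({"t": [1.0, 2.0, 3.0]}, index=list("abc"))
        out = compare_groups(ab, ["x", "y", "y"])
        assert out.loc["t", "untestable"]
        assert np.isnan(out.loc["t", "F"])


class TestUpgmaJackknife:
    def test_forced_merge_order_and_degenerate_replicate(self, small_community):
        table = small_community.table
        tree = small_community.tree
        res = upgma_jackknife(table, tree, n_replicates=1, subsample_fraction=1.0, seed=0)
        # fraction 1 on a uniform-depth table is the identity: same tree
        assert all(s in (0.0, 1.0) for s in res.support)
        assert all(s == 1.0 for s in res.support)

    def test_planted_clusters_fully_supported(self):
        from digestnet import generate_community

        # well-separated clusters: strong between-cluster contrast, low noise
        comm = generate_community(
            n_samples_I=8, n_samples_II=8, n_otus=150, depth=800, seed=3,
            cluster_separation=2.5, noise_sd=0.3, enforce_prevalence=False,
        )
        table = comm.table
        labels = comm.metadata.frame["cluster"]
        res = upgma_jackknife(table, comm.tree, n_replicates=50,
                              subsample_fraction=0.75, seed=3)
        cluster_i = frozenset(str(s) for s in labels.index[labels == "I"])
        cluster_ii = frozenset(str(s) for s in labels.index[labels == "II"])
        support = dict(zip(res.node_clusters, res.support))
        assert support.get(cluster_i, 0.0) == 1.0
        assert support.get(cluster_ii, 0.0) == 1.0

    def test_bad_fraction_rejected(self, small_community):
        with pytest.raises(ValueError):
            upgma_jackknife(small_community.table, small_community.tree,
                            subsample_fraction=1.5)
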