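"""Population structure: PCA, ancestry, AMOVA, F_ST, IBD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from landgen import popstruct as ps
from landgen import synthdata as sd
from landgen.genio import GenotypeMatrix, SiteFrame


def _gm(values):
    values = np.asarray(values, dtype=float)
    L = values.shape[1]
    meta = pd.DataFrame(
        {"id": [f"L{i}" for i in range(L)], "contig": [f"c{i}" for i in range(L)],
         "position": range(L), "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(values, meta, [f"i{j}" for j in range(len(values))])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.integers(0, 3, size=(12, 7)).astype(float)
        scores, loadings, eig = ps.pca_genotypes(X)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        w, V = np.linalg.eigh(cov)
        w, V = w[::-1], V[:, ::-1]
        np.testing.assert_allclose(eig, w[: len(eig)], atol=1e-8)
        for k in range(3):  # sign-align before comparing
            ref = Xc @ V[:, k]
            sign = np.sign(ref @ scores[:, k]) or 1.0
            np.testing.assert_allclose(scores[:, k], sign * ref, atol=1e-8)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        X = rng.integers(0, 3, size=(15, 9)).astype(float)
        _, _, eig = ps.pca_genotypes(X)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            eig.sum(), (Xc**2).sum() / (len(X) - 1), atol=1e-8
        )

    def test_two_clouds_separate_on_pc1(self):
        X = np.r_[np.zeros((6, 10)), np.full((6, 10), 2.0)]
        scores, _, eig = ps.pca_genotypes(X)
        assert eig[0] / eig.sum() > 0.999
        assert (scores[:6, 0] * scores[6:, 0] < 0).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ps.pca_genotypes(np.ones((5, 5)))


# ---------------------------------------------------------------------------
# ancestry
# ---------------------------------------------------------------------------


class TestAncestry:
    def test_k1_closed_form(self, rng):
        X = rng.integers(0, 3, size=(10, 6)).astype(float)
        X[2, 3] = np.nan
        m = ps.estimate_ancestry(X, 1)
        np.testing.assert_array_equal(m.Q, np.ones((10, 1)))
        np.testing.assert_allclose(
            m.F[0], np.nanmean(X, axis=0) / 2, atol=1e-12
        )

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.integers(0, 3, size=(40, 60)).astype(float)
        m = ps.estimate_ancestry(X, 3, seed=0, n_restarts=1)
        path = np.array(m.objective_path)
        assert (np.diff(path) <= 1e-9).all()

    def test_two_cluster_recovery(self):
        rng = np.random.default_rng(4)
        f = np.where(rng.random((2, 80)) < 0.5, 0.05, 0.95)
        f[1] = 1 - f[0]
        labels = np.r_[np.zeros(25, int), np.ones(25, int)]
        X = rng.binomial(2, f[labels]).astype(float)
        m = ps.estimate_ancestry(X, 2, seed=0, n_restarts=2)
        true_Q = np.eye(2)[labels]
        Qa = ps.align_clusters(m.Q, true_Q)
        assert np.abs(Qa - true_Q).mean() < 0.05

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.estimate_ancestry(np.zeros((3, 5)), 4)

    def test_q_statistics_invariant_to_cluster_permutation(self, rng):
        X = rng.integers(0, 3, size=(30, 40)).astype(float)
        m = ps.estimate_ancestry(X, 3, seed=1, n_restarts=1)
        perm = [2, 0, 1]
        fully_perm = m.count_fully_assigned()[perm]
        m2 = ps.AncestryModel(3, m.Q[:, perm], m.F[perm], m.objective)
        np.testing.assert_array_equal(m2.count_fully_assigned(), fully_perm)
        np.testing.assert_allclose(m2.expected_freq(), m.expected_freq())


class TestChooseK:
    def test_unstructured_data_prefers_k1(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.2, 0.8, size=200)
        X = rng.binomial(2, p, size=(60, 200)).astype(float)
        cv = ps.choose_K(X, K_range=range(1, 4), seed=3)
        assert ps.select_K(cv) == 1

    def test_unsupported_extra_cluster_flagged_implausible(self, rng,
                                                           monkeypatch):
        # craft a fit whose third cluster has no fully assigned individual:
        # such a K must be reported implausible
        X = rng.integers(0, 3, size=(30, 50)).astype(float)

        def fake_fit(Xin, K, seed=0, n_restarts=1):
            n = len(Xin)
            Q = np.full((n, K), 0.02 / max(K - 1, 1))
            Q[: n // 2, 0] = 0.98
            Q[n // 2:, min(1, K - 1)] = 0.98
            Q /= Q.sum(axis=1, keepdims=True)
            F = np.full((K, Xin.shape[1]), 0.5)
            return ps.AncestryModel(K, Q, F, 0.0)

        monkeypatch.setattr(ps, "estimate_ancestry", fake_fit)
        cv = ps.choose_K(X, K_range=range(2, 4), seed=5)
        assert bool(cv.loc[cv["K"] == 2, "plausible"].iloc[0])
        assert not bool(cv.loc[cv["K"] == 3, "plausible"].iloc[0])
        assert cv.loc[cv["K"] == 3, "min_fully_assigned"].iloc[0] == 0

    def test_mask_fraction_validated(self, rng):
        with pytest.raises(ValueError):
            ps.choose_K(np.zeros((4, 4)), mask_fraction=0.7)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


class TestImpute:
    def test_no_missing_is_identity(self, rng):
        X = rng.integers(0, 3, size=(8, 5)).astype(float)
        g = _gm(X)
        m = ps.estimate_ancestry(X, 2, seed=0, n_restarts=1)
        out = ps.impute_genotypes(g, m)
        np.testing.assert_array_equal(out.values, X)

    def test_forced_mode(self):
        X = np.array([[0.0, np.nan], [0.0, 0.0]])
        g = _gm(X)
        m = ps.AncestryModel(1, np.ones((2, 1)), np.array([[0.0, 0.0]]), 0.0)
        out = ps.impute_genotypes(g, m)
        assert out.values[0, 1] == 0.0

    def test_all_missing_locus_rejected(self):
        X = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        g = _gm(X)
        m = ps.AncestryModel(1, np.ones((2, 1)), np.array([[0.5, 0.5]]), 0.0)
        with pytest.raises(ValueError, match="L0"):
            ps.impute_genotypes(g, m)

    def test_self_masking_recovery_reaches_analytic_ceiling(self):
        """Masked-entry recovery should approach the Bayes rate of the
        generating model (modal genotype under the true Q and F)."""
        cfg = sd.SimConfig(
            n_individuals=200, n_sites=150, n_neutral=500, n_adaptive=0,
            K_true=3, drift=0.15, missing_rate=0.0, grid_shape=(20, 30),
            temperature=2.0, seed=77,
        )
        g, sites, env, truth = sd.simulate(cfg)
        rng = np.random.default_rng(5)
        mask = rng.random(g.values.shape) < 0.15
        masked = g.values.copy()
        masked[mask] = np.nan
        model = ps.estimate_ancestry(masked, 3, seed=1, n_restarts=2)
        gi = ps.impute_genotypes(
            GenotypeMatrix(masked, g.locus_meta, g.individual_ids), model
        )
        recovery = (gi.values[mask] == g.values[mask]).mean()
        # analytic ceiling: expected max-pmf accuracy under the true model
        P = (truth.true_Q @ truth.true_cluster_freqs).clip(0, 1)
        pmf = np.stack([(1 - P) ** 2, 2 * P * (1 - P), P**2])
        ceiling = pmf.max(axis=0).mean()
        assert recovery > ceiling - 0.03


# ---------------------------------------------------------------------------
# Q interpolation
# ---------------------------------------------------------------------------


class TestInterpolateQ:
    def test_reproduces_site_values_and_stays_on_simplex(self, small_sim):
        g, sites, env = small_sim["g"], small_sim["sites"], small_sim["env"]
        m = ps.estimate_ancestry(g, 2, seed=0, n_restarts=1)
        Qg, modal = ps.interpolate_Q(m, sites, env)
        np.testing.assert_allclose(Qg.sum(axis=0), 1.0, atol=1e-9)
        assert modal.min() >= 1 and modal.max() <= 2
        # evaluation at one site cell approximates the site-mean q
        df = sites.data.copy()
        df["q0"] = m.Q[:, 0]
        site0 = df.groupby("site_id").agg(
            {"longitude": "mean", "latitude": "mean", "q0": "mean"}
        ).iloc[0]
        r, c = env.cell_of(site0["longitude"], site0["latitude"])
        assert abs(Qg[0, r, c] - site0["q0"]) < 0.05  # cell-center offset

    def test_k1_everything_group_one(self, small_sim):
        g, sites, env = small_sim["g"], small_sim["sites"], small_sim["env"]
        m = ps.estimate_ancestry(g, 1)
        Qg, modal = ps.interpolate_Q(m, sites, env)
        assert (modal == 1).all()

    def test_collinear_sites_rejected(self, small_sim):
        g = small_sim["g"]
        m = ps.estimate_ancestry(g.values[:5], 2, seed=0, n_restarts=1)
        df = pd.DataFrame(
            {
                "individual_id": [f"i{j}" for j in range(5)],
                "site_id": [f"s{j}" for j in range(5)],
                "longitude": np.arange(5.0),
                "latitude": np.zeros(5),
                "zone": "z",
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            ps.interpolate_Q(m, SiteFrame(df), small_sim["env"])


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _amova_oracle(X, labels):
    """Brute-force variance components from pairwise squared distances."""
    X = np.asarray(X, float)
    N = len(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    groups = np.unique(labels)
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(groups) - 1, N - len(groups)
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    counts = np.array([np.sum(labels == g) for g in groups])
    n0 = (N - (counts**2).sum() / N) / df_a
    s_w = ms_w
    s_a = (ms_a - ms_w) / n0
    return s_a, s_w, s_a / (s_a + s_w)


class TestAMOVA:
    def test_components_match_bruteforce_oracle(self, rng):
        X = rng.integers(0, 3, size=(6, 3)).astype(float)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = ps.amova(X, labels, n_perm=99, seed=0)
        s_a, s_w, phi = _amova_oracle(X, labels)
        np.testing.assert_allclose(res.amova_components, (s_a, s_w),
                                   atol=1e-10)
        np.testing.assert_allclose(res.phi_st, phi, atol=1e-10)

    def test_fixed_opposite_groups_give_phi_one(self):
        X = np.r_[np.zeros((4, 6)), np.full((4, 6), 2.0)]
        labels = np.r_[["a"] * 4, ["b"] * 4]
        res = ps.amova(X, labels, n_perm=99, seed=0)
        np.testing.assert_allclose(res.phi_st, 1.0, atol=1e-12)

    def test_singleton_group_rejected(self, rng):
        X = rng.integers(0, 3, size=(5, 4)).astype(float)
        with pytest.raises(ValueError, match="size 1"):
            ps.amova(X, np.array(["a", "a", "a", "a", "b"]))

    def test_type_one_error_near_alpha(self):
        """Random labels on exchangeable genotypes: rejection rate ~ 5%."""
        rng = np.random.default_rng(303)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            X = rng.binomial(2, 0.4, size=(24, 30)).astype(float)
            labels = np.repeat(["a", "b", "c"], 8)
            res = ps.amova(X, labels, n_perm=99,
                           seed=int(rng.integers(2**31 - 1)))
            hits += res.p_perm <= 0.05
        assert abs(hits / n_rep - 0.05) <= 0.03


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _wc_theta_oracle(X, labels):
    """Scalar-level Weir-Cockerham components, summed over loci."""
    pops = np.unique(labels)
    r = len(pops)
    num = den = 0.0
    for l in range(X.shape[1]):
        n_i, p_i, h_i = [], [], []
        for pop in pops:
            col = X[labels == pop, l]
            col = col[~np.isnan(col)]
            n_i.append(len(col))
            p_i.append(col.sum() / (2 * len(col)))
            h_i.append(np.mean(col == 1))
        n_i, p_i, h_i = map(np.asarray, (n_i, p_i, h_i))
        nbar = n_i.mean()
        nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
        pbar = (n_i * p_i).sum() / (nbar * r)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (nbar * r)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if np.isfinite(a + b + c):
            num += a
            den += a + b + c
    return num / den


class TestFst:
    def test_theta_matches_component_oracle(self):
        X = np.array(
            [[0, 1], [1, 2], [0, 0], [2, 2], [2, 1], [1, 2]], dtype=float
        )
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        np.testing.assert_allclose(
            ps.wc_theta(X, labels), _wc_theta_oracle(X, labels), atol=1e-10
        )

    def test_fixed_opposite_alleles_give_theta_one(self):
        X = np.r_[np.zeros((5, 8)), np.full((5, 8), 2.0)]
        labels = np.r_[["a"] * 5, ["b"] * 5]
        np.testing.assert_allclose(ps.wc_theta(X, labels), 1.0, atol=1e-12)

    def test_identical_groups_give_theta_near_zero(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, 500)
        X = rng.binomial(2, p, size=(40, 500)).astype(float)
        labels = np.r_[["a"] * 20, ["b"] * 20]
        assert abs(ps.wc_theta(X, labels)) < 0.02

    def test_monomorphic_rejected(self):
        X = np.zeros((6, 4))
        labels = np.r_[["a"] * 3, ["b"] * 3]
        with pytest.raises(ValueError, match="undefined"):
            ps.wc_theta(X, labels)

    def test_pairwise_matrix_symmetric_zero_diagonal(self, rng):
        X = rng.integers(0, 3, size=(18, 40)).astype(float)
        labels = np.repeat(["a", "b", "c"], 6)
        res = ps.pairwise_fst(X, labels, n_perm=49, seed=0)
        M = res.pairwise_fst.to_numpy()
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(M), 0.0)

    def test_global_nei_two_fixed_groups(self):
        X = np.r_[np.zeros((5, 8)), np.full((5, 8), 2.0)]
        labels = np.r_[["a"] * 5, ["b"] * 5]
        res = ps.global_fst(X, labels)
        np.testing.assert_allclose(res.global_fst, 1.0, atol=1e-12)

    def test_amova_and_theta_agree_in_rank_order_over_drift(self):
        phis, thetas = [], []
        for F in (0.01, 0.05, 0.15):
            cfg = sd.SimConfig(
                n_individuals=120, n_sites=90, n_neutral=200, n_adaptive=0,
                grid_shape=(15, 20), drift=F, missing_rate=0.0,
                temperature=1.0, seed=13,
            )
            g, sites, env, truth = sd.simulate(cfg)
            labels = truth.true_Q.argmax(axis=1)
            phis.append(ps.amova(g, labels, n_perm=9, seed=0).phi_st)
            thetas.append(ps.wc_theta(g.values, labels))
        assert np.argsort(phis).tolist() == np.argsort(thetas).tolist()


# ---------------------------------------------------------------------------
# geodesics, Mantel, IBD
# ---------------------------------------------------------------------------


class TestGeodesics:
    def test_one_degree_longitude_at_equator(self):
        d = ps.haversine_km(0.0, 0.0, 1.0, 0.0)
        assert abs(d - 111.195) < 0.01

    def test_identical_coordinates_zero(self):
        coords = pd.DataFrame(
            {"longitude": [8.0, 8.0], "latitude": [50.0, 50.0]}
        )
        D = ps.geodesic_matrix(coords)
        np.testing.assert_allclose(D.to_numpy(), 0.0, atol=1e-12)

    def test_mantel_affine_invariance(self, rng):
        pts = rng.normal(size=(7, 2))
        D1 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        D2 = 3 * D1 + 2
        np.fill_diagonal(D2, 0)
        r, p = ps.mantel_test(D1, D2, n_perm=99, seed=0)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        assert p == pytest.approx(0.01, abs=1e-9)

    def test_non_symmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            ps.mantel_test(D, D.T @ D, n_perm=99)

    def test_mantel_null_p_uniform(self):
        """Independent matrices: Mantel p is uniform (KS over replicates)."""
        rng = np.random.default_rng(555)
        pvals = []
        for _ in range(500):
            a = rng.normal(size=(8, 8))
            b = rng.normal(size=(8, 8))
            D1, D2 = np.abs(a + a.T), np.abs(b + b.T)
            np.fill_diagonal(D1, 0)
            np.fill_diagonal(D2, 0)
            _, p = ps.mantel_test(D1, D2, n_perm=199,
                                  seed=int(rng.integers(2**31 - 1)))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_mantel_r_matches_scikit_bio(self, rng):
        """Cross-check the Mantel statistic against an independent
        implementation."""
        from skbio.stats.distance import DistanceMatrix, mantel

        pts = rng.normal(size=(9, 2))
        D1 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        noise = rng.normal(size=(9, 9))
        D2 = D1 + 0.3 * np.abs(noise + noise.T)
        np.fill_diagonal(D2, 0)
        r_ours, _ = ps.mantel_test(D1, D2, n_perm=99, seed=0)
        r_skbio, _, _ = mantel(DistanceMatrix(D1), DistanceMatrix(D2),
                               permutations=0)
        np.testing.assert_allclose(r_ours, r_skbio, atol=1e-10)

    def test_ibd_slope_recovers_linear_relation(self, rng):
        pts = rng.uniform(0, 5, size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)) * 100
        F = 0.007 * D / 100.0
        res = ps.ibd_fit(F, D, n_perm=99, seed=0)
        np.testing.assert_allclose(res.slope_per_100km, 0.007, atol=1e-10)
        np.testing.assert_allclose(res.r2, 1.0, atol=1e-10)
        np.testing.assert_allclose(res.mantel_r, 1.0, atol=1e-12)
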