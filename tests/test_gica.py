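"""PCA reduction, Infomax, ICASSO stability, back-projection, z maps."""
import numpy as np
import pytest

import fluctica as fl
from fluctica.gica import (
    back_project,
    icasso_select,
    infomax_unmix,
    match_components,
    pca_reduce,
    zscore_map,
)


class TestPcaReduce:
    def test_identity_covariance_full_retention(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 20000))
        red = pca_reduce(X, 5)
        assert red.retained_variance == pytest.approx(1.0)

    def test_exact_subspace_of_rank2_mixture(self):
        rng = np.random.default_rng(1)
        S = rng.standard_normal((2, 500))
        A = rng.standard_normal((6, 2))
        X = A @ S
        red = pca_reduce(X, 2)
        # perfect reconstruction from the retained subspace
        Xc = X - X.mean(axis=1, keepdims=True)
        recon = np.linalg.lstsq(red.reduced.T, Xc.T, rcond=None)[0].T @ red.reduced
        assert np.allclose(recon, Xc, atol=1e-8)

    def test_retained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 1000)) * np.linspace(1, 5, 100)[:, None]
        red = pca_reduce(X, 10)
        Xc = X - X.mean(axis=1, keepdims=True)
        evals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        assert red.retained_variance == pytest.approx(
            evals[:10].sum() / evals.sum(), rel=1e-10
        )

    def test_whitening_contract(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4000)) * np.linspace(1, 3, 30)[:, None]
        red = pca_reduce(X, 12)
        C = red.reduced @ red.reduced.T / red.reduced.shape[1]
        assert np.allclose(C, np.eye(12), atol=1e-6)

    def test_rank_deficient_rejected_naming_rank(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((2, 100))] * 3)  # rank 2
        with pytest.raises(ValueError, match="rank 2"):
            pca_reduce(X, 4)

    def test_nonfinite_rejected(self):
        X = np.ones((3, 10))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pca_reduce(X, 2)


class TestInfomax:
    def _mixture(self, seed, k=2, n=5000):
        rng = np.random.default_rng(seed)
        S = rng.laplace(size=(k, n))
        A = rng.standard_normal((k, k))
        return S, pca_reduce(A @ S, k).reduced

    def test_recovers_supergaussian_sources(self):
        S, Xw = self._mixture(0)
        U = infomax_unmix(Xw, seed=1) @ Xw
        r = np.abs(np.corrcoef(np.vstack([S, U]))[:2, 2:])
        assert (r.max(axis=1) > 0.95).all()

    def test_independent_input_gives_signed_permutation(self):
        rng = np.random.default_rng(5)
        S = rng.laplace(size=(3, 8000))
        Xw = pca_reduce(S, 3).reduced
        W = infomax_unmix(Xw, seed=2)
        # each recovered source aligns with exactly one input coordinate
        U = W @ Xw
        r = np.abs(np.corrcoef(np.vstack([S, U]))[:3, 3:])
        perm = r.argmax(axis=1)
        assert sorted(perm) == [0, 1, 2]
        off = r.copy()
        for i, j in enumerate(perm):
            off[i, j] = 0
        assert off.max() < 0.1

    def test_seed_stability_after_matching(self):
        S, Xw = self._mixture(7, k=3)
        U1 = infomax_unmix(Xw, seed=10) @ Xw
        U2 = infomax_unmix(Xw, seed=20) @ Xw
        _, r = match_components(U1.T, U2.T)
        assert (r > 0.95).all()

    def test_unit_norm_rows(self):
        _, Xw = self._mixture(8)
        W = infomax_unmix(Xw, seed=3)
        assert np.allclose(np.linalg.norm(W, axis=1), 1.0, atol=1e-12)


class TestIcasso:
    def test_degenerate_identical_runs(self):
        """Identical runs (no bootstrap) produce pure clusters of size
        n_runs with intra-cluster similarity exactly one."""
        rng = np.random.default_rng(0)
        S = rng.laplace(size=(3, 4000))
        A = rng.standard_normal((3, 3))
        Xw = pca_reduce(A @ S, 3).reduced
        res = icasso_select(Xw, n_runs=5, bootstrap=False, seed=42, similarity="maps")
        assert (res.cluster_sizes == 5).all()
        for lab in np.unique(res.labels):
            members = np.flatnonzero(res.labels == lab)
            sub = res.similarity[np.ix_(members, members)]
            assert np.allclose(sub, 1.0, atol=1e-9)
        assert res.stability_iq == pytest.approx(1.0, abs=0.05)

    def test_high_snr_mixture_is_stable(self):
        rng = np.random.default_rng(1)
        S = rng.laplace(size=(5, 6000))
        A = rng.standard_normal((5, 5))
        Xw = pca_reduce(A @ S, 5).reduced
        res = icasso_select(Xw, n_runs=10, bootstrap=True, seed=3, similarity="maps")
        assert (res.stability_iq > 0.9).all()

    def test_noise_less_stable_than_signal(self):
        rng = np.random.default_rng(2)
        S = rng.laplace(size=(5, 6000))
        A = rng.standard_normal((5, 5))
        strong = icasso_select(
            pca_reduce(A @ S, 5).reduced, n_runs=6, seed=4, similarity="maps"
        )
        noise = icasso_select(
            pca_reduce(rng.standard_normal((40, 6000)), 5).reduced,
            n_runs=6,
            seed=4,
            similarity="maps",
        )
        assert noise.stability_iq.mean() < strong.stability_iq.mean() - 0.2

    def test_requires_two_runs(self):
        with pytest.raises(ValueError, match="n_runs"):
            icasso_select(np.eye(3), n_runs=1)


class TestBackProject:
    def test_noiseless_data_recovers_timecourses_exactly(self):
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((300, 4))
        tc = rng.standard_normal((50, 4))
        data = tc @ maps.T
        rec, smaps = back_project(maps, data)
        assert np.allclose(rec, tc, atol=1e-8)
        assert np.allclose(smaps, maps.T, atol=1e-6)

    def test_orthogonal_maps_equal_inner_product_projection(self):
        maps, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((100, 3)))
        data = np.random.default_rng(2).standard_normal((20, 100))
        rec, _ = back_project(maps, data)
        assert np.allclose(rec, data @ maps, atol=1e-10)

    def test_collinear_maps_rejected(self):
        base = np.random.default_rng(3).standard_normal(100)
        maps = np.column_stack([base, base * (1 + 1e-12)])
        with pytest.raises(ValueError, match="collinear"):
            back_project(maps, np.zeros((10, 100)))


class TestZscoreMap:
    def test_constant_map_is_all_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            z, supra = zscore_map(np.full(100, 2.0))
        assert not z.any() and not supra.any()

    def test_single_extreme_voxel_survives(self):
        v = np.zeros(1000)
        v[17] = 10.0
        _, supra = zscore_map(v, threshold=2.0)
        assert supra[17] and supra.sum() == 1

    def test_normal_tail_fraction(self):
        v = np.random.default_rng(4).standard_normal(200_000)
        _, supra = zscore_map(v, threshold=2.0)
        assert supra.mean() == pytest.approx(0.0455, abs=0.004)


class TestEndToEnd:
    def test_every_network_matches_one_component(self, cohort, gica_fit, gica_assignment):
        assign, spatial_r = gica_assignment
        assert len(set(assign.tolist())) == len(cohort.specs)  # bijective match
        assert (spatial_r > 0.8).all()

    def test_map_sign_convention_positive_skewness(self, gica_fit):
        from scipy import stats

        sk = stats.skew(gica_fit.group_maps, axis=0)
        assert (sk > 0).all()

    def test_zscored_maps_over_mask(self, cohort, gica_fit):
        m = gica_fit.group_maps[cohort.mask]
        assert np.allclose(m.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(m.std(axis=0), 1.0, atol=1e-6)

    def test_downstream_stats_invariant_to_sign_flip(self, cohort):
        """Flipping a component's time-course sign flips t but not p."""
        by_subject = [
            [cohort.timecourses[s, r][4:, :2] for r in range(2)] for s in range(5)
        ]
        flipped = [[np.column_stack([-tc[:, 0], tc[:, 1]]) for tc in runs] for runs in by_subject]
        dm = fl.build_design_matrix(cohort.design, trim_volumes=4)
        a = fl.analysis1(by_subject, dm)
        b = fl.analysis1(flipped, dm)
        assert np.allclose(a.p, b.p, atol=1e-12)
        assert np.allclose(a.t[0], -b.t[0], atol=1e-9)
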