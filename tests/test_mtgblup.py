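import numpy as np
import pandas as pd
import pytest

import kinblend as kb
from kinblend.mtgblup import MTModelSpec, TraitCovariances
from oracles import dense_blup, dense_restricted_loglik


def _rand_psd(T, rng, ridge=0.0):
    Z = rng.standard_normal((T, T + 2))
    return Z @ Z.T / (T + 2) + ridge * np.eye(T)


def _rand_instance(rng, n=None, T=None):
    n = n or int(rng.integers(6, 21))
    T = T or int(rng.choice([2, 3]))
    B = rng.standard_normal((n, n + 3))
    K = B @ B.T / (n + 3)
    ids = [f"i{j}" for j in range(n)]
    Y = rng.standard_normal((n, T)) + rng.standard_normal(T)
    return kb.KinshipMatrix(K, ids), pd.DataFrame(Y, index=ids)


def _dummy_fit(spec, Q, R, mu):
    return kb.MTModelFit(
        spec=spec, params=TraitCovariances(Q, R, mu), restricted_loglik=0.0,
        heritabilities=pd.Series(dtype=float), genetic_corr=pd.DataFrame(),
        residual_corr=pd.DataFrame(), phenotypic_corr=pd.DataFrame(),
        se=pd.Series(dtype=float), converged=True, n_iter=0, boundary=False,
    )


class TestRestrictedLoglik:
    def test_matches_dense_formula(self, rng):
        for _ in range(25):
            K, Y = _rand_instance(rng)
            T = Y.shape[1]
            Q, R = _rand_psd(T, rng), _rand_psd(T, rng, 0.5)
            spec = MTModelSpec(Y, K)
            ll = kb.restricted_loglik(spec, TraitCovariances(Q, R, np.zeros(T)))
            lld = dense_restricted_loglik(K.values, Y.to_numpy(), Q, R)
            assert ll == pytest.approx(lld, abs=1e-8)

    def test_permutation_invariance(self, rng):
        K, Y = _rand_instance(rng, n=12, T=3)
        Q, R = _rand_psd(3, rng), _rand_psd(3, rng, 0.5)
        params = TraitCovariances(Q, R, np.zeros(3))
        ll = kb.restricted_loglik(MTModelSpec(Y, K), params)
        perm = rng.permutation(12)
        ids_p = [K.ids[i] for i in perm]
        ll_p = kb.restricted_loglik(
            MTModelSpec(Y.loc[ids_p], K.align(ids_p)), params
        )
        assert ll_p == pytest.approx(ll, abs=1e-8)

    def test_singular_block_gives_minus_inf(self, rng):
        K, Y = _rand_instance(rng, n=8, T=2)
        params = TraitCovariances(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))
        assert kb.restricted_loglik(MTModelSpec(Y, K), params) == -np.inf


class TestRemlFit:
    def test_maximizes_over_documented_starts(self, small_A, small_sim):
        pheno = pd.DataFrame(
            small_sim.phenotypes_raw, index=small_sim.ids,
            columns=list(small_sim.truth.trait_names),
        )
        spec = MTModelSpec(pheno, small_A)
        fit = kb.reml_fit(spec, compute_se=False)
        S = np.cov(pheno.to_numpy(), rowvar=False)
        for f in (0.5, 0.1, 0.9):
            start = TraitCovariances(f * S, (1 - f) * S, pheno.mean().to_numpy())
            assert fit.restricted_loglik >= kb.restricted_loglik(spec, start) - 1e-6

    def test_fit_loglik_consistent_with_evaluator(self, small_A, small_corrected):
        spec = MTModelSpec(small_corrected, small_A)
        fit = kb.reml_fit(spec, compute_se=False)
        assert fit.restricted_loglik == pytest.approx(
            kb.restricted_loglik(spec, fit.params), abs=1e-6
        )

    def test_duplicate_trait_hits_correlation_boundary(self, small_A, small_corrected):
        pheno = small_corrected[["trait1", "trait2"]].copy()
        pheno["trait2"] = pheno["trait1"]
        fit = kb.reml_fit(MTModelSpec(pheno, small_A), compute_se=False)
        assert fit.genetic_corr.iloc[0, 1] > 0.99
        assert fit.residual_corr.iloc[0, 1] > 0.99
        assert fit.boundary

    def test_scale_equivariance(self, small_A, small_corrected):
        f1 = kb.reml_fit(MTModelSpec(small_corrected, small_A), compute_se=False)
        scaled = small_corrected.copy()
        scaled["trait2"] = scaled["trait2"] * 7.3
        f2 = kb.reml_fit(MTModelSpec(scaled, small_A), compute_se=False)
        assert np.abs(
            f1.heritabilities.values - f2.heritabilities.values
        ).max() < 1e-6
        assert np.abs(f1.genetic_corr.values - f2.genetic_corr.values).max() < 1e-6
        assert f2.params.Q[1, 1] / f1.params.Q[1, 1] == pytest.approx(7.3**2, rel=1e-6)

    def test_identity_kinship_rejected(self, rng):
        ids = [f"i{j}" for j in range(20)]
        K = kb.KinshipMatrix(np.eye(20), ids)
        Y = pd.DataFrame(rng.standard_normal((20, 2)), index=ids)
        with pytest.raises(ValueError, match="proportional to I"):
            kb.reml_fit(MTModelSpec(Y, K))

    def test_missing_phenotypes_rejected(self, small_A):
        Y = pd.DataFrame(np.ones((small_A.n, 2)), index=small_A.ids)
        Y.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            MTModelSpec(Y, small_A)


class TestDeriveParameters:
    def test_textbook_values(self):
        Q = np.array([[1.0, 0.5], [0.5, 1.0]])
        R = np.array([[3.0, 0.0], [0.0, 1.0]])
        out = kb.derive_parameters(TraitCovariances(Q, R, np.zeros(2)))
        assert out["h2"].iloc[0] == pytest.approx(0.25)
        assert out["r_G"].iloc[0, 1] == pytest.approx(0.5)
        assert out["r_P"].iloc[0, 1] == pytest.approx(0.5 / np.sqrt(4 * 2))

    def test_zero_variance_gives_nan(self):
        Q = np.array([[0.0, 0.0], [0.0, 1.0]])
        out = kb.derive_parameters(TraitCovariances(Q, np.eye(2), np.zeros(2)))
        assert np.isnan(out["r_G"].iloc[0, 1])
        assert out["h2"].iloc[0] == 0.0


class TestPredictDGV:
    def test_matches_dense_mme_oracle(self, rng):
        for _ in range(10):
            ntr, ntg, T = 12, 4, 2
            n = ntr + ntg
            B = rng.standard_normal((n, n + 3))
            K = B @ B.T / (n + 3)
            ids = [f"i{j}" for j in range(n)]
            Kfull = kb.KinshipMatrix(K, ids)
            Y = pd.DataFrame(rng.standard_normal((ntr, T)), index=ids[:ntr])
            Q, R = _rand_psd(T, rng), _rand_psd(T, rng, 0.5)
            mu = rng.standard_normal(T)
            spec = MTModelSpec(Y, Kfull.align(ids[:ntr]))
            fit = _dummy_fit(spec, Q, R, mu)
            pred = kb.predict_dgv(fit, Kfull, ids[:ntr], ids[ntr:])
            oracle = dense_blup(K, Y.to_numpy(), Q, R, mu,
                                np.arange(ntr), np.arange(ntr, n))
            np.testing.assert_allclose(pred.values.to_numpy(), oracle, atol=1e-8)

    def test_unrelated_target_predicts_zero(self, rng):
        ntr, T = 10, 2
        B = rng.standard_normal((ntr, ntr + 3))
        Ktr = B @ B.T / (ntr + 3)
        K = np.block([[Ktr, np.zeros((ntr, 2))],
                      [np.zeros((2, ntr)), np.eye(2)]])
        ids = [f"i{j}" for j in range(ntr + 2)]
        Kfull = kb.KinshipMatrix(K, ids)
        Y = pd.DataFrame(rng.standard_normal((ntr, T)), index=ids[:ntr])
        fit = _dummy_fit(MTModelSpec(Y, Kfull.align(ids[:ntr])),
                         _rand_psd(T, rng), _rand_psd(T, rng, 0.5),
                         np.zeros(T))
        pred = kb.predict_dgv(fit, Kfull, ids[:ntr], ids[ntr:])
        np.testing.assert_allclose(pred.values.to_numpy(), 0.0, atol=1e-10)

    def test_same_kernel_same_predictions(self, small_A, small_GV, small_corrected):
        """A blend at lambda = 0 is the pedigree kernel, so predictions match."""
        ids = list(small_corrected.index)
        train, test = ids[: int(0.6 * len(ids))], ids[int(0.6 * len(ids)):]
        K0 = kb.blend_kernels(small_GV.align(ids), small_A.align(ids), 0.0)
        fit_a = kb.reml_fit(MTModelSpec(small_corrected.loc[train],
                                        small_A.align(train)), compute_se=False)
        p_a = kb.predict_dgv(fit_a, small_A.align(ids), train, test)
        p_0 = kb.predict_dgv(fit_a, K0, train, test)
        np.testing.assert_allclose(p_a.values.to_numpy(), p_0.values.to_numpy())


def test_parameter_recovery_three_traits():
    """REML on a 750-member pedigree recovers the generating h2 and r_G to
    well within their reported standard errors."""
    cfg = kb.SimConfig(n_founders=150, n_generations=2, n_sires=20, n_dams=60,
                       offspring_per_mating=5, n_snps=20, n_qtl=0,
                       nuisance_levels={}, seed=314)
    ped = kb.simulate_pedigree(cfg)
    ds = kb.simulate_traits(ped, None, cfg)
    A = kb.build_A(ped)
    pheno = pd.DataFrame(ds.phenotypes_raw, index=ds.ids,
                         columns=list(cfg.trait_names))
    fit = kb.reml_fit(MTModelSpec(pheno, A))
    truth = kb.derive_parameters(
        TraitCovariances(cfg.Q_true, cfg.R_true, np.zeros(3)),
        cfg.trait_names,
    )
    for t, name in enumerate(cfg.trait_names):
        se = fit.se[f"h2:{name}"]
        assert abs(fit.heritabilities.iloc[t] - truth["h2"].iloc[t]) < 3 * se
    names = list(cfg.trait_names)
    for i in range(3):
        for j in range(i + 1, 3):
            se = fit.se[f"r_G:{names[i]}:{names[j]}"]
            assert abs(fit.genetic_corr.iloc[i, j]
                       - truth["r_G"].iloc[i, j]) < 3 * se
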