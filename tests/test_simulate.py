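import numpy as np
import pytest

import kinblend as kb


def _founder_cfg(n, seed=0, **kw):
    return kb.SimConfig(n_founders=n, n_generations=0, n_snps=kw.pop("n_snps", 50),
                        n_qtl=kw.pop("n_qtl", 10), seed=seed, **kw)


class TestSimulatePedigree:
    def test_minimal_mating_design(self):
        cfg = kb.SimConfig(n_founders=2, n_generations=1, n_sires=1, n_dams=1,
                           offspring_per_mating=2, n_snps=10, n_qtl=0)
        ped = kb.simulate_pedigree(cfg)
        assert len(ped) == 4
        sibs = [i for i in range(4) if ped.sire[i] >= 0]
        assert len(sibs) == 2
        assert ped.sire[sibs[0]] == ped.sire[sibs[1]]
        assert ped.dam[sibs[0]] == ped.dam[sibs[1]]

    def test_zero_generations_founders_only(self):
        ped = kb.simulate_pedigree(_founder_cfg(15))
        assert len(ped) == 15 and ped.is_founder.all()

    def test_deterministic_given_seed(self):
        cfg = kb.SimConfig(n_founders=30, n_generations=2, n_sires=5, n_dams=15,
                           offspring_per_mating=2, n_snps=10, n_qtl=0, seed=4)
        p1, p2 = kb.simulate_pedigree(cfg), kb.simulate_pedigree(cfg)
        assert p1.ids == p2.ids
        assert (p1.sire == p2.sire).all() and (p1.dam == p2.dam).all()

    def test_no_selfing(self, small_sim):
        ped = small_sim.pedigree
        both = (ped.sire >= 0) & (ped.dam >= 0)
        assert (ped.sire[both] != ped.dam[both]).all()

    def test_impossible_design_errors(self):
        with pytest.raises(ValueError):
            kb.SimConfig(n_founders=10, n_generations=1, n_sires=8, n_dams=0,
                         n_snps=10, n_qtl=0)
        cfg = kb.SimConfig(n_founders=5, n_generations=1, n_sires=4, n_dams=4,
                           offspring_per_mating=1, n_snps=10, n_qtl=0)
        with pytest.raises(ValueError, match="candidates"):
            kb.simulate_pedigree(cfg)


class TestGeneDrop:
    def test_founder_frequency_expectation(self):
        cfg = _founder_cfg(600, seed=8, n_snps=200)
        ped = kb.simulate_pedigree(cfg)
        geno = kb.gene_drop_genotypes(ped, cfg)
        p = geno.allele_freq
        rng_cfg = cfg.substreams()["genotypes"]
        truth = rng_cfg.uniform(*cfg.founder_maf_range, size=cfg.n_snps)
        se = np.sqrt(truth * (1 - truth) / (2 * 600))
        z = np.abs(p - truth) / se
        assert np.mean(z < 3) > 0.98 and z.max() < 6

    def test_mendelian_consistency(self, small_sim):
        ped, codes = small_sim.pedigree, small_sim.genotypes.codes
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0:
                continue
            lo = (codes[s] == 2).astype(int) + (codes[d] == 2).astype(int)
            hi = 2 - (codes[s] == 0).astype(int) - (codes[d] == 0).astype(int)
            assert ((codes[i] >= lo) & (codes[i] <= hi)).all()

    def test_offspring_of_homozygous_ref_parents(self):
        ped = kb.Pedigree.from_records(
            [("a", None, None), ("b", None, None), ("c", "a", "b")]
        )
        cfg = kb.SimConfig(n_founders=2, n_snps=2000, n_qtl=0,
                           founder_maf_range=(0.01, 0.02), seed=1)
        geno = kb.gene_drop_genotypes(ped, cfg)
        zero = (geno.codes[0] == 0) & (geno.codes[1] == 0)
        assert zero.any()
        assert (geno.codes[2][zero] == 0).all()

    def test_fullsib_ibs_exceeds_unrelated(self, small_sim):
        """IBS sharing among full sibs beats pedigree-unrelated founder pairs."""
        ped, codes = small_sim.pedigree, small_sim.genotypes.codes

        def ibs(i, j):
            return np.mean(1.0 - np.abs(codes[i] - codes[j]) / 2.0)

        rng = np.random.default_rng(0)
        sib_pairs, unrel_pairs = [], []
        fam = {}
        for i in range(ped.n):
            if ped.sire[i] >= 0:
                fam.setdefault((ped.sire[i], ped.dam[i]), []).append(i)
        for members in fam.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    sib_pairs.append((members[a], members[b]))
        founders = np.nonzero(ped.is_founder)[0]
        while len(unrel_pairs) < 1000:
            i, j = rng.choice(founders, 2, replace=False)
            unrel_pairs.append((i, j))
        sib_mean = np.mean([ibs(i, j) for i, j in sib_pairs[:1000]])
        unrel_mean = np.mean([ibs(i, j) for i, j in unrel_pairs])
        assert sib_mean > unrel_mean + 0.01

    def test_missingness_rate_applied(self):
        cfg = _founder_cfg(100, seed=3, n_snps=300, missing_rate=0.1)
        ped = kb.simulate_pedigree(cfg)
        geno = kb.gene_drop_genotypes(ped, cfg)
        frac = np.isnan(geno.codes).mean()
        assert 0.08 < frac < 0.12


class TestSimulateTraits:
    def test_founder_bv_covariance_matches_Q(self):
        cfg = _founder_cfg(2500, seed=12, nuisance_levels={})
        ped = kb.simulate_pedigree(cfg)
        ds = kb.simulate_traits(ped, None, cfg)
        S = np.cov(ds.true_breeding_values, rowvar=False)
        Q = cfg.Q_true
        n = 2500
        for i in range(3):
            for j in range(3):
                se = np.sqrt((Q[i, i] * Q[j, j] + Q[i, j] ** 2) / (n - 1))
                assert abs(S[i, j] - Q[i, j]) < 3 * se

    def test_heritability_by_construction(self):
        Q = np.diag([0.3, 0.5, 0.2])
        R = np.diag([0.7, 0.5, 0.8])
        cfg = kb.SimConfig(n_founders=2500, n_generations=0, n_snps=20, n_qtl=0,
                           Q_true=Q, R_true=R, nuisance_levels={}, seed=21)
        ped = kb.simulate_pedigree(cfg)
        ds = kb.simulate_traits(ped, None, cfg)
        vg = ds.true_breeding_values.var(axis=0, ddof=1)
        ve = ds.residuals.var(axis=0, ddof=1)
        h2 = vg / (vg + ve)
        truth = np.diag(Q) / (np.diag(Q) + np.diag(R))
        # delta-method MC standard error of the variance ratio
        n = 2500
        se = np.sqrt(2.0 / (n - 1)) * truth * (1 - truth) * np.sqrt(
            1 / truth**2 + 1 / (1 - truth) ** 2
        ) / np.sqrt(2)
        assert (np.abs(h2 - truth) < 3 * np.maximum(se, 0.01)).all()

    def test_phenotype_reconstruction(self, small_sim):
        recon = (small_sim.truth.intercepts + small_sim.nuisance_effects
                 + small_sim.true_breeding_values + small_sim.residuals)
        np.testing.assert_allclose(small_sim.phenotypes_raw, recon, atol=1e-12)

    def test_near_zero_genetic_variance_limit(self):
        cfg = kb.SimConfig(
            n_founders=800, n_generations=0, n_snps=20, n_qtl=0,
            Q_true=1e-8 * np.eye(3), R_true=np.eye(3),
            nuisance_levels={}, seed=5,
        )
        ped = kb.simulate_pedigree(cfg)
        ds = kb.simulate_traits(ped, None, cfg)
        C = np.corrcoef(ds.phenotypes_raw, rowvar=False)
        off = C[np.triu_indices(3, k=1)]
        assert np.abs(off).max() < 0.1

    def test_bitwise_determinism(self):
        cfg = kb.SimConfig(n_founders=40, n_generations=1, n_sires=8, n_dams=20,
                           offspring_per_mating=2, n_snps=60, n_qtl=10, seed=77)
        d1, d2 = kb.simulate(cfg), kb.simulate(cfg)
        assert (d1.genotypes.codes == d2.genotypes.codes).all()
        assert (d1.phenotypes_raw == d2.phenotypes_raw).all()
        assert (d1.true_breeding_values == d2.true_breeding_values).all()
        assert d1.nuisance_assignments.equals(d2.nuisance_assignments)

    def test_qtl_architecture_trace_matches(self, small_sim):
        cfg = kb.SimConfig(n_founders=400, n_generations=0, n_snps=300, n_qtl=60,
                           architecture="pleiotropic_qtl", nuisance_levels={},
                           seed=9)
        ped = kb.simulate_pedigree(cfg)
        geno = kb.gene_drop_genotypes(ped, cfg)
        ds = kb.simulate_traits(ped, geno, cfg)
        S = np.cov(ds.true_breeding_values, rowvar=False)
        assert np.trace(S) == pytest.approx(np.trace(cfg.Q_true), rel=1e-6)

    def test_invalid_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="positive definite"):
            kb.SimConfig(n_founders=10, n_snps=10, n_qtl=0, Q_true=bad,
                         R_true=np.eye(2))
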