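import numpy as np
import pandas as pd
import pytest

from epiblup.epirel import build_lambda_dense
from epiblup.models import VarianceComponents
from epiblup.simulate import (ConfigurationError, SimulationConfig,
                              simulate_dataset, simulate_effects,
                              simulate_genotypes, simulate_pedigree,
                              simulate_phenotypes)


def expansion_config(**kw):
    base = dict(n_founders=20, n_generations=3, dams_per_sire=2,
                litters_per_dam=1, litter_size_mean=6.0,
                target_generation_size=None, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestPedigreeSim:
    def test_founders_only(self):
        ped = simulate_pedigree(SimulationConfig(n_founders=20,
                                                 n_generations=1, seed=1))
        assert ped.n == 20
        assert (ped.sire == 0).all() and (ped.dam == 0).all()

    def test_topological_order_always(self):
        for seed in range(3):
            ped = simulate_pedigree(expansion_config(seed=seed))
            for i in range(1, ped.n + 1):
                s, d = ped.parents(i)
                assert s < i and d < i

    def test_mating_design_recount(self):
        cfg = expansion_config()
        ped = simulate_pedigree(cfg)
        df = ped.to_frame()
        for g in range(1, 3):
            cur = df[df.generation == g]
            prev = df[df.generation == g - 1]
            prev_females = set(prev.loc[prev.sex == 2, "id"])
            prev_males = set(prev.loc[prev.sex == 1, "id"])
            # every dam is a previous-generation female with exactly
            # litters_per_dam litters; sires serve <= dams_per_sire dams
            by_dam = cur.groupby("dam")
            assert set(by_dam.groups) <= prev_females
            assert len(set(cur["dam"])) == len(prev_females)
            for _, rows in by_dam:
                assert rows["litter"].nunique() == cfg.litters_per_dam
            assert set(cur["sire"]) <= prev_males
            for _, rows in cur.groupby("sire"):
                assert rows["dam"].nunique() <= cfg.dams_per_sire
            sizes = cur.groupby("litter").size()
            assert sizes.between(3, 20).all()

    def test_bitwise_reproducible(self):
        a = simulate_dataset(expansion_config(), with_genotypes=True)
        b = simulate_dataset(expansion_config(), with_genotypes=True)
        assert np.array_equal(a.pedigree.sire, b.pedigree.sire)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
        assert np.array_equal(a.true_effects.xi, b.true_effects.xi)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_founders=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_generations=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(reset_nu=1.5)


class TestEffects:
    def test_zero_epigenetic_variance(self):
        cfg = expansion_config(true_varcomps=VarianceComponents(
            sigma2_u=0.1, sigma2_q=0.1, sigma2_xi=0.0, sigma2_e=0.8))
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, cfg)
        assert np.all(eff.xi == 0.0)

    def test_full_reset_gives_iid_xi(self):
        cfg = SimulationConfig(n_founders=120, n_generations=5,
                               target_generation_size=1200, reset_nu=1.0,
                               true_varcomps=VarianceComponents(
                                   sigma2_u=0.1, sigma2_q=0.1,
                                   sigma2_xi=1.0, sigma2_e=0.3),
                               seed=9)
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, cfg)
        kids = np.nonzero(ped.sire > 0)[0]
        cov = np.cov(eff.xi[kids], eff.xi[ped.sire[kids] - 1])[0, 1]
        assert abs(cov) < 3.0 / np.sqrt(len(kids))

    def test_xi_variance_and_parent_offspring_covariance(self):
        cfg = SimulationConfig(n_founders=200, n_generations=5,
                               target_generation_size=1200,
                               reset_nu=0.9,
                               true_varcomps=VarianceComponents(
                                   sigma2_u=0.1, sigma2_q=0.1,
                                   sigma2_xi=1.0, sigma2_e=0.3),
                               seed=10)
        ped = simulate_pedigree(cfg)
        eff = simulate_effects(ped, cfg)
        assert ped.n > 4000
        assert abs(eff.xi.var() - 1.0) < 0.05

    def test_xi_covariance_matches_lambda_on_fixed_pedigree(self):
        # 10-animal pedigree: empirical covariance across many replicates
        # must match the Lambda entries times sigma2_xi
        from epiblup.pedigree import Pedigree
        ped = Pedigree(sire=[0, 0, 0, 0, 1, 1, 3, 5, 5, 7],
                       dam=[0, 0, 0, 0, 2, 4, 4, 6, 6, 8])
        vc = VarianceComponents(sigma2_xi=1.0, sigma2_e=1.0)
        n_rep = 4000
        xis = np.empty((n_rep, 10))
        for r in range(n_rep):
            cfg = SimulationConfig(n_founders=10, n_generations=1,
                                   reset_nu=0.8, true_varcomps=vc,
                                   seed=10_000 + r)
            xis[r] = simulate_effects(ped, cfg).xi
        emp = np.cov(xis.T)
        lam_mat = build_lambda_dense(ped, 0.1)
        # Monte-Carlo error of a covariance at n=4000 is about 0.03
        assert np.abs(emp - lam_mat).max() < 0.08

    def test_unsorted_pedigree_rejected(self):
        from epiblup.pedigree import Pedigree, PedigreeError
        with pytest.raises(PedigreeError):
            Pedigree(sire=[2, 0], dam=[0, 0])


class TestPhenotypeSim:
    def test_no_noise_phenotype_is_fixed_effect_sum(self):
        vc = VarianceComponents(sigma2_u=0.0, sigma2_q=0.0, sigma2_xi=0.0,
                                sigma2_e=0.0)
        cfg = expansion_config(true_varcomps=vc)
        data = simulate_dataset(cfg)
        t = data.phenotypes
        # y must lie exactly in the column space of the fixed-effect design
        cells = t[["sex", "parity", "year", "month", "farm"]].astype(str).agg(
            "-".join, axis=1)
        x = pd.get_dummies(cells, dtype=float).to_numpy()
        x = np.column_stack([x, t["covariate"].to_numpy()])
        resid = t["value"].to_numpy() - x @ np.linalg.lstsq(
            x, t["value"].to_numpy(), rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

    def test_repeated_records_per_female(self):
        cfg = expansion_config(trait_kind="repeated_record", n_parities=3,
                               true_varcomps=VarianceComponents(
                                   sigma2_u=0.5, sigma2_pe=0.6,
                                   sigma2_xi=0.5, sigma2_e=9.8))
        data = simulate_dataset(cfg)
        counts = data.phenotypes.groupby("animal").size()
        assert (counts == 3).all()

    def test_variance_decomposition_recovered(self):
        from epiblup.simulate import FixedEffectConfig
        fx = FixedEffectConfig(intercept=0.0, sex_effect=0.0,
                               parity_effect_sd=0.0, cg_effect_sd=0.0,
                               covariate_slope=0.0)
        cfg = SimulationConfig(seed=12, fixed_effects=fx)
        data = simulate_dataset(cfg)
        assert len(data.phenotypes) > 2000
        total = cfg.true_varcomps.total
        assert abs(data.phenotypes["value"].var() - total) / total < 0.10


class TestGenotypeSim:
    def test_fixed_founder_snps_stay_fixed(self):
        cfg = expansion_config(founder_allele_freq_range=(0.95, 0.99),
                               n_snps=120)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        founders = ped.generation == 0
        fixed = np.nonzero((geno.codes[founders] == 2).all(axis=0))[0]
        assert fixed.size > 0
        assert (geno.codes[:, fixed] == 2).all()

    def test_realized_frequency_binomial(self):
        cfg = SimulationConfig(n_founders=2000, n_generations=1,
                               founder_allele_freq_range=(0.5, 0.5),
                               n_snps=200, seed=8)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        freqs = geno.allele_frequencies()
        se = np.sqrt(0.25 / (2 * 2000))
        assert abs(freqs.mean() - 0.5) < 4 * se / np.sqrt(200) + 1e-3
        assert (np.abs(freqs - 0.5) < 5 * se).mean() > 0.95

    def test_deterministic(self):
        cfg = expansion_config(n_snps=50)
        ped = simulate_pedigree(cfg)
        a = simulate_genotypes(ped, cfg)
        b = simulate_genotypes(ped, cfg)
        assert np.array_equal(a.codes, b.codes)

    def test_zero_snps_rejected(self):
        cfg = expansion_config()
        ped = simulate_pedigree(cfg)
        object.__setattr__(cfg, "n_snps", 0)
        with pytest.raises(ConfigurationError):
            simulate_genotypes(ped, cfg)
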