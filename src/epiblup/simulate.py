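"""Synthetic nucleus-herd data with known truth for recovery testing.

Generates a multi-generation pig-breeding pedigree with discrete,
non-overlapping generations and random mating, true genetic / epigenetic /
environmental effects with the exact covariance structure the models assume,
phenotypes for a single-record trait (direct + maternal + common-litter +
epigenetic, birth-weight-like) or a repeated-record trait (direct +
permanent-environment + epigenetic, litter-size-like), and optional SNP
genotypes by gene dropping.

Epigenetic effects follow ξ_i = λ(ξ_sire + ξ_dam) + ε_i with
Var(ε_i) = d_i σ²ξ and λ = 0.5(1 − ν); additive effects follow pedigree gene
flow with Mendelian sampling variance shrunk by parental inbreeding.  All
randomness flows from one root seed through per-component substreams, so a
dataset regenerates bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epirel import reset_to_lambda
from .genomic import GenotypeMatrix
from .models import VarianceComponents
from .pedigree import Pedigree, mendelian_variances

MALE, FEMALE = 1, 2


class ConfigurationError(ValueError):
    pass


@dataclass
class FixedEffectConfig:
    """Levels and magnitudes of the systematic effects in simulated records."""

    intercept: float = 10.0
    sex_effect: float = 0.5          # added for females (single-record trait)
    n_parity_levels: int = 4
    parity_effect_sd: float = 0.3
    n_farms: int = 3
    cg_effect_sd: float = 0.5        # contemporary-group (year-month-farm)
    covariate_slope: float = 0.25
    covariate_sd: float = 1.0


def _default_varcomps() -> VarianceComponents:
    # single-record defaults on a unit phenotypic scale: moderate epigenetic
    # variance (h²ξ = 0.30 at ν = 0.9), low direct heritability (h²u = 0.10)
    # and a common-litter fraction typical of piglet traits
    return VarianceComponents(sigma2_u=0.10, sigma2_q=0.15, sigma2_xi=0.30,
                              sigma2_e=0.45)


def repeated_record_varcomps() -> VarianceComponents:
    """Litter-size-like truth: low h²u and h²ξ, moderate repeatability."""
    return VarianceComponents(sigma2_u=0.55, sigma2_pe=0.60, sigma2_xi=0.50,
                              sigma2_e=9.80)


@dataclass
class SimulationConfig:
    """Design and truth of one synthetic dataset.

    With ``target_generation_size`` set, each generation mates just enough
    dams to reproduce roughly that many offspring; with ``None`` every
    available female is mated (pure expansion).  Litter sizes are Poisson
    with mean ``litter_size_mean`` truncated to [3, 20].
    """

    n_founders: int = 100
    n_generations: int = 5
    dams_per_sire: int = 3
    litters_per_dam: int = 1
    litter_size_mean: float = 8.0
    target_generation_size: int | None = 600
    trait_kind: str = "single_record"
    n_parities: int = 3
    true_varcomps: VarianceComponents = field(default_factory=_default_varcomps)
    reset_nu: float = 0.9
    fixed_effects: FixedEffectConfig = field(default_factory=FixedEffectConfig)
    founder_allele_freq_range: tuple[float, float] = (0.1, 0.9)
    n_snps: int = 500
    seed: int = 1

    def __post_init__(self):
        if self.n_founders < 1 or self.n_generations < 1:
            raise ConfigurationError("need at least one founder and one "
                                     "generation")
        if not 0.0 <= self.reset_nu <= 1.0:
            raise ConfigurationError("reset coefficient must be in [0, 1]")
        if self.trait_kind not in ("single_record", "repeated_record"):
            raise ConfigurationError(f"unknown trait kind {self.trait_kind}")
        lo, hi = self.founder_allele_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigurationError("founder allele frequencies must lie "
                                     "in (0, 1)")

    @property
    def lam(self) -> float:
        return reset_to_lambda(self.reset_nu)


@dataclass
class TrueEffects:
    """Per-animal truth; absent components are all-zero vectors."""

    u: np.ndarray
    m: np.ndarray
    q_litter: np.ndarray   # one value per litter code (1-based)
    pe: np.ndarray
    xi: np.ndarray


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    true_effects: TrueEffects
    config: SimulationConfig
    genotypes: GenotypeMatrix | None = None

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(out / "pedigree.csv")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        if self.genotypes is not None:
            self.genotypes.write(out / "genotypes.txt", out / "snp_map.txt")
        truth = {
            "config": _config_dict(self.config),
            "effects": {k: np.asarray(v).tolist()
                        for k, v in asdict(self.true_effects).items()},
        }
        (out / "truth.json").write_text(json.dumps(truth))


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["true_varcomps"] = config.true_varcomps.as_dict()
    return d


def _substream(config: SimulationConfig, name: str) -> np.random.Generator:
    tags = {"pedigree": 1, "effects": 2, "phenotypes": 3, "genotypes": 4}
    return np.random.default_rng([config.seed, tags[name]])


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Discrete non-overlapping generations under random mating.

    Founders (generation 0) have unknown parents and alternating sex; every
    later animal has both parents drawn from the previous generation.  Litter
    membership is recorded for all non-founders.
    """
    rng = _substream(config, "pedigree")
    sire, dam, gen, sex, litter = [], [], [], [], []
    for _ in range(config.n_founders):
        sire.append(0)
        dam.append(0)
        gen.append(0)
        litter.append(0)
    sex.extend((MALE if i % 2 == 0 else FEMALE)
               for i in range(config.n_founders))

    litter_counter = 0
    prev = list(range(1, config.n_founders + 1))
    for g in range(1, config.n_generations):
        males = [a for a in prev if sex[a - 1] == MALE]
        females = [a for a in prev if sex[a - 1] == FEMALE]
        if not males or not females:
            break
        rng.shuffle(males)
        rng.shuffle(females)
        if config.target_generation_size is not None:
            need = int(np.ceil(config.target_generation_size
                               / (config.litters_per_dam
                                  * config.litter_size_mean)))
            females = females[:max(1, min(need, len(females)))]
        n_sires = max(1, int(np.ceil(len(females) / config.dams_per_sire)))
        sires = (males * n_sires)[:n_sires]
        cur = []
        for k, d in enumerate(females):
            s = sires[k % n_sires]
            for _ in range(config.litters_per_dam):
                litter_counter += 1
                size = int(np.clip(rng.poisson(config.litter_size_mean),
                                   3, 20))
                for _ in range(size):
                    sire.append(s)
                    dam.append(d)
                    gen.append(g)
                    litter.append(litter_counter)
                    sex.append(MALE if rng.random() < 0.5 else FEMALE)
                    cur.append(len(sire))
        prev = cur
    return Pedigree(sire=np.asarray(sire), dam=np.asarray(dam),
                    generation=np.asarray(gen),
                    sex=np.asarray(sex, dtype=np.int8),
                    litter=np.asarray(litter))


def simulate_effects(ped: Pedigree, config: SimulationConfig) -> TrueEffects:
    """Draw true u, m, q, pe and ξ with the model covariance structure.

    (u, m) flow through the pedigree jointly with Mendelian sampling variance
    d_i G0, G0 the 2×2 direct–maternal (co)variance; q is iid per litter, pe
    iid per animal, and ξ follows the epigenetic recursion with residual
    variance d_i σ²ξ (d_i = 1−2λ², 1−λ² or 1 by number of known parents).
    """
    rng = _substream(config, "effects")
    vc = config.true_varcomps
    n = ped.n
    lam = config.lam

    s2u = vc.sigma2_u or 0.0
    s2m = vc.sigma2_m or 0.0
    cum = vc.cov_um or 0.0
    g0 = np.array([[s2u, cum], [cum, s2m]])
    # exact PSD square root (handles zero/singular direct-maternal blocks)
    evals, evecs = np.linalg.eigh(g0)
    chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    d_gen = mendelian_variances(ped)
    um = np.zeros((n + 1, 2))
    z = rng.standard_normal((n, 2))
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        parent_avg = 0.5 * (um[s] + um[d])
        um[i] = parent_avg + np.sqrt(d_gen[i - 1]) * (chol @ z[i - 1])
    u, m = um[1:, 0].copy(), um[1:, 1].copy()

    s2xi = vc.sigma2_xi or 0.0
    xi = np.zeros(n + 1)
    zx = rng.standard_normal(n)
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        n_known = (s > 0) + (d > 0)
        d_epi = 1.0 - (2.0 if n_known == 2 else float(n_known)) * lam * lam
        xi[i] = lam * (xi[s] + xi[d]) + np.sqrt(d_epi * s2xi) * zx[i - 1]
    xi = xi[1:]

    n_litters = int(ped.litter.max()) if ped.litter is not None else 0
    q = (rng.standard_normal(n_litters) * np.sqrt(vc.sigma2_q)
         if vc.sigma2_q else np.zeros(n_litters))
    pe = (rng.standard_normal(n) * np.sqrt(vc.sigma2_pe)
          if vc.sigma2_pe else np.zeros(n))
    return TrueEffects(u=u, m=m, q_litter=q, pe=pe, xi=xi)


def _cg_fields(rng, n, generation, fx: FixedEffectConfig):
    year = 2014 + generation
    month = rng.integers(1, 13, size=n)
    farm = rng.integers(1, fx.n_farms + 1, size=n)
    return year, month, farm


def _cg_effects(rng, year, month, farm, fx: FixedEffectConfig):
    keys = [f"{y}-{mo}-{f}" for y, mo, f in zip(year, month, farm)]
    uniq = sorted(set(keys))
    eff = dict(zip(uniq, rng.standard_normal(len(uniq)) * fx.cg_effect_sd))
    return np.array([eff[k] for k in keys])


def simulate_phenotypes(ped: Pedigree, effects: TrueEffects,
                        config: SimulationConfig) -> pd.DataFrame:
    """Phenotype records with systematic effects plus the true random effects.

    single_record: one record per non-founder,
        y = fixed + u + m_dam + q_litter + ξ + e.
    repeated_record: ``n_parities`` records per non-founder female,
        y = fixed + u + pe + ξ + e, with a litter_size column.
    """
    rng = _substream(config, "phenotypes")
    vc = config.true_varcomps
    fx = config.fixed_effects
    sd_e = np.sqrt(vc.sigma2_e)
    parity_eff = rng.standard_normal(fx.n_parity_levels) * fx.parity_effect_sd

    if config.trait_kind == "single_record":
        rec = np.nonzero((ped.sire > 0) & (ped.dam > 0))[0] + 1
        if rec.size == 0:
            raise ValueError("no animals with known dam and litter to record")
        n = rec.size
        gen = ped.generation[rec - 1]
        year, month, farm = _cg_fields(rng, n, gen, fx)
        cg_eff = _cg_effects(rng, year, month, farm, fx)
        parity = rng.integers(1, fx.n_parity_levels + 1, size=n)
        cov = rng.standard_normal(n) * fx.covariate_sd
        sexes = ped.sex[rec - 1]
        dams = ped.dam[rec - 1]
        litters = ped.litter[rec - 1]
        fixed = (fx.intercept + fx.sex_effect * (sexes == FEMALE)
                 + parity_eff[parity - 1] + cg_eff + fx.covariate_slope * cov)
        y = (fixed + effects.u[rec - 1] + effects.m[dams - 1]
             + effects.q_litter[litters - 1]
             + effects.xi[rec - 1] + rng.standard_normal(n) * sd_e)
        return pd.DataFrame({
            "animal": rec, "value": y, "sex": sexes, "parity": parity,
            "farm": farm, "year": year, "month": month, "covariate": cov,
            "litter": litters, "dam": dams,
        })

    females = np.nonzero((ped.sex == FEMALE) & (ped.sire > 0)
                         & (ped.dam > 0))[0] + 1
    if females.size == 0:
        raise ValueError("no non-founder females to record")
    rec = np.repeat(females, config.n_parities)
    parity = np.tile(np.arange(1, config.n_parities + 1), females.size)
    n = rec.size
    gen = ped.generation[rec - 1] + (parity - 1)
    year, month, farm = _cg_fields(rng, n, gen, fx)
    cg_eff = _cg_effects(rng, year, month, farm, fx)
    cov = rng.standard_normal(n) * fx.covariate_sd
    p_idx = np.minimum(parity, fx.n_parity_levels) - 1
    fixed = (fx.intercept + parity_eff[p_idx] + cg_eff
             + fx.covariate_slope * cov)
    y = (fixed + effects.u[rec - 1] + effects.pe[rec - 1]
         + effects.xi[rec - 1] + rng.standard_normal(n) * sd_e)
    litter_size = np.clip(rng.poisson(13.0, size=n), 1, 25)
    return pd.DataFrame({
        "animal": rec, "value": y, "sex": np.full(n, FEMALE, dtype=np.int8),
        "parity": parity, "farm": farm, "year": year, "month": month,
        "covariate": cov, "litter_size": litter_size,
        "dam": ped.dam[rec - 1],
    })


def simulate_genotypes(ped: Pedigree, config: SimulationConfig
                       ) -> GenotypeMatrix:
    """Gene dropping: founder alleles at uniform-drawn frequencies, one
    allele transmitted from each parent per SNP."""
    if config.n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    rng = _substream(config, "genotypes")
    n, m = ped.n, config.n_snps
    lo, hi = config.founder_allele_freq_range
    p = rng.uniform(lo, hi, size=m)
    alleles = np.zeros((n + 1, m, 2), dtype=np.int8)
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        for k, par in enumerate((s, d)):
            if par == 0:
                alleles[i, :, k] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                alleles[i, :, k] = alleles[par, np.arange(m), pick]
    codes = alleles[1:].sum(axis=2).astype(np.int16)
    snp_map = pd.DataFrame({
        "snp": [f"snp{j + 1}" for j in range(m)],
        "chrom": rng.integers(1, 19, size=m),
        "pos": np.arange(1, m + 1) * 1000,
    })
    return GenotypeMatrix(individuals=ped.ids, codes=codes, snp_map=snp_map)


def simulate_dataset(config: SimulationConfig,
                     with_genotypes: bool = False) -> SimulatedDataset:
    """Full dataset: pedigree, true effects, phenotypes, optional genotypes."""
    ped = simulate_pedigree(config)
    effects = simulate_effects(ped, config)
    phen = simulate_phenotypes(ped, effects, config)
    geno = simulate_genotypes(ped, config) if with_genotypes else None
    return SimulatedDataset(pedigree=ped, phenotypes=phen,
                            true_effects=effects, config=config,
                            genotypes=geno)
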