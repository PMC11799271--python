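"""End-to-end conveniences tying the modules into the standard analyses.

These helpers encode the default trait models: a birth-weight-like
single-record model (sex, parity, contemporary group, one covariate; direct
+ common-litter [+ maternal] + epigenetic random effects) and a
litter-size-like repeated-record model (parity, contemporary group,
covariate; direct + permanent environment + epigenetic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epirel import build_lambda_inverse_long
from .gibbs import GibbsConfig, PosteriorChain, run_gibbs
from .mme import assemble_mme, solve_mme
from .models import ModelSpec, VarianceComponents
from .pedigree import Pedigree, build_a_inverse
from .phenotypes import CGDefinition, DesignMatrices, build_contemporary_groups, build_design
from .simulate import SimulatedDataset


def single_record_spec(lam: float | None = None,
                       with_maternal: bool = False,
                       with_litter: bool = True) -> ModelSpec:
    random = ("u",)
    if with_maternal:
        random += ("m",)
    if with_litter:
        random += ("q",)
    if lam is not None:
        random += ("xi",)
    return ModelSpec(trait="single_record", fixed=("mu", "sex", "parity", "cg"),
                     covariates=("covariate",), random=random, lam=lam)


def repeated_record_spec(lam: float | None = None) -> ModelSpec:
    random = ("u", "pe") + (("xi",) if lam is not None else ())
    return ModelSpec(trait="repeated_record", fixed=("mu", "parity", "cg"),
                     covariates=("covariate",), random=random, lam=lam,
                     repeated=True)


def prepare_table(dataset: SimulatedDataset,
                  min_cg: int = 5) -> pd.DataFrame:
    """Contemporary-group coding on the simulated phenotype table."""
    return build_contemporary_groups(dataset.phenotypes,
                                     CGDefinition(min_size=min_cg))


def relationship_inverses(ped: Pedigree, lam: float | None) -> dict:
    inv = {"A": build_a_inverse(ped).to_csr()}
    if lam is not None:
        inv["lambda"] = build_lambda_inverse_long(ped, lam).to_csr()
    return inv


def moment_starts(spec: ModelSpec, y: np.ndarray) -> VarianceComponents:
    """Equal split of the phenotypic variance over the fitted components."""
    vary = float(np.var(y))
    n_parts = len(spec.random) + 1
    share = vary / n_parts
    kw = {"sigma2_e": share}
    names = {"u": "sigma2_u", "m": "sigma2_m", "q": "sigma2_q",
             "pe": "sigma2_pe", "xi": "sigma2_xi"}
    for term in spec.random:
        kw[names[term]] = share
    if spec.direct_maternal_cov:
        kw["cov_um"] = 0.0
    return VarianceComponents(**kw)


def fit_gibbs(dataset: SimulatedDataset, spec: ModelSpec,
              config: GibbsConfig,
              table: pd.DataFrame | None = None,
              inverses: dict | None = None) -> PosteriorChain:
    """Design → relationship inverses → Gibbs chain for one trait model."""
    table = prepare_table(dataset) if table is None else table
    design = build_design(table, spec, dataset.pedigree)
    if inverses is None:
        inverses = relationship_inverses(dataset.pedigree, spec.lam)
    starts = moment_starts(spec, design.y)
    return run_gibbs(spec, design, inverses, config, starts)


def solve_blup(table: pd.DataFrame, spec: ModelSpec, ped: Pedigree,
               vc: VarianceComponents,
               inverses: dict | None = None) -> tuple[np.ndarray, dict]:
    """BLUP/BLUE solutions at fixed variance components; returns (sol, blocks)."""
    design = build_design(table, spec, ped)
    if inverses is None:
        inverses = relationship_inverses(ped, spec.lam)
    system = assemble_mme(spec, design, inverses, vc)
    return solve_mme(system), system.blocks
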