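"""Gibbs sampling of variance components for single-trait animal models.

Location effects are drawn one equation at a time from their normal full
conditionals (single-site Gibbs over Henderson's equations, with the pass
compiled by numba); variances are drawn from scaled inverse chi-square full
conditionals under flat priors, the direct–maternal 2×2 block from an
inverse-Wishart, and the residual from the sum of squared residuals.  Each
stored sample carries the variance components, the derived ratios (so the
posterior SD of h² reflects per-sample ratios, not a ratio of means), and
the conditional deviance used for the DIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy import stats

from .models import ModelSpec, VarianceComponents, derive_ratios
from .mme import (effect_blocks, penalty_coefficients, penalty_components,
                  stack_design)
from .phenotypes import DesignMatrices


@dataclass
class GibbsConfig:
    """MCMC chain dimensions: total size, burn-in, thinning, seed."""

    size: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.size:
            raise ValueError("burn_in must be smaller than size")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def doubled(self) -> "GibbsConfig":
        return GibbsConfig(size=2 * self.size, burn_in=2 * self.burn_in,
                           thin=self.thin, seed=self.seed)


@njit(cache=True)
def _location_pass(indptr, indices, data, rhs, theta, sigma2_e, normals):
    """One single-site Gibbs sweep over all equations (in place)."""
    n = rhs.shape[0]
    for i in range(n):
        dii = 0.0
        adj = rhs[i]
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            v = data[k]
            if j == i:
                dii = v
            else:
                adj -= v * theta[j]
        mean = adj / dii
        theta[i] = mean + normals[i] * np.sqrt(sigma2_e / dii)


def _aligned_pattern(base: sp.csr_matrix, comps: list[sp.csr_matrix]):
    """Union CSR pattern plus each matrix's data mapped onto it."""
    pattern = abs(base.copy())
    for m in comps:
        pattern = pattern + abs(m)
    pattern = pattern.tocsr()
    pattern.sort_indices()
    n = pattern.shape[0]
    rownum = np.repeat(np.arange(n), np.diff(pattern.indptr))
    keys = rownum * n + pattern.indices

    def map_onto(m: sp.csr_matrix) -> np.ndarray:
        coo = m.tocoo()
        coo.sum_duplicates()
        k = coo.row.astype(np.int64) * n + coo.col
        pos = np.searchsorted(keys, k)
        out = np.zeros(pattern.nnz)
        out[pos] = coo.data
        return out

    return pattern, map_onto


@dataclass
class PosteriorChain:
    """Stored post-burn-in samples plus what the DIC needs."""

    samples: pd.DataFrame
    deviance: np.ndarray
    theta_mean: np.ndarray
    blocks: dict[str, slice]
    spec: ModelSpec
    config: GibbsConfig
    _y: np.ndarray = field(repr=False, default=None)
    _w: sp.csr_matrix = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def solutions(self, term: str) -> np.ndarray:
        """Posterior-mean solutions (EBV for 'u') of one effect block."""
        return self.theta_mean[self.blocks[term]]

    def posterior_mean_vc(self) -> VarianceComponents:
        m = self.samples.mean()
        kw = {}
        for name in ("sigma2_u", "sigma2_m", "cov_um", "sigma2_q",
                     "sigma2_pe", "sigma2_xi", "sigma2_e"):
            if name in m.index:
                kw[name] = float(m[name])
        return VarianceComponents(**kw)

    def write_csv(self, path) -> None:
        df = self.samples.copy()
        df["deviance"] = self.deviance
        df.to_csv(path, index=False)


def _sample_variances(rng, spec: ModelSpec, theta, blocks, kinv,
                      n_levels) -> dict[str, float]:
    """Draw non-residual variances from their full conditionals (flat priors)."""
    kw: dict[str, float] = {}
    if spec.direct_maternal_cov:
        u = theta[blocks["u"]]
        m = theta[blocks["m"]]
        a_inv = kinv["genetic"]
        s = np.array([[u @ (a_inv @ u), u @ (a_inv @ m)],
                      [0.0, m @ (a_inv @ m)]])
        s[1, 0] = s[0, 1]
        df = n_levels["u"] - 3
        g0 = stats.invwishart.rvs(df=df, scale=s, random_state=rng)
        kw["sigma2_u"] = g0[0, 0]
        kw["sigma2_m"] = g0[1, 1]
        kw["cov_um"] = g0[0, 1]
    for term in spec.random:
        if spec.direct_maternal_cov and term in ("u", "m"):
            continue
        a = theta[blocks[term]]
        if term in ("u", "m"):
            q = a @ (kinv["genetic"] @ a)
        elif term == "xi":
            q = a @ (kinv["lambda"] @ a)
        else:
            q = a @ a
        name = {"u": "sigma2_u", "m": "sigma2_m", "q": "sigma2_q",
                "pe": "sigma2_pe", "xi": "sigma2_xi"}[term]
        kw[name] = q / rng.chisquare(n_levels[term] - 2)
    return kw


def run_gibbs(spec: ModelSpec, design: DesignMatrices, inverses: dict,
              config: GibbsConfig, starts: VarianceComponents
              ) -> PosteriorChain:
    """Sample variance components; returns the thinned post-burn-in chain.

    ``inverses`` maps "A" or "H" (matching ``spec.relationship``) and
    "lambda" (when ξ is fitted) to sparse relationship inverses.  ``starts``
    must provide a positive variance for every fitted term.
    """
    rng = np.random.default_rng(config.seed)
    w = stack_design(spec, design)
    y = design.y
    n_rec = len(y)
    ww = (w.T @ w).tocsr()
    rhs = np.asarray(w.T @ y).ravel()
    blocks = effect_blocks(spec, design)
    comps = penalty_components(spec, design, inverses)
    pattern, map_onto = _aligned_pattern(ww, [m for _, m in comps])
    data_ww = map_onto(ww)
    tags = [tag for tag, _ in comps]
    data_tags = [map_onto(m) for _, m in comps]

    from .mme import _as_csr
    kinv = {}
    if {"u", "m"} & set(spec.random):
        kinv["genetic"] = _as_csr(inverses[spec.relationship])
    if "xi" in spec.random:
        kinv["lambda"] = _as_csr(inverses["lambda"])
    n_levels = {t: design.z[t].shape[1] for t in spec.random}

    vc = starts
    theta = np.zeros(len(rhs))
    theta_sum = np.zeros_like(theta)
    records: list[dict] = []
    deviances: list[float] = []
    log2pi = np.log(2.0 * np.pi)

    for it in range(config.size):
        coefs = penalty_coefficients(spec, vc)
        data = data_ww.copy()
        for tag, dat in zip(tags, data_tags):
            data += coefs[tag] * dat
        _location_pass(pattern.indptr, pattern.indices, data, rhs, theta,
                       vc.sigma2_e, rng.standard_normal(len(rhs)))

        e = y - w @ theta
        sse = float(e @ e)
        sigma2_e = sse / rng.chisquare(n_rec - 2)
        kw = _sample_variances(rng, spec, theta, blocks, kinv, n_levels)
        vc = VarianceComponents(sigma2_e=sigma2_e, **kw)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            row = vc.as_dict()
            row.update(derive_ratios(vc))
            records.append(row)
            deviances.append(n_rec * (log2pi + np.log(sigma2_e))
                             + sse / sigma2_e)
            theta_sum += theta

    samples = pd.DataFrame.from_records(records)
    n_stored = len(records)
    return PosteriorChain(
        samples=samples,
        deviance=np.asarray(deviances),
        theta_mean=theta_sum / max(n_stored, 1),
        blocks=blocks,
        spec=spec,
        config=config,
        _y=y,
        _w=w,
    )


def compute_dic(chain: PosteriorChain) -> float:
    """DIC from the conditional (location-parameter) deviance.

    DIC = 2·mean(D) − D(posterior means); D(θ) = −2 Σ log N(yᵢ | ŷᵢ(θ), σ²e).
    Lower values indicate better fit.
    """
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    d_bar = float(chain.deviance.mean())
    sigma2_e = float(chain.samples["sigma2_e"].mean())
    e = chain._y - chain._w @ chain.theta_mean
    d_at_mean = (len(chain._y) * (np.log(2.0 * np.pi) + np.log(sigma2_e))
                 + float(e @ e) / sigma2_e)
    return 2.0 * d_bar - d_at_mean


def spectrum0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Geyer's initial positive
    sequence of autocovariances (monotone truncation)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    s = acov[0]
    k = 1
    while k + 1 < n:
        gamma = acov[k] + acov[k + 1]
        if gamma <= 0:
            break
        s += 2.0 * gamma
        k += 2
    return float(max(s, 1e-300))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: early vs late chain means with spectral SEs."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[n - max(int(last * n), 2):]
    var = spectrum0(a) / len(a) + spectrum0(b) / len(b)
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


def hpd_interval(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    import arviz as az

    lo, hi = az.hdi(np.asarray(x, dtype=float), hdi_prob=mass)
    return float(lo), float(hi)


@dataclass
class PosteriorSummary:
    """Posterior table plus cross-parameter sample correlations."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    significant: pd.DataFrame  # 5% two-sided mask on the correlations
    converged: bool


def summarize_chain(chain: PosteriorChain, hpd_mass: float = 0.95,
                    geweke_windows: tuple[float, float] = (0.1, 0.5)
                    ) -> PosteriorSummary:
    """Means, SDs, shortest-interval HPDs and Geweke z per parameter."""
    if chain.n_samples < 100:
        raise ValueError("need at least 100 stored samples to summarize")
    rows = {}
    for col in chain.samples.columns:
        x = chain.samples[col].to_numpy()
        if np.ptp(x) == 0:
            lo = hi = float(x[0])
            z = 0.0
        else:
            lo, hi = hpd_interval(x, hpd_mass)
            z = geweke_z(x, *geweke_windows)
        rows[col] = {"mean": x.mean(), "sd": x.std(ddof=1),
                     "hpd_low": lo, "hpd_high": hi, "geweke_z": z}
    table = pd.DataFrame(rows).T

    corr = chain.samples.corr()
    n = chain.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        t = corr * np.sqrt((n - 2) / np.maximum(1 - corr ** 2, 1e-300))
    pvals = 2 * stats.t.sf(np.abs(t), df=n - 2)
    signif = pd.DataFrame(pvals < 0.05, index=corr.index, columns=corr.columns)
    converged = bool((table["geweke_z"].abs() < 1.96).all())
    return PosteriorSummary(table=table, correlations=corr,
                            significant=signif, converged=converged)


def run_gibbs_until_converged(spec, design, inverses, config, starts,
                              max_doublings: int = 2):
    """Run the sampler, doubling size and burn-in while any |Geweke z| ≥ 1.96."""
    chain = run_gibbs(spec, design, inverses, config, starts)
    for _ in range(max_doublings):
        if summarize_chain(chain).converged:
            break
        config = config.doubled()
        chain = run_gibbs(spec, design, inverses, config, starts)
    return chain
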