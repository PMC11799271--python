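"""Henderson's mixed-model equations: assembly and solution.

The single-trait equations are

    [W'W + Σ_k K_k⁻¹ (σ²e / σ²_k)] θ = W'y,   W = [X | Z_1 | ... | Z_K],

with K⁻¹ the relationship inverse of each random term (A⁻¹ or H⁻¹ for the
genetic terms, Λ⁻¹ for the epigenetic term, identity for litter and
permanent-environment terms).  A correlated direct–maternal pair contributes
σ²e · G0⁻¹ ⊗ A⁻¹ with G0 the 2×2 (co)variance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .models import ModelSpec, VarianceComponents
from .phenotypes import DesignMatrices
from .sparsesym import SparseSymTriplets


def _as_csr(k) -> sp.csr_matrix:
    if isinstance(k, SparseSymTriplets):
        return k.to_csr()
    return sp.csr_matrix(k)


@dataclass
class MMESystem:
    """Assembled equations with an effect → equation-range map."""

    lhs: sp.csr_matrix
    rhs: np.ndarray
    blocks: dict[str, slice]

    @property
    def n_equations(self) -> int:
        return len(self.rhs)


def effect_blocks(spec: ModelSpec, design: DesignMatrices) -> dict[str, slice]:
    """Equation ranges: fixed effects first, then random terms in spec order."""
    blocks = {"fixed": slice(0, design.x.shape[1])}
    pos = design.x.shape[1]
    for term in spec.random:
        width = design.z[term].shape[1]
        blocks[term] = slice(pos, pos + width)
        pos += width
    return blocks


def stack_design(spec: ModelSpec, design: DesignMatrices) -> sp.csr_matrix:
    return sp.hstack([design.x] + [design.z[t] for t in spec.random],
                     format="csr")


def _require(inverses: dict, key: str, term: str) -> sp.csr_matrix:
    if key not in inverses:
        raise ValueError(f"missing relationship inverse '{key}' for term "
                         f"'{term}'")
    return _as_csr(inverses[key])


def penalty_components(spec: ModelSpec, design: DesignMatrices,
                       inverses: dict) -> list[tuple[tuple[str, ...], sp.csr_matrix]]:
    """K⁻¹ contributions placed at their equation offsets.

    Returns (tag, matrix) pairs where the matrix is n_eq × n_eq and the tag
    names the variance parameter(s) that scale it: ("u",), ("m",), ("u", "m")
    for the covariance cross-block, ("q",), ("pe",), ("xi",).
    """
    blocks = effect_blocks(spec, design)
    n_eq = design.x.shape[1] + sum(design.z[t].shape[1] for t in spec.random)

    def placed(k: sp.spmatrix, rblk: slice, cblk: slice,
               symmetrize: bool = False) -> sp.csr_matrix:
        coo = sp.coo_matrix(k)
        rows = coo.row + rblk.start
        cols = coo.col + cblk.start
        data = coo.data
        if symmetrize:
            rows, cols = np.concatenate([rows, cols]), np.concatenate([cols, rows])
            data = np.concatenate([data, data])
        return sp.csr_matrix((data, (rows, cols)), shape=(n_eq, n_eq))

    out = []
    genetic_key = spec.relationship  # "A" or "H"
    for term in spec.random:
        if term in ("u", "m"):
            k = _require(inverses, genetic_key, term)
        elif term == "xi":
            k = _require(inverses, "lambda", term)
        else:
            k = sp.identity(design.z[term].shape[1], format="csr")
        out.append(((term,), placed(k, blocks[term], blocks[term])))
    if spec.direct_maternal_cov:
        k = _require(inverses, genetic_key, "u,m")
        out.append((("u", "m"),
                    placed(k, blocks["u"], blocks["m"], symmetrize=True)))
    return out


def penalty_coefficients(spec: ModelSpec,
                         vc: VarianceComponents) -> dict[tuple[str, ...], float]:
    """Multipliers σ²e·(G⁻¹ elements) for each penalty component."""
    coefs: dict[tuple[str, ...], float] = {}
    if spec.direct_maternal_cov:
        g0 = np.array([[vc.sigma2_u, vc.cov_um], [vc.cov_um, vc.sigma2_m]])
        g0i = np.linalg.inv(g0)
        coefs[("u",)] = vc.sigma2_e * g0i[0, 0]
        coefs[("m",)] = vc.sigma2_e * g0i[1, 1]
        coefs[("u", "m")] = vc.sigma2_e * g0i[0, 1]
    for term in spec.random:
        if spec.direct_maternal_cov and term in ("u", "m"):
            continue
        var = vc.get(term)
        if var is None or var <= 0:
            raise ValueError(f"variance for '{term}' must be positive")
        coefs[(term,)] = vc.sigma2_e / var
    return coefs


def assemble_mme(spec: ModelSpec, design: DesignMatrices, inverses: dict,
                 vc: VarianceComponents) -> MMESystem:
    """Assemble the mixed-model equations for given variance components."""
    w = stack_design(spec, design)
    lhs = (w.T @ w).tocsr()
    coefs = penalty_coefficients(spec, vc)
    for tag, mat in penalty_components(spec, design, inverses):
        lhs = lhs + coefs[tag] * mat
    rhs = np.asarray(w.T @ design.y).ravel()
    return MMESystem(lhs=lhs.tocsr(), rhs=rhs,
                     blocks=effect_blocks(spec, design))


def solve_mme(system: MMESystem, rtol: float = 1e-8) -> np.ndarray:
    """Solve the equations by sparse LU, falling back to least-norm LSMR.

    A rank-deficient fixed block (e.g. confounded class effects) yields the
    minimum-norm solution from LSMR.
    """
    lhs, rhs = system.lhs.tocsc(), system.rhs
    norm = np.linalg.norm(rhs)
    if norm == 0:
        return np.zeros_like(rhs)
    try:
        sol = spla.spsolve(lhs, rhs)
        if np.all(np.isfinite(sol)):
            resid = np.linalg.norm(lhs @ sol - rhs) / norm
            if resid <= max(rtol, 1e-10) * 1e2:
                return sol
    except Exception:
        pass
    sol = spla.lsmr(lhs, rhs, atol=rtol, btol=rtol, conlim=1e14,
                    maxiter=10 * lhs.shape[0])[0]
    resid = np.linalg.norm(lhs @ sol - rhs) / norm
    if resid > 1e-5:
        raise RuntimeError(f"MME solution did not converge: relative "
                           f"residual {resid:.2e}")
    return sol
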