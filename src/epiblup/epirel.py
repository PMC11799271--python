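"""Epigenetic relationship matrix Λ, its sparse inverse, and λ↔ν conversion.

Transgenerational epigenetic effects are modelled at the individual level by
the recursion

    ξ_i = λ(ξ_sire + ξ_dam) + ε_i,      Var(ε_i) = d_i σ²ξ,

where λ = 0.5(1 − ν) and ν is the reset coefficient: the probability that an
epigenetic mark is erased between generations.  The transmitted fraction per
generation is 2λ = 1 − ν.  The residual scaling d_i is 1 − 2λ² when both
parents are known, 1 − λ² with one known parent, and 1 for founders, so that
Λ_ii = 1 whenever the parents are epigenetically unrelated.

Λ factorizes as (I − P)⁻¹ D (I − P)⁻ᵀ with P the λ-weighted parent incidence
and D = diag(d_i); hence Λ⁻¹ = (I − P)ᵀ D⁻¹ (I − P) has the same sparse
structure as the pedigree inverse A⁻¹, with λ in place of 0.5.  d_i is used
unchanged even when mates are epigenetically related, which keeps the sparse
inverse exact against the same generative recursion (Λ_ii may then slightly
exceed 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree
from .sparsesym import SparseSymTriplets


def reset_to_lambda(nu: float) -> float:
    """λ = 0.5(1 − ν) for reset coefficient ν ∈ [0, 1]."""
    if not 0.0 <= nu <= 1.0:
        raise ValueError(f"reset coefficient must be in [0, 1], got {nu}")
    return 0.5 * (1.0 - nu)


def lambda_to_reset(lam: float) -> float:
    """ν = 1 − 2λ for recursive parameter λ ∈ [0, 0.5]."""
    if not 0.0 <= lam <= 0.5:
        raise ValueError(f"lambda must be in [0, 0.5], got {lam}")
    return 1.0 - 2.0 * lam


def lambda_grid(start: float = 0.05, stop: float = 0.45,
                step: float = 0.05) -> np.ndarray:
    """Inclusive arithmetic λ grid; the default spans nine candidate models."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not (0.0 <= start <= stop < 0.5):
        raise ValueError("grid must satisfy 0 <= start <= stop < 0.5")
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    return grid[grid <= stop + 1e-12]


@dataclass
class EpiParams:
    """λ and ν kept consistent (λ = 0.5(1−ν)), plus the model-search grid."""

    lam: float
    grid: np.ndarray = field(default_factory=lambda_grid)

    def __post_init__(self):
        if not 0.0 <= self.lam <= 0.5:
            raise ValueError("lambda must be in [0, 0.5]")
        g = np.asarray(self.grid, dtype=float)
        if g.size and (np.any(np.diff(g) <= 0) or g[0] < 0 or g[-1] >= 0.5):
            raise ValueError("grid must be strictly increasing within [0, 0.5)")
        self.grid = g

    @property
    def reset(self) -> float:
        return lambda_to_reset(self.lam)

    @classmethod
    def from_reset(cls, nu: float, **kw) -> "EpiParams":
        return cls(lam=reset_to_lambda(nu), **kw)


def _mendelian_d(sire: int, dam: int, lam: float) -> float:
    if sire and dam:
        return 1.0 - 2.0 * lam * lam
    if sire or dam:
        return 1.0 - lam * lam
    return 1.0


def build_lambda_dense(ped: Pedigree, lam: float) -> np.ndarray:
    """Dense Λ by the generative tabular recursion (reference construction)."""
    if not 0.0 <= lam <= 0.5:
        raise ValueError("lambda must be in [0, 0.5]")
    n = ped.n
    L = np.zeros((n + 1, n + 1))  # index 0 = unknown parent
    for i in range(1, n + 1):
        s, d = ped.parents(i)
        L[i, 1:i] = lam * (L[s, 1:i] + L[d, 1:i])
        L[1:i, i] = L[i, 1:i]
        L[i, i] = (lam * lam * (L[s, s] + L[d, d] + 2.0 * L[s, d])
                   + _mendelian_d(s, d, lam))
    return L[1:, 1:]


def build_lambda_inverse_long(ped: Pedigree, lam: float) -> SparseSymTriplets:
    """Sparse Λ⁻¹ in long (triplet) format, built animal by animal.

    Per animal i with known-parent set K: add 1/d_i to (i,i), −λ/d_i to
    (i, p) for p ∈ K, and λ²/d_i to every pair over K including squares.
    Duplicate coordinates are summed.
    """
    if not 0.0 <= lam <= 0.5:
        raise ValueError("lambda must be in [0, 0.5]")
    out = SparseSymTriplets(n=ped.n)
    for i in range(1, ped.n + 1):
        s, d = ped.parents(i)
        w = 1.0 / _mendelian_d(s, d, lam)
        out.add(i, i, w)
        known = [p for p in (s, d) if p]
        for p in known:
            out.add(i, p, -lam * w)
        for a in known:
            for b in known:
                if a >= b:
                    out.add(a, b, lam * lam * w)
    return out.accumulate()
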