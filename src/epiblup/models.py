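"""Model specifications and variance-component containers.

A trait model is a fixed part (class effects + covariates) plus a subset of
the random terms used in pig genetic evaluation:

    u   direct additive genetic        (A- or H-structured)
    m   maternal additive genetic      (A- or H-structured, optional cov with u)
    q   common litter environment      (identity)
    pe  permanent environment          (identity; repeated records only)
    xi  transgenerational epigenetic   (Λ(λ)-structured)

Phenotypic variance is the sum of all fitted components (the direct–maternal
covariance counted once), and every ratio is that component over σ²P.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

RANDOM_TERMS = ("u", "m", "q", "pe", "xi")


@dataclass
class VarianceComponents:
    """(Co)variance components; ``None`` marks a term absent from the model."""

    sigma2_u: float | None = None
    sigma2_m: float | None = None
    cov_um: float | None = None
    sigma2_q: float | None = None
    sigma2_pe: float | None = None
    sigma2_xi: float | None = None
    sigma2_e: float = 1.0

    _FIELD_BY_TERM = {"u": "sigma2_u", "m": "sigma2_m", "q": "sigma2_q",
                      "pe": "sigma2_pe", "xi": "sigma2_xi"}

    def __post_init__(self):
        for name in ("sigma2_u", "sigma2_m", "sigma2_q", "sigma2_pe",
                     "sigma2_xi", "sigma2_e"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.cov_um is not None:
            if self.sigma2_u is None or self.sigma2_m is None:
                raise ValueError("cov_um requires both sigma2_u and sigma2_m")
            bound = np.sqrt(self.sigma2_u * self.sigma2_m)
            if abs(self.cov_um) > bound + 1e-12:
                raise ValueError("|cov_um| exceeds sqrt(sigma2_u * sigma2_m)")

    def get(self, term: str) -> float | None:
        return getattr(self, self._FIELD_BY_TERM[term])

    def replace(self, **kw) -> "VarianceComponents":
        return replace(self, **kw)

    @property
    def total(self) -> float:
        """Phenotypic variance σ²P: sum of all components, cov_um once."""
        parts = [self.sigma2_u, self.sigma2_m, self.cov_um, self.sigma2_q,
                 self.sigma2_pe, self.sigma2_xi, self.sigma2_e]
        return float(sum(p for p in parts if p is not None))

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def derive_ratios(vc: VarianceComponents) -> dict[str, float]:
    """Heritabilities and variance ratios on the σ²P scale.

    Returns sigma2_p plus h2_u, h2_m, r_um, q2, pe2 and h2_xi for whichever
    components are present.
    """
    sp = vc.total
    if sp <= 0:
        raise ValueError("phenotypic variance must be positive")
    out = {"sigma2_p": sp}
    if vc.sigma2_u is not None:
        out["h2_u"] = vc.sigma2_u / sp
    if vc.sigma2_m is not None:
        out["h2_m"] = vc.sigma2_m / sp
    if vc.cov_um is not None:
        denom = np.sqrt(vc.sigma2_u * vc.sigma2_m)
        out["r_um"] = vc.cov_um / denom if denom > 0 else 0.0
    if vc.sigma2_q is not None:
        out["q2"] = vc.sigma2_q / sp
    if vc.sigma2_pe is not None:
        out["pe2"] = vc.sigma2_pe / sp
    if vc.sigma2_xi is not None:
        out["h2_xi"] = vc.sigma2_xi / sp
    return out


@dataclass
class ModelSpec:
    """Fixed and random structure of a single-trait animal model."""

    trait: str
    fixed: tuple[str, ...] = ("mu",)
    covariates: tuple[str, ...] = ()
    quadratic_covariates: tuple[str, ...] = ()
    random: tuple[str, ...] = ("u",)
    direct_maternal_cov: bool = False
    relationship: str = "A"          # "A" or "H" for u (and m)
    lam: float | None = None         # λ of the Λ structure when xi is fitted
    repeated: bool = False

    def __post_init__(self):
        unknown = set(self.random) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms {sorted(unknown)}")
        if "pe" in self.random and not self.repeated:
            raise ValueError("pe requires a repeated-record trait")
        if self.direct_maternal_cov and not {"u", "m"} <= set(self.random):
            raise ValueError("direct-maternal covariance needs both u and m")
        if "xi" in self.random:
            if self.lam is None or not 0.0 < self.lam <= 0.5:
                raise ValueError("xi requires lambda in (0, 0.5]")
        if self.relationship not in ("A", "H"):
            raise ValueError("relationship must be 'A' or 'H'")

    def with_lambda(self, lam: float) -> "ModelSpec":
        rnd = self.random if "xi" in self.random else self.random + ("xi",)
        return replace(self, random=rnd, lam=lam)

    def without_xi(self) -> "ModelSpec":
        rnd = tuple(t for t in self.random if t != "xi")
        return replace(self, random=rnd, lam=None)
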