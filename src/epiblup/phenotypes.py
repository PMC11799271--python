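"""Phenotype QC, contemporary groups, and design-matrix assembly.

Phenotype records live in a pandas DataFrame with one row per record:
``animal`` (renumbered pedigree id), ``value`` (the trait), class-effect
columns (``sex``, ``parity``, ``farm``, ``year``, ``month``, ...), covariate
columns, and for maternal / litter models ``dam`` and ``litter`` (plus
``litter_size`` for reproductive records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .models import ModelSpec
from .pedigree import Pedigree, completeness_index


@dataclass
class CGDefinition:
    """Contemporary-group keys (concatenated) and the minimum level size."""

    keys: tuple[str, ...] = ("year", "month", "farm")
    min_size: int = 5

    def __post_init__(self):
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class PhenotypeQCReport:
    rows_in: int
    outlier: int = 0
    parity: int = 0
    litter_size: int = 0
    not_in_pedigree: int = 0
    completeness: int = 0

    @property
    def rows_out(self) -> int:
        return self.rows_in - (self.outlier + self.parity + self.litter_size
                               + self.not_in_pedigree + self.completeness)

    def as_dict(self) -> dict[str, int]:
        d = dict(self.__dict__)
        d["rows_out"] = self.rows_out
        return d


def apply_phenotype_qc(table: pd.DataFrame, ped: Pedigree,
                       sd_k: float = 3.5, max_parity: int = 6,
                       litter_bounds: tuple[int, int] = (3, 20),
                       depth: int = 4, min_completeness: float = 0.25
                       ) -> tuple[pd.DataFrame, PhenotypeQCReport]:
    """Record-level quality control mirroring routine pig-evaluation edits.

    Removes, in order (each record charged to the first rule it fails):
    trait values outside mean ± sd_k·SD (closed interval: a value exactly on
    the boundary is kept; mean and SD computed once, before filtering),
    parities above ``max_parity``, reproductive records with litter size
    outside ``litter_bounds``, animals absent from the pedigree, and animals
    whose pedigree-completeness index at ``depth`` falls below
    ``min_completeness`` (the 0.25 default corresponds to both parents
    known at depth 4).
    """
    if table.empty:
        raise ValueError("empty phenotype table")
    rep = PhenotypeQCReport(rows_in=len(table))
    t = table.reset_index(drop=True)
    fail = np.zeros(len(t), dtype=bool)

    mu, sd = t["value"].mean(), t["value"].std()
    out = (t["value"] - mu).abs() > sd_k * sd + 1e-12
    rep.outlier = int(out.sum())
    fail |= out.to_numpy()

    if "parity" in t.columns:
        bad = (~fail) & (t["parity"].to_numpy() > max_parity)
        rep.parity = int(bad.sum())
        fail |= bad

    if "litter_size" in t.columns:
        ls = t["litter_size"].to_numpy(dtype=float)
        bad = (~fail) & ~np.isnan(ls) & ((ls < litter_bounds[0])
                                         | (ls > litter_bounds[1]))
        rep.litter_size = int(bad.sum())
        fail |= bad

    in_ped = np.isin(t["animal"].to_numpy(), ped.ids)
    bad = (~fail) & ~in_ped
    rep.not_in_pedigree = int(bad.sum())
    fail |= bad

    comp = np.zeros(ped.n + 1)
    comp[1:] = completeness_index(ped, depth)
    anim = t["animal"].to_numpy()
    safe = np.where(in_ped, anim, 0)
    bad = (~fail) & (comp[safe] < min_completeness)
    rep.completeness = int(bad.sum())
    fail |= bad

    kept = t.loc[~fail].reset_index(drop=True)
    if kept.empty:
        raise ValueError("all records removed by phenotype QC")
    return kept, rep


def build_contemporary_groups(table: pd.DataFrame,
                              cg: CGDefinition | None = None,
                              also_enforce: tuple[str, ...] = ()
                              ) -> pd.DataFrame:
    """Attach a CG code column and drop records in undersized levels.

    The CG code concatenates the key fields.  Levels of the CG (and of any
    column in ``also_enforce``) with fewer than ``min_size`` records are
    removed rather than merged.
    """
    cg = cg or CGDefinition()
    t = table.copy()
    missing = [k for k in cg.keys if k not in t.columns]
    if missing:
        raise ValueError(f"missing CG key columns {missing}")
    t["cg"] = t[list(cg.keys)].astype(str).agg("-".join, axis=1)
    for col in ("cg", *also_enforce):
        sizes = t.groupby(col)[col].transform("size")
        t = t.loc[sizes >= cg.min_size]
    if t.empty:
        raise ValueError("no contemporary group reaches the minimum size")
    return t.reset_index(drop=True)


@dataclass
class DesignMatrices:
    """Assembled incidence matrices for one trait model."""

    y: np.ndarray
    x: sp.csr_matrix
    z: dict[str, sp.csr_matrix]
    fixed_columns: list[str]
    levels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.y)


def build_design(table: pd.DataFrame, spec: ModelSpec,
                 ped: Pedigree) -> DesignMatrices:
    """Build X and the Z incidence matrices for ``spec``.

    Class effects are dummy-coded with the first level dropped (the
    intercept absorbs the reference level).  Z for u, m and ξ spans the full
    pedigree so ancestors without records still receive equations; q maps to
    litter levels and pe to the distinct recorded animals.
    """
    n = len(table)
    y = table["value"].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(n)]
    names = ["mu"]
    for term in spec.fixed:
        if term == "mu":
            continue
        if term not in table.columns:
            raise ValueError(f"fixed effect column '{term}' not in table")
        d = pd.get_dummies(table[term].astype(str), prefix=term,
                           drop_first=True, dtype=float)
        cols.extend(d[c].to_numpy() for c in d.columns)
        names.extend(d.columns)
    for cov in spec.covariates:
        cols.append(table[cov].to_numpy(dtype=float))
        names.append(cov)
    for cov in spec.quadratic_covariates:
        cols.append(table[cov].to_numpy(dtype=float) ** 2)
        names.append(f"{cov}^2")
    x = sp.csr_matrix(np.column_stack(cols))

    rows = np.arange(n)
    ones = np.ones(n)
    anim = table["animal"].to_numpy(dtype=np.int64)
    z: dict[str, sp.csr_matrix] = {}
    levels: dict[str, np.ndarray] = {}

    def incidence(codes: np.ndarray, width: int) -> sp.csr_matrix:
        mask = codes >= 0
        return sp.csr_matrix(
            (ones[mask], (rows[mask], codes[mask])), shape=(n, width))

    for term in spec.random:
        if term in ("u", "xi"):
            z[term] = incidence(anim - 1, ped.n)
        elif term == "m":
            if "dam" not in table.columns:
                raise ValueError("maternal model requires a 'dam' column")
            dams = table["dam"].to_numpy(dtype=np.int64)
            if np.any(dams <= 0):
                raise ValueError("maternal model: records with unknown dam")
            z[term] = incidence(dams - 1, ped.n)
        elif term == "q":
            if "litter" not in table.columns:
                raise ValueError("litter model requires a 'litter' column")
            lit = table["litter"].to_numpy()
            if pd.isna(lit).any():
                raise ValueError("litter model: records with missing litter")
            uniq, codes = np.unique(lit, return_inverse=True)
            levels["q"] = uniq
            z[term] = incidence(codes, len(uniq))
        elif term == "pe":
            uniq, codes = np.unique(anim, return_inverse=True)
            levels["pe"] = uniq
            z[term] = incidence(codes, len(uniq))
    return DesignMatrices(y=y, x=x, z=z, fixed_columns=names, levels=levels)
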