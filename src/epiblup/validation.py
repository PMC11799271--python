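"""LR-method validation of breeding values and model solution comparison.

The Linear Regression (LR) method compares EBVs of focal animals (young
selection candidates) predicted from the whole dataset against those from a
partial dataset in which the focal phenotypes are masked:

    accuracy   = sqrt( cov(EBV_w, EBV_p) / ((1 − F̄) σ̂²u) )
    bias       = mean(EBV_p) − mean(EBV_w)           (trait units)
    dispersion = cov(EBV_w, EBV_p) / var(EBV_p) − 1  (0 = no inflation)

F̄ is the mean inbreeding of the focal animals and σ̂²u the additive variance
from the whole-data fit.  The square-root convention makes the accuracy an
estimate of the correlation between the partial EBV and the true breeding
value; the squared variant is obtained by squaring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LRResult:
    accuracy: float
    bias: float
    dispersion: float
    focal_ids: np.ndarray
    mean_inbreeding: float
    sigma2_u: float


@dataclass
class SolutionComparison:
    pearson_r: float
    t_statistic: float
    p_value: float
    mean_difference: float


def make_partial_dataset(phenotypes: pd.DataFrame, focal) -> pd.DataFrame:
    """Remove the phenotype records of the focal animals.

    Pedigree, genotypes and all non-focal records are untouched; EBVs of the
    focal animals in the partial run come only from relatives' records.
    """
    focal = set(int(a) for a in focal)
    if not focal:
        raise ValueError("focal set is empty")
    mask = phenotypes["animal"].isin(focal)
    return phenotypes.loc[~mask].reset_index(drop=True)


def youngest_phenotyped_cohort(phenotypes: pd.DataFrame,
                               generation: np.ndarray) -> np.ndarray:
    """Focal-animal default: the last generation carrying phenotypes."""
    anim = phenotypes["animal"].to_numpy(dtype=np.int64)
    gen = generation[anim - 1]
    return np.unique(anim[gen == gen.max()])


def lr_metrics(ebv_whole: np.ndarray, ebv_partial: np.ndarray,
               mean_inbreeding: float, sigma2_u: float,
               focal_ids=None) -> LRResult:
    """Accuracy, bias and dispersion of focal-animal EBVs.

    Vectors must be aligned on the focal animals.  A negative whole/partial
    covariance yields accuracy 0 with a warning.
    """
    w = np.asarray(ebv_whole, dtype=float)
    p = np.asarray(ebv_partial, dtype=float)
    if w.shape != p.shape or w.ndim != 1:
        raise ValueError("EBV vectors must be 1-D and aligned")
    if sigma2_u <= 0:
        raise ValueError("sigma2_u must be positive")
    if not 0.0 <= mean_inbreeding < 1.0:
        raise ValueError("mean inbreeding must be in [0, 1)")
    var_p = p.var(ddof=1)
    if var_p == 0:
        raise ValueError("partial EBVs have zero variance: dispersion "
                         "undefined")
    cov = np.cov(w, p, ddof=1)[0, 1]
    if cov < 0:
        warnings.warn("negative whole/partial EBV covariance; accuracy "
                      "reported as 0", stacklevel=2)
        acc = 0.0
    else:
        acc = float(np.sqrt(cov / ((1.0 - mean_inbreeding) * sigma2_u)))
    return LRResult(
        accuracy=acc,
        bias=float(p.mean() - w.mean()),
        dispersion=float(cov / var_p - 1.0),
        focal_ids=(np.asarray(focal_ids) if focal_ids is not None
                   else np.arange(len(w))),
        mean_inbreeding=float(mean_inbreeding),
        sigma2_u=float(sigma2_u),
    )


def compare_solutions(sol_a: np.ndarray, sol_b: np.ndarray
                      ) -> SolutionComparison:
    """Pearson correlation and paired t-test between two solution vectors."""
    a = np.asarray(sol_a, dtype=float)
    b = np.asarray(sol_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("solution vectors must align with length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance solutions: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    if np.allclose(a - b, (a - b)[0]):
        # constant shift: the paired t-test degenerates (zero variance of
        # differences); report an exact result
        d = float((b - a).mean())
        t = np.inf if d != 0 else 0.0
        pv = 0.0 if d != 0 else 1.0
    else:
        t_res = stats.ttest_rel(b, a)
        t, pv = float(t_res.statistic), float(t_res.pvalue)
        d = float((b - a).mean())
    return SolutionComparison(pearson_r=r, t_statistic=t, p_value=pv,
                              mean_difference=d)
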