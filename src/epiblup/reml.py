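"""AI-REML variance-component estimation and AIC model ranking.

Maximizes the restricted likelihood of y = Xb + Σ Z_k a_k + e by Newton
steps on the average-information matrix, with step halving into the
parameter space and an EM-REML fallback when the AI step is unusable.
Intended for the model-building stage (choosing the random-effect set by
AIC) and for generating starting values; works on the dense phenotypic
covariance V = Σ σ²_k Z_k K_k Z_k' + σ²e I, so it targets data sizes where
n_records is a few thousand at most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ModelSpec, VarianceComponents
from .phenotypes import DesignMatrices


@dataclass
class REMLResult:
    vc: VarianceComponents
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    message: str = ""


def _v_components(spec: ModelSpec, design: DesignMatrices,
                  structures: dict) -> tuple[list[str], list[np.ndarray]]:
    """Dense V_k = Z K Z' per parameter, plus the residual identity last."""
    names: list[str] = []
    mats: list[np.ndarray] = []
    for term in spec.random:
        z = design.z[term].toarray()
        if term in ("u", "m"):
            k = structures[spec.relationship]
            v = z @ k @ z.T
        elif term == "xi":
            v = z @ structures["lambda"] @ z.T
        else:
            v = z @ z.T
        names.append({"u": "sigma2_u", "m": "sigma2_m", "q": "sigma2_q",
                      "pe": "sigma2_pe", "xi": "sigma2_xi"}[term])
        mats.append(v)
    if spec.direct_maternal_cov:
        zu = design.z["u"].toarray()
        zm = design.z["m"].toarray()
        k = structures[spec.relationship]
        cross = zu @ k @ zm.T
        names.append("cov_um")
        mats.append(cross + cross.T)
    names.append("sigma2_e")
    mats.append(np.eye(design.n_records))
    return names, mats


def _restricted_loglik(theta, names, mats, x, y):
    v = sum(t * m for t, m in zip(theta, mats))
    try:
        lv = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return None
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return None
    logdet_v = 2.0 * np.log(np.diag(lv)).sum()
    p_mat = vinv - vinv @ x @ np.linalg.solve(xtvx, x.T @ vinv)
    py = p_mat @ y
    ll = -0.5 * (logdet_v + logdet_xtvx + y @ py)
    return ll, p_mat, py


def _feasible(theta, names) -> bool:
    for t, name in zip(theta, names):
        if name != "cov_um" and t <= 0:
            return False
    if "cov_um" in names:
        su = theta[names.index("sigma2_u")]
        sm = theta[names.index("sigma2_m")]
        c = theta[names.index("cov_um")]
        if c * c >= su * sm:
            return False
    return True


def reml_aic(spec: ModelSpec, design: DesignMatrices, structures: dict,
             max_iter: int = 60, tol: float = 1e-8) -> REMLResult:
    """Estimate variance components by AI-REML and report the AIC.

    ``structures`` maps "A"/"H" and "lambda" to dense relationship matrices
    (not inverses).  AIC = −2·logL_restricted + 2·(free (co)variance
    parameters); variances estimated at the zero boundary are pinned there.
    """
    names, mats = _v_components(spec, design, structures)
    x = design.x.toarray()
    y = design.y
    vary = float(np.var(y))
    floor = max(1e-8 * vary, 1e-12)

    k = len(names)
    theta = np.full(k, vary / k)
    if "cov_um" in names:
        theta[names.index("cov_um")] = 0.0
    pinned = np.zeros(k, dtype=bool)

    ll, p_mat, py = _restricted_loglik(theta, names, mats, x, y)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        # score and average-information matrix (V_k symmetric, so
        # tr(P V_k) = sum(P ∘ V_k) and no dense matrix products are needed)
        score = np.empty(k)
        trace_pv = np.array([np.sum(p_mat * m) for m in mats])
        mpy = [m @ py for m in mats]
        for i in range(k):
            score[i] = -0.5 * (trace_pv[i] - py @ mpy[i])
        pmpy = [p_mat @ v for v in mpy]
        ai = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * mpy[i] @ pmpy[j]

        free = ~pinned
        step = np.zeros(k)
        try:
            step[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
            ai_ok = True
        except np.linalg.LinAlgError:
            ai_ok = False
        if not ai_ok:
            # EM-REML fallback: guaranteed uphill, always feasible
            for i in range(k):
                if pinned[i] or names[i] == "cov_um":
                    continue
                step[i] = (theta[i] ** 2 / design.n_records
                           * (py @ mpy[i] - trace_pv[i]))

        # step-halve into the feasible region
        scale = 1.0
        new = theta + step
        while not _feasible(np.where(pinned, theta, new), names) and scale > 1e-4:
            scale *= 0.5
            new = theta + scale * step
        new = np.where(pinned, theta, new)
        if not _feasible(new, names):
            # pin offending variances at the floor
            for i in range(k):
                if names[i] != "cov_um" and new[i] <= floor:
                    new[i] = floor
                    pinned[i] = True
            if "cov_um" in names:
                ci = names.index("cov_um")
                su = new[names.index("sigma2_u")]
                sm = new[names.index("sigma2_m")]
                bound = 0.99 * np.sqrt(su * sm)
                new[ci] = np.clip(new[ci], -bound, bound)

        res = _restricted_loglik(new, names, mats, x, y)
        if res is None:
            scale = 0.5
            while res is None and scale > 1e-6:
                new = theta + scale * (new - theta)
                res = _restricted_loglik(new, names, mats, x, y)
                scale *= 0.5
            if res is None:
                message = "restricted likelihood not evaluable"
                break
        new_ll, p_mat, py = res
        delta = np.max(np.abs(new - theta)) / max(vary, 1e-12)
        theta = new
        ll = new_ll
        if delta < tol or np.max(np.abs(score[~pinned])) < 1e-6:
            converged = True
            break
    else:
        message = "maximum iterations reached"

    kw = {}
    for name, t in zip(names, theta):
        val = float(t)
        if name != "cov_um" and val <= 2 * floor:
            val = 0.0 if name != "sigma2_e" else val
        kw[name] = val
    # zero-pinned variances stay in the component set at the boundary
    vc = VarianceComponents(**kw)
    aic = -2.0 * ll + 2.0 * k
    return REMLResult(vc=vc, loglik=float(ll), aic=float(aic),
                      converged=converged, n_iter=it, message=message)
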