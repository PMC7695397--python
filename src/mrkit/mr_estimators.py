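"""Univariable two-sample MR estimators and the MR-Egger pleiotropy test.

All estimators consume harmonized per-SNP vectors: exposure betas ``bx``
with SEs ``sx``, outcome betas ``by`` with SEs ``sy``.  The causal effect
is on the outcome's beta scale (log-odds ratio for a binary outcome), and
every estimate is also reported as an odds ratio with a normal 95% CI.

* IVW fixed effects — inverse-variance-weighted mean of per-SNP ratio
  estimates; algebraically a weighted regression of by on bx through the
  origin with weights 1/sy².
* Maximum likelihood — joint normal model bx_j ~ N(ξ_j, sx_j²),
  by_j ~ N(θ·ξ_j, sy_j²) with the nuisance true effects ξ_j profiled out;
  unlike IVW it accounts for exposure-side sampling error.
* Weighted median — the 50th percentile of the ratio estimates under
  inverse-variance weights; consistent when ≥50% of weight comes from
  valid instruments.  SE by parametric bootstrap.
* MR-Egger — weighted regression of by on bx with an unconstrained
  intercept; a nonzero intercept estimates directional pleiotropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("mrkit")

#: normal 97.5th percentile used for all 95% confidence intervals
Z_95 = 1.959964


class EstimationError(ValueError):
    """Estimator preconditions violated (too few SNPs, degenerate inputs)."""


class ConvergenceError(RuntimeError):
    """Iterative optimisation failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class MrEstimate:
    """One estimator's causal effect with SE, p, and odds-ratio CI."""

    method: str  # ivw_fe | max_lik | weighted_median | egger_slope
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    or_lci95: float
    or_uci95: float

    @classmethod
    def from_beta(cls, method: str, n_snp: int, beta: float, se: float,
                  pval: float | None = None) -> "MrEstimate":
        if pval is None:
            pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")
        return cls(
            method=method,
            n_snp=n_snp,
            beta=float(beta),
            se=float(se),
            pval=float(pval),
            or_=math.exp(beta),
            or_lci95=math.exp(beta - Z_95 * se),
            or_uci95=math.exp(beta + Z_95 * se),
        )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger intercept (directional-pleiotropy estimate) and slope."""

    intercept: float
    intercept_se: float
    intercept_pval: float
    slope: MrEstimate


def _as_vectors(bx, sx, by, sy):
    bx, sx, by, sy = (np.asarray(v, dtype=float).ravel() for v in (bx, sx, by, sy))
    if not (len(bx) == len(sx) == len(by) == len(sy)):
        raise EstimationError("bx, sx, by, sy must have equal length")
    if np.any(sy <= 0) or not np.all(np.isfinite(sy)):
        raise EstimationError("all outcome SEs must be finite and > 0")
    return bx, sx, by, sy


def ivw_fixed_effects(bx, sx, by, sy) -> MrEstimate:
    """Inverse-variance-weighted fixed-effects estimate.

    θ̂ = Σ bx·by/sy² / Σ bx²/sy², se(θ̂) = (Σ bx²/sy²)^(−1/2); exposure-side
    SEs are ignored (the NOME approximation), matching the fixed-effects
    convention.  Set ``random_effects=True`` on :func:`ivw` for the
    multiplicative random-effects variant.
    """
    return ivw(bx, sx, by, sy, random_effects=False)


def ivw(bx, sx, by, sy, random_effects: bool = False) -> MrEstimate:
    bx, sx, by, sy = _as_vectors(bx, sx, by, sy)
    J = len(bx)
    if J == 0:
        raise EstimationError("IVW requires at least one SNP")
    w = sy**-2
    denom = float(np.sum(bx**2 * w))
    if denom == 0.0:
        raise EstimationError("all exposure betas are zero: causal effect undefined")
    theta = float(np.sum(bx * by * w)) / denom
    se = denom**-0.5
    if random_effects and J > 1:
        # multiplicative overdispersion: scale by sqrt(Cochran Q / (J-1)), floored at 1
        q = float(np.sum(w * (by - theta * bx) ** 2))
        se *= max(1.0, math.sqrt(q / (J - 1)))
    return MrEstimate.from_beta("ivw_fe" if not random_effects else "ivw_mre", J, theta, se)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def _profile_loglik(theta: float, bx, sx, by, sy) -> float:
    # profiling the per-SNP nuisance means out of the joint normal model
    # leaves -0.5 * sum (by - theta*bx)^2 / (sy^2 + theta^2 sx^2) + const
    v = sy**2 + theta**2 * sx**2
    r = by - theta * bx
    return -0.5 * float(np.sum(r * r / v))


def _profile_grad(theta: float, bx, sx, by, sy) -> float:
    v = sy**2 + theta**2 * sx**2
    r = by - theta * bx
    return float(np.sum(bx * r / v) + theta * np.sum(sx**2 * r * r / v**2))


def maximum_likelihood(bx, sx, by, sy, grad_tol: float = 1e-8,
                       max_iter: int = 200) -> MrEstimate:
    """Profile-likelihood MR estimate accounting for exposure-side error.

    The nuisance true SNP-exposure effects are profiled out analytically;
    the scalar profile log-likelihood is maximised by Newton iteration from
    the IVW starting value.  The SE comes from the observed information
    (numerical curvature of the profile log-likelihood) at the optimum.
    Convergence requires the gradient to fall below ``grad_tol`` (or the
    Newton step to fall below machine precision).
    """
    bx, sx, by, sy = _as_vectors(bx, sx, by, sy)
    J = len(bx)
    if J < 2:
        raise EstimationError("maximum likelihood requires at least 2 SNPs")
    if np.any(sx < 0) or not np.all(np.isfinite(sx)):
        raise EstimationError("exposure SEs must be finite and >= 0")

    theta = ivw_fixed_effects(bx, sx, by, sy).beta
    h0 = 1e-6 * (1.0 + abs(theta))
    converged = False
    for _ in range(max_iter):
        g = _profile_grad(theta, bx, sx, by, sy)
        if abs(g) <= grad_tol:
            converged = True
            break
        h = 1e-6 * (1.0 + abs(theta))
        curv = (_profile_grad(theta + h, bx, sx, by, sy)
                - _profile_grad(theta - h, bx, sx, by, sy)) / (2 * h)
        if curv >= 0:  # not locally concave: damped gradient ascent fallback
            step = g * 1e-3
        else:
            step = -g / curv
        if abs(step) > 1.0 + abs(theta):  # damp wild steps
            step = math.copysign(1.0 + abs(theta), step)
        theta += step
        if abs(step) <= 4 * np.finfo(float).eps * (1.0 + abs(theta)):
            converged = True  # stationary to machine precision
            break
    if not converged:
        g = _profile_grad(theta, bx, sx, by, sy)
        raise ConvergenceError(
            f"profile-likelihood Newton did not converge: |grad|={abs(g):.3e} "
            f"> {grad_tol:g} after {max_iter} iterations (theta={theta:.6g})"
        )

    h = max(h0, 1e-6 * (1.0 + abs(theta)))
    curv = (_profile_grad(theta + h, bx, sx, by, sy)
            - _profile_grad(theta - h, bx, sx, by, sy)) / (2 * h)
    if curv >= 0:
        raise ConvergenceError("profile log-likelihood not concave at the optimum")
    se = (-curv) ** -0.5
    return MrEstimate.from_beta("max_lik", J, theta, se)


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: quantile of ratios at cumulative
    weight 0.5, with breakpoints p_j = S_j − w_j/2 (weights normalized)."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(bx, sx, by, sy, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios by/bx are weighted by bx²/sy² (the inverse variance of
    the ratio under the NOME approximation); the estimate interpolates the
    weighted 50th percentile.  SNPs with bx exactly 0 are excluded with a
    warning.  The SE is the SD of the estimate over ``n_boot`` parametric
    resamples of (bx, by) from their reported sampling distributions.
    """
    bx, sx, by, sy = _as_vectors(bx, sx, by, sy)
    nonzero = bx != 0.0
    if not np.all(nonzero):
        logger.warning("weighted_median: excluding %d SNP(s) with exposure beta 0",
                       int(np.sum(~nonzero)))
        bx, sx, by, sy = bx[nonzero], sx[nonzero], by[nonzero], sy[nonzero]
    J = len(bx)
    if J < 3:
        raise EstimationError("weighted median requires at least 3 SNPs with nonzero bx")

    theta = _weighted_median_point(by / bx, bx**2 / sy**2)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + rng.normal(0.0, sx) if np.any(sx > 0) else bx
        bys = by + rng.normal(0.0, sy)
        ok = bxs != 0.0
        boots[i] = _weighted_median_point(bys[ok] / bxs[ok], bxs[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return MrEstimate.from_beta("weighted_median", J, theta, se)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(bx, sx, by, sy) -> EggerResult:
    """MR-Egger regression: weighted by-on-bx fit with a free intercept.

    Each SNP is first re-signed so bx ≥ 0 (the InSIDE orientation
    convention); the regression is weighted by 1/sy².  The intercept
    estimates directional pleiotropy; intercept and slope p-values use the
    t distribution on J−2 degrees of freedom.
    """
    bx, sx, by, sy = _as_vectors(bx, sx, by, sy)
    J = len(bx)
    if J < 3:
        raise EstimationError("MR-Egger requires at least 3 SNPs")
    sign = np.where(bx < 0, -1.0, 1.0)
    bxo, byo = bx * sign, by * sign
    if np.ptp(bxo) == 0.0:
        raise EstimationError("no spread in |exposure betas|: Egger slope unidentifiable")

    X = sm.add_constant(bxo)
    fit = sm.WLS(byo, X, weights=sy**-2).fit()
    icept, slope = fit.params
    icept_se, slope_se = fit.bse
    df = J - 2
    # an exact fit leaves 0/0 noise in the intercept t statistic; report p=1
    yscale = float(np.sum((byo / sy) ** 2))
    exact = fit.ssr <= 1e-24 * max(yscale, 1e-300)
    if exact or icept_se == 0:
        icept_p = 1.0
    else:
        icept_p = 2.0 * stats.t.sf(abs(icept / icept_se), df)
    slope_p = 2.0 * stats.t.sf(abs(slope / slope_se), df)
    return EggerResult(
        intercept=float(icept),
        intercept_se=float(icept_se),
        intercept_pval=float(icept_p),
        slope=MrEstimate.from_beta("egger_slope", J, slope, slope_se, pval=slope_p),
    )


ESTIMATORS = {
    "ivw": ivw_fixed_effects,
    "ml": maximum_likelihood,
    "wm": weighted_median,
}

METHOD_LABELS = {
    "ivw_fe": "IVW fixed effects",
    "ivw_mre": "IVW multiplicative random effects",
    "max_lik": "Maximum likelihood",
    "weighted_median": "Weighted median",
    "egger_slope": "MR Egger",
}
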