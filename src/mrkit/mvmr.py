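"""Multivariable IVW: joint direct effects of K exposures on the outcome.

The outcome betas are regressed on the J×K matrix of exposure betas with
no intercept (exclusion restriction), weighted by the inverse outcome
variance.  With K = 1 this reduces exactly to univariable fixed-effects
IVW.  Collinear exposures (e.g. algebraically related lipid fractions) are
surfaced through the smallest singular value of the weighted design rather
than silently regularized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonization import HarmonizedDataset
from .mr_estimators import Z_95, EstimationError


@dataclass
class MvmrEstimate:
    """Per-exposure joint (direct) causal effects from multivariable IVW."""

    exposure_ids: list[str]
    theta: np.ndarray  # (K,)
    se: np.ndarray  # (K,)
    pval: np.ndarray  # (K,)
    n_snp: int
    #: smallest singular value of the weighted design (conditioning diagnostic)
    min_singular_value: float

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.theta)

    @property
    def or_lci95(self) -> np.ndarray:
        return np.exp(self.theta - Z_95 * self.se)

    @property
    def or_uci95(self) -> np.ndarray:
        return np.exp(self.theta + Z_95 * self.se)


def mvmr_ivw(dataset: HarmonizedDataset, residual_scale: bool = False) -> MvmrEstimate:
    """Multivariable IVW fit θ̂ = (XᵀWX)⁻¹XᵀWy with W = diag(sy⁻²).

    The fixed-effects covariance is (XᵀWX)⁻¹; with ``residual_scale=True``
    it is multiplied by the residual mean square (floored at 1), the
    multiplicative random-effects variant.  Rank deficiency (smallest
    singular value < 1e−10 × largest) is fatal and names the exposures
    involved in the collinearity.
    """
    X = np.asarray(dataset.bx, dtype=float)
    y = np.asarray(dataset.by, dtype=float)
    sy = np.asarray(dataset.sy, dtype=float)
    J, K = X.shape
    if J <= K:
        raise EstimationError(f"multivariable IVW needs more SNPs than exposures (J={J}, K={K})")

    sw = 1.0 / sy
    Xw = X * sw[:, None]
    yw = y * sw
    u, s, vt = np.linalg.svd(Xw, full_matrices=False)
    if s[0] == 0 or s[-1] < 1e-10 * s[0]:
        null = vt[-1]
        guilty = [dataset.exposure_ids[k] for k in np.flatnonzero(np.abs(null) > 1e-6)]
        raise EstimationError(
            "weighted design is rank deficient; collinear exposure(s): " + ", ".join(guilty)
        )

    xtwx_inv = (vt.T / s**2) @ vt
    theta = xtwx_inv @ (Xw.T @ yw)
    cov = xtwx_inv
    if residual_scale:
        resid = yw - Xw @ theta
        cov = cov * max(1.0, float(resid @ resid) / (J - K))
    se = np.sqrt(np.diag(cov))
    pval = 2.0 * stats.norm.sf(np.abs(theta) / se)
    return MvmrEstimate(
        exposure_ids=list(dataset.exposure_ids),
        theta=theta,
        se=se,
        pval=pval,
        n_snp=J,
        min_singular_value=float(s[-1]),
    )
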