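"""Multivariable MR with Bayesian model averaging (risk-factor selection).

Risk-factor selection is cast as variable selection in the weighted linear
model relating SNP-outcome effects to SNP-exposure effects.  Working on the
standardized scale ỹ_j = by_j/sy_j, X̃_jk = bx_jk/sy_j (unit residual
variance), each subset γ of exposures is scored by the closed-form marginal
likelihood under a zero-centred Gaussian prior with effect SD σ_prior on
the causal effects (no intercept), combined with an independent Bernoulli
inclusion prior p per factor:

    PP(γ) ∝ p^|γ| (1−p)^(K−|γ|) · m(ỹ | X̃_γ)

normalized over the enumerated models.  Reported per factor are the
marginal inclusion probability MIP_k = Σ_{γ∋k} PP(γ) and the
model-averaged causal estimate MACE_k = Σ_γ PP(γ)·θ̂_kγ, with θ̂_kγ the
posterior-mean effect in γ (0 when k ∉ γ).  Models are ranked by PP,
factors by MIP.

Exact enumeration of all nonempty subsets is the default (511 models for
nine factors); a shotgun-style stochastic search over the model space is
provided for larger K, renormalizing over the set of distinct models
visited.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .harmonization import HarmonizedDataset

logger = logging.getLogger("mrkit")

MAX_EXACT_FACTORS = 20


class BmaError(ValueError):
    pass


@dataclass
class BmaConfig:
    """Priors and search settings for :func:`run_bma`.

    ``prior_inclusion`` and ``prior_scale`` default to the originating
    method's published values (p = 0.1, σ = 0.25); marginal inclusion
    probabilities are prior-sensitive, so both are always echoed in output.
    """

    prior_inclusion: float = 0.1
    prior_scale: float = 0.25
    max_model_size: int | None = None  # None: unrestricted (all combinations)
    enumeration: str = "exact"  # "exact" | "stochastic"
    n_iter: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_inclusion < 1.0):
            raise BmaError("prior_inclusion must lie in (0, 1)")
        if self.prior_scale <= 0:
            raise BmaError("prior_scale must be > 0")
        if self.enumeration not in ("exact", "stochastic"):
            raise BmaError(f"unknown enumeration mode {self.enumeration!r}")


@dataclass
class BmaResult:
    """Posterior over factor subsets plus per-factor MIP and MACE."""

    factor_ids: list[str]
    #: list of (subset tuple of factor indices, PP, {index: posterior-mean θ})
    models: list[tuple]
    mip: np.ndarray  # (K,)
    mace: np.ndarray  # (K,)
    config: BmaConfig = field(default=None)

    @property
    def ranking(self) -> list[int]:
        """Factor indices sorted by MIP descending, ties by factor name."""
        return sorted(range(len(self.factor_ids)),
                      key=lambda k: (-self.mip[k], self.factor_ids[k]))

    def top_models(self, n: int = 10) -> list[tuple]:
        return sorted(self.models, key=lambda m: -m[1])[:n]


def _design(dataset: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray]:
    sy = np.asarray(dataset.sy, dtype=float)
    X = np.asarray(dataset.bx, dtype=float) / sy[:, None]
    y = np.asarray(dataset.by, dtype=float) / sy
    return X, y


def _log_marginal(Xg: np.ndarray, y: np.ndarray, sigma: float):
    """Closed-form log marginal likelihood and posterior-mean effects.

    Model: y = Xg θ + ε, ε ~ N(0, I), θ ~ N(0, σ² I).  Marginally
    y ~ N(0, I + σ² Xg Xgᵀ); determinant and quadratic form are reduced to
    the k×k scale via the matrix determinant lemma and Woodbury identity.
    Returns (−inf, None) for a rank-deficient subset design.
    """
    J, k = Xg.shape
    xtx = Xg.T @ Xg
    eig = np.linalg.eigvalsh(xtx)
    if eig[-1] <= 0 or eig[0] < 1e-10 * eig[-1]:
        return -np.inf, None
    A = xtx + np.eye(k) / sigma**2
    xty = Xg.T @ y
    theta_post = np.linalg.solve(A, xty)
    quad = float(y @ y - xty @ theta_post)
    sign, logdet_A = np.linalg.slogdet(A)
    # |I_J + σ² X Xᵀ| = σ^{2k} |XᵀX + I/σ²|
    logdet = 2 * k * math.log(sigma) + logdet_A
    logml = -0.5 * (J * math.log(2 * math.pi) + logdet + quad)
    return logml, theta_post


def score_model(dataset: HarmonizedDataset, subset, config: BmaConfig):
    """Log marginal likelihood and posterior-mean estimates for one subset.

    A rank-deficient subset (e.g. duplicated columns) receives −inf
    (zero posterior weight) and is logged.
    """
    subset = tuple(sorted(subset))
    if not subset:
        raise BmaError("subset must be nonempty")
    X, y = _design(dataset)
    logml, theta = _log_marginal(X[:, list(subset)], y, config.prior_scale)
    if theta is None:
        logger.warning("model %s is rank deficient: assigned zero posterior weight", subset)
        return logml, {}
    return logml, {k: float(t) for k, t in zip(subset, theta)}


def _model_log_prior(size: int, K: int, p: float) -> float:
    return size * math.log(p) + (K - size) * math.log1p(-p)


def _finalize(factor_ids, scored, K, config) -> BmaResult:
    """Normalize scored models into PPs, MIP and MACE."""
    subsets = list(scored.keys())
    logpost = np.array([scored[s][0] + _model_log_prior(len(s), K, config.prior_inclusion)
                        for s in subsets])
    finite = np.isfinite(logpost)
    if not finite.any():
        raise BmaError("all candidate models have zero posterior weight")
    lz = logsumexp(logpost[finite])
    pp = np.where(finite, np.exp(logpost - lz, where=finite, out=np.zeros_like(logpost)), 0.0)

    mip = np.zeros(K)
    mace = np.zeros(K)
    models = []
    for s, prob in zip(subsets, pp):
        estimates = scored[s][1]
        models.append((s, float(prob), estimates))
        for k in s:
            mip[k] += prob
        for k, t in estimates.items():
            mace[k] += prob * t
    models.sort(key=lambda m: -m[1])
    mip = np.clip(mip, 0.0, 1.0)  # guard float-summation overshoot
    return BmaResult(factor_ids=list(factor_ids), models=models, mip=mip, mace=mace,
                     config=config)


def run_bma(dataset: HarmonizedDataset, config: BmaConfig | None = None) -> BmaResult:
    """Enumerate (or stochastically search) factor subsets and average.

    Exact mode enumerates every nonempty subset up to ``max_model_size``
    and is the default for K ≤ 20.  Stochastic mode runs a Metropolis
    add/remove/swap walk over subsets, scoring each distinct model once and
    renormalizing over the visited set; with enough iterations at small K
    it visits every model and coincides with exact enumeration.
    """
    config = config or BmaConfig()
    K = dataset.n_exposures
    max_size = config.max_model_size or K
    X, y = _design(dataset)
    sigma = config.prior_scale

    def score(subset: tuple):
        logml, theta = _log_marginal(X[:, list(subset)], y, sigma)
        if theta is None:
            logger.warning("model %s is rank deficient: assigned zero posterior weight", subset)
            return logml, {}
        return logml, {k: float(t) for k, t in zip(subset, theta)}

    if config.enumeration == "exact":
        if K > MAX_EXACT_FACTORS:
            raise BmaError(
                f"exact enumeration with K={K} > {MAX_EXACT_FACTORS} factors is intractable; "
                "use enumeration='stochastic'"
            )
        scored = {}
        for size in range(1, max_size + 1):
            for subset in itertools.combinations(range(K), size):
                scored[subset] = score(subset)
        return _finalize(dataset.exposure_ids, scored, K, config)

    # stochastic shotgun-style search
    rng = np.random.default_rng(config.seed)
    scored: dict[tuple, tuple] = {}

    def log_post(subset: tuple) -> float:
        if subset not in scored:
            scored[subset] = score(subset)
        return scored[subset][0] + _model_log_prior(len(subset), K, config.prior_inclusion)

    current = (int(rng.integers(K)),)
    lp_cur = log_post(current)
    for _ in range(config.n_iter):
        cur = set(current)
        move = rng.integers(3)
        prop = set(cur)
        if move == 0 and len(cur) < max_size:  # add
            choices = [k for k in range(K) if k not in cur]
            if choices:
                prop.add(int(rng.choice(choices)))
        elif move == 1 and len(cur) > 1:  # remove
            prop.discard(int(rng.choice(sorted(cur))))
        else:  # swap
            choices = [k for k in range(K) if k not in cur]
            if choices:
                prop.discard(int(rng.choice(sorted(cur))))
                prop.add(int(rng.choice(choices)))
        proposal = tuple(sorted(prop))
        if proposal == current or not proposal:
            continue
        lp_prop = log_post(proposal)
        if math.log(rng.random()) < lp_prop - lp_cur:
            current, lp_cur = proposal, lp_prop
    return _finalize(dataset.exposure_ids, scored, K, config)
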