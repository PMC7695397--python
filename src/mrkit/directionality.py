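"""Causal-direction diagnostics: Steiger test and bi-directional MR.

The Steiger test asks whether the instruments explain more variance in the
exposure than in the outcome; if not, the assumed causal direction is
suspect (e.g. reverse causation).  Bi-directional MR simply re-runs the
whole instrument-selection → harmonization → estimation pipeline with the
roles of the two traits exchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonization import HarmonizedDataset, HarmonizationError, harmonize
from .iv_selection import DEFAULT_LD_R2_MAX, DEFAULT_P_THRESHOLD, select_instruments
from .mr_estimators import (EstimationError, MrEstimate, ivw_fixed_effects,
                            maximum_likelihood, weighted_median)
from .sumstats_io import LdTable, SummaryStatsTable

logger = logging.getLogger("mrkit")


class DirectionalityError(ValueError):
    pass


@dataclass(frozen=True)
class SteigerResult:
    exposure_id: str
    n_snp: int
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    steiger_pval: float
    #: natural-log p-value, exact even when steiger_pval underflows to 0
    log_pval: float

    def format_pval(self) -> str:
        """Human-readable p; extreme underflow printed as '<1e-300'."""
        return "<1e-300" if self.steiger_pval < 1e-300 else f"{self.steiger_pval:.3g}"


def _r2_from_tstat(beta: np.ndarray, se: np.ndarray, n: int) -> np.ndarray:
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def _r2_from_maf(beta: np.ndarray, eaf: np.ndarray) -> np.ndarray:
    maf = np.minimum(eaf, 1.0 - eaf)
    return 2.0 * beta**2 * maf * (1.0 - maf)


def steiger_test(
    dataset: HarmonizedDataset,
    n_exp: int | None = None,
    n_out: int | None = None,
    method: str = "tstat",
) -> SteigerResult:
    """Steiger directionality test for a single-exposure dataset.

    Per-SNP variance explained is recovered from the association test
    statistic, r_j² = t_j²/(t_j² + n − 2), and summed over the (assumed
    independent) instruments for each trait.  ``method="maf"`` instead uses
    2β²·MAF(1−MAF), valid for standardized continuous traits with reported
    allele frequencies.  The p-value compares the two aggregate
    correlations √r² via Fisher's z transform, treating the two GWAS
    cohorts as independent samples.
    """
    if dataset.n_exposures != 1:
        raise DirectionalityError("steiger_test expects a single-exposure dataset")
    n_exp = n_exp if n_exp is not None else dataset.n_x[0]
    n_out = n_out if n_out is not None else dataset.n_y
    if n_exp is None:
        raise DirectionalityError(f"sample size unknown for exposure {dataset.exposure_ids[0]!r}")
    if n_out is None:
        raise DirectionalityError(f"sample size unknown for outcome {dataset.outcome_id!r}")

    bx, sx = dataset.bx[:, 0], dataset.sx[:, 0]
    if method == "tstat":
        r2x = _r2_from_tstat(bx, sx, n_exp)
        r2y = _r2_from_tstat(dataset.by, dataset.sy, n_out)
    elif method == "maf":
        r2x = _r2_from_maf(bx, dataset.eaf_x[:, 0])
        r2y = _r2_from_maf(dataset.by, dataset.eaf_y)
    else:
        raise DirectionalityError(f"unknown method {method!r}")

    r2_exp, r2_out = float(np.sum(r2x)), float(np.sum(r2y))
    for name, val in (("exposure", r2_exp), ("outcome", r2_out)):
        if val >= 1.0:
            raise DirectionalityError(
                f"summed r² in {name} is {val:.3f} ≥ 1: instruments are not "
                "independent or inputs are corrupt"
            )

    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / denom
    log_p = np.log(2.0) + stats.norm.logsf(abs(z))
    return SteigerResult(
        exposure_id=dataset.exposure_ids[0],
        n_snp=dataset.n_snps,
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        correct_direction=r2_exp > r2_out,
        steiger_pval=float(np.exp(log_p)),
        log_pval=float(log_p),
    )


def _one_direction(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LdTable | None,
    p_threshold: float,
    ld_r2_max: float,
    palindrome_eaf_window: tuple,
    n_boot: int,
    seed: int,
) -> list[MrEstimate]:
    iv = select_instruments(exposure, ld, p_threshold, ld_r2_max)
    if not iv.snp_ids:
        return []
    try:
        ds = harmonize(exposure.subset(iv.snp_ids), outcome, palindrome_eaf_window)
    except HarmonizationError:
        return []
    bx, sx = ds.bx[:, 0], ds.sx[:, 0]
    out: list[MrEstimate] = []
    for fn, kwargs in (
        (ivw_fixed_effects, {}),
        (maximum_likelihood, {}),
        (weighted_median, {"n_boot": n_boot, "seed": seed}),
    ):
        try:
            out.append(fn(bx, sx, ds.by, ds.sy, **kwargs))
        except EstimationError as exc:
            logger.warning("%s -> %s: %s skipped (%s)",
                           exposure.trait_id, outcome.trait_id, fn.__name__, exc)
    return out


def bidirectional_mr(
    forward_exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LdTable | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    ld_r2_max: float = DEFAULT_LD_R2_MAX,
    palindrome_eaf_window: tuple = (0.42, 0.58),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Run selection → harmonization → {IVW, ML, weighted median} both ways.

    Returns ``{"forward": [...], "reverse": [...]}``; a direction with zero
    surviving instruments is reported as an empty list while the other is
    still produced.
    """
    forward = _one_direction(forward_exposure, outcome, ld, p_threshold, ld_r2_max,
                             palindrome_eaf_window, n_boot, seed)
    reverse = _one_direction(outcome, forward_exposure, ld, p_threshold, ld_r2_max,
                             palindrome_eaf_window, n_boot, seed)
    if not forward:
        logger.warning("forward direction %s -> %s: no usable instruments",
                       forward_exposure.trait_id, outcome.trait_id)
    if not reverse:
        logger.warning("reverse direction %s -> %s: no usable instruments",
                       outcome.trait_id, forward_exposure.trait_id)
    return {"forward": forward, "reverse": reverse}
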