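"""Allele harmonization: put exposure and outcome effects on one strand.

Every estimator downstream assumes that, for each SNP, the exposure beta
and the outcome beta refer to the same effect allele.  GWAS consortia do
not share an orientation convention, so records can disagree by an allele
swap (effect/other exchanged), a strand flip (both alleles complemented),
or both.  Palindromic SNPs (A/T, C/G) are their own strand complement and
can only be oriented through the effect-allele frequency: if the frequency
is too close to 0.5 the orientation is unknowable and the SNP is dropped.

The first exposure table holding a SNP defines the reference orientation;
all other exposures and the outcome are aligned to it.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats_io import GwasRecord, LdTable, SummaryStatsTable

logger = logging.getLogger("mrkit")


class HarmonizationError(ValueError):
    """No SNPs survived harmonization (or inputs were unusable)."""


# action tags, one per kept SNP (describing the outcome-record alignment)
KEPT = "kept-as-is"
SIGN_FLIPPED = "sign-flipped"
STRAND_COMPLEMENTED = "strand-complemented"
PALINDROMIC_ALIGNED = "palindromic-aligned"
DROPPED = "dropped"

DEFAULT_PALINDROME_WINDOW = (0.42, 0.58)


@dataclass
class HarmonizedDataset:
    """SNP-aligned effect matrices on a common effect-allele orientation.

    Rows are SNPs (length J), columns are exposures (K).  A SNP absent from
    an exposure (multivariable mode only) carries beta 0 and SE +inf as the
    missing marker, giving it zero weight for that exposure.
    """

    snp_ids: list[str]
    exposure_ids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    bx: np.ndarray  # (J, K)
    sx: np.ndarray  # (J, K); +inf marks a missing exposure record
    pvals_x: np.ndarray  # (J, K)
    eaf_x: np.ndarray  # (J, K)
    by: np.ndarray  # (J,)
    sy: np.ndarray  # (J,)
    pvals_y: np.ndarray  # (J,)
    eaf_y: np.ndarray  # (J,)
    n_x: list  # per-exposure sample size (None when unknown)
    n_y: int | None
    outcome_id: str = "outcome"
    outcome_type: str = "binary"
    #: snp_id -> (action, reason); includes dropped SNPs
    provenance: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    def for_exposure(self, k: int) -> "HarmonizedDataset":
        """Univariable view: SNPs with an observed record for exposure k."""
        keep = np.isfinite(self.sx[:, k])
        idx = np.flatnonzero(keep)
        return HarmonizedDataset(
            snp_ids=[self.snp_ids[i] for i in idx],
            exposure_ids=[self.exposure_ids[k]],
            effect_allele=[self.effect_allele[i] for i in idx],
            other_allele=[self.other_allele[i] for i in idx],
            bx=self.bx[np.ix_(idx, [k])],
            sx=self.sx[np.ix_(idx, [k])],
            pvals_x=self.pvals_x[np.ix_(idx, [k])],
            eaf_x=self.eaf_x[np.ix_(idx, [k])],
            by=self.by[idx],
            sy=self.sy[idx],
            pvals_y=self.pvals_y[idx],
            eaf_y=self.eaf_y[idx],
            n_x=[self.n_x[k]],
            n_y=self.n_y,
            outcome_id=self.outcome_id,
            outcome_type=self.outcome_type,
            provenance={s: self.provenance[s] for s in (self.snp_ids[i] for i in idx)},
        )

    def to_tables(self) -> tuple[list[SummaryStatsTable], SummaryStatsTable]:
        """Reconstruct sumstats tables in the harmonized orientation."""

        def _rec(j, k):
            if not np.isfinite(self.sx[j, k]):
                return None
            return GwasRecord(
                snp_id=self.snp_ids[j],
                effect_allele=self.effect_allele[j],
                other_allele=self.other_allele[j],
                beta=float(self.bx[j, k]),
                se=float(self.sx[j, k]),
                pval=float(self.pvals_x[j, k]),
                eaf=None if np.isnan(self.eaf_x[j, k]) else float(self.eaf_x[j, k]),
                n=self.n_x[k],
            )

        exposures = [
            SummaryStatsTable(
                self.exposure_ids[k],
                "continuous",
                [r for j in range(self.n_snps) if (r := _rec(j, k)) is not None],
            )
            for k in range(self.n_exposures)
        ]
        outcome = SummaryStatsTable(
            self.outcome_id,
            self.outcome_type,
            [
                GwasRecord(
                    snp_id=self.snp_ids[j],
                    effect_allele=self.effect_allele[j],
                    other_allele=self.other_allele[j],
                    beta=float(self.by[j]),
                    se=float(self.sy[j]),
                    pval=float(self.pvals_y[j]),
                    eaf=None if np.isnan(self.eaf_y[j]) else float(self.eaf_y[j]),
                    n=self.n_y,
                )
                for j in range(self.n_snps)
            ],
        )
        return exposures, outcome

    def report(self) -> pd.DataFrame:
        rows = [
            {"snp": snp, "action": act, "reason": reason}
            for snp, (act, reason) in self.provenance.items()
        ]
        return pd.DataFrame(rows, columns=["snp", "action", "reason"])


def _align_to_reference(
    ref: GwasRecord,
    rec: GwasRecord,
    window: tuple,
) -> tuple[int, str, str]:
    """Alignment of ``rec`` onto the orientation of ``ref``.

    Returns ``(sign, action, reason)``: ``sign`` +1 keeps rec's beta, −1
    negates it, 0 drops the SNP (reason then says why).
    """
    lo, hi = window
    ref_pair = frozenset((ref.effect_allele, ref.other_allele))

    if ref.is_palindromic:
        rec_pair = frozenset((rec.effect_allele, rec.other_allele))
        if rec_pair != ref_pair:
            return 0, DROPPED, "incompatible alleles"
        # nominal alignment by allele labels, then frequency concordance
        sign = 1 if rec.effect_allele == ref.effect_allele else -1
        eaf = rec.eaf if sign == 1 else (None if rec.eaf is None else 1.0 - rec.eaf)
        if ref.eaf is None or eaf is None:
            return 0, DROPPED, "ambiguous palindrome (missing eaf)"
        if lo < ref.eaf < hi or lo < eaf < hi:
            return 0, DROPPED, "ambiguous palindrome"
        same_side = (ref.eaf < 0.5) == (eaf < 0.5)
        final = sign if same_side else -sign
        if final == 1 and rec.effect_allele == ref.effect_allele:
            return 1, KEPT, ""  # already oriented: idempotent re-pass
        return final, PALINDROMIC_ALIGNED, ""

    for complemented in (False, True):
        cand = rec.complemented() if complemented else rec
        if cand.effect_allele == ref.effect_allele and cand.other_allele == ref.other_allele:
            if complemented:
                return 1, STRAND_COMPLEMENTED, ""
            return 1, KEPT, ""
        if cand.effect_allele == ref.other_allele and cand.other_allele == ref.effect_allele:
            return -1, (STRAND_COMPLEMENTED if complemented else SIGN_FLIPPED), ""
    return 0, DROPPED, "incompatible alleles"


def harmonize(
    exposures: Sequence[SummaryStatsTable] | SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_window: tuple = DEFAULT_PALINDROME_WINDOW,
    mode: str = "univariable",
) -> HarmonizedDataset:
    """Align exposure and outcome records on a common effect allele.

    Parameters
    ----------
    exposures
        One table (univariable) or a sequence of K tables.
    palindrome_eaf_window
        Open interval around 0.5; a palindromic SNP whose effect-allele
        frequency falls inside it (in either study) is dropped as
        strand-ambiguous.
    mode
        ``"univariable"`` keeps only SNPs present in every table;
        ``"multivariable"`` keeps SNPs present in the outcome and at least
        one exposure, marking absent exposure records with beta 0 / SE +inf
        (the convention that an instrument need not associate with every
        risk factor).
    """
    if isinstance(exposures, SummaryStatsTable):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise HarmonizationError("at least one exposure table is required")
    if mode not in ("univariable", "multivariable"):
        raise ValueError(f"unknown mode {mode!r}")

    K = len(exposures)
    provenance: dict[str, tuple[str, str]] = {}
    drop_reasons: Counter = Counter()

    # candidate universe in outcome order (deterministic)
    kept_rows = []
    for snp in outcome.snp_ids:
        holders = [k for k, t in enumerate(exposures) if snp in t]
        if not holders:
            provenance[snp] = (DROPPED, "absent from all exposures")
            drop_reasons["absent from all exposures"] += 1
            continue
        if mode == "univariable" and len(holders) < K:
            provenance[snp] = (DROPPED, "absent from an exposure")
            drop_reasons["absent from an exposure"] += 1
            continue

        ref = exposures[holders[0]][snp]
        row_bx = np.zeros(K)
        row_sx = np.full(K, np.inf)
        row_px = np.full(K, np.nan)
        row_eafx = np.full(K, np.nan)
        failed = None
        actions = []
        for k in range(K):
            rec = exposures[k].get(snp)
            if rec is None:
                continue
            sign, action, reason = _align_to_reference(ref, rec, palindrome_eaf_window)
            if sign == 0:
                failed = reason
                break
            row_bx[k] = sign * rec.beta
            row_sx[k] = rec.se
            row_px[k] = rec.pval
            if rec.eaf is not None:
                row_eafx[k] = rec.eaf if sign == 1 else 1.0 - rec.eaf
            actions.append(action)
        if failed is not None:
            provenance[snp] = (DROPPED, failed)
            drop_reasons[failed] += 1
            continue

        orec = outcome[snp]
        sign, action, reason = _align_to_reference(ref, orec, palindrome_eaf_window)
        if sign == 0:
            provenance[snp] = (DROPPED, reason)
            drop_reasons[reason] += 1
            continue

        by = sign * orec.beta
        eafy = np.nan
        if orec.eaf is not None:
            eafy = orec.eaf if sign == 1 else 1.0 - orec.eaf
        provenance[snp] = (action, "")
        kept_rows.append(
            (snp, ref.effect_allele, ref.other_allele, row_bx, row_sx, row_px, row_eafx,
             by, orec.se, orec.pval, eafy)
        )

    if not kept_rows:
        detail = "; ".join(f"{r}: {c}" for r, c in drop_reasons.most_common())
        raise HarmonizationError(f"zero SNPs survived harmonization ({detail or 'empty input'})")

    if drop_reasons:
        logger.info("harmonization dropped %d SNP(s): %s",
                    sum(drop_reasons.values()), dict(drop_reasons))

    def _mode_n(table: SummaryStatsTable):
        ns = [r.n for r in table if r.n is not None]
        return int(np.median(ns)) if ns else None

    snp_ids = [r[0] for r in kept_rows]
    return HarmonizedDataset(
        snp_ids=snp_ids,
        exposure_ids=[t.trait_id for t in exposures],
        effect_allele=[r[1] for r in kept_rows],
        other_allele=[r[2] for r in kept_rows],
        bx=np.vstack([r[3] for r in kept_rows]),
        sx=np.vstack([r[4] for r in kept_rows]),
        pvals_x=np.vstack([r[5] for r in kept_rows]),
        eaf_x=np.vstack([r[6] for r in kept_rows]),
        by=np.array([r[7] for r in kept_rows]),
        sy=np.array([r[8] for r in kept_rows]),
        pvals_y=np.array([r[9] for r in kept_rows]),
        eaf_y=np.array([r[10] for r in kept_rows]),
        n_x=[_mode_n(t) for t in exposures],
        n_y=_mode_n(outcome),
        outcome_id=outcome.trait_id,
        outcome_type=outcome.trait_type,
        provenance=provenance,
    )


def find_proxies(
    target: str,
    candidates: SummaryStatsTable,
    ld: LdTable,
    r2_min: float = 0.8,
) -> str | None:
    """Best LD proxy for ``target`` among ``candidates``.

    Returns the candidate snp_id with maximal r² ≥ ``r2_min``; ties broken
    by smaller candidate p-value, then lexicographic snp_id.  ``None`` when
    no candidate qualifies (absence is a valid result).
    """
    best: tuple | None = None
    for rec in candidates:
        if rec.snp_id == target:
            continue
        r2 = ld.r2(target, rec.snp_id)
        if r2 < r2_min:
            continue
        key = (-r2, rec.pval, rec.snp_id)
        if best is None or key < best[0]:
            best = (key, rec.snp_id)
    return None if best is None else best[1]
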