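"""Instrument selection: genome-wide significance filter + greedy LD clumping.

Candidates below the significance threshold are ranked by p-value; the best
remaining candidate is kept and every remaining candidate correlated with it
above the r² ceiling is removed ("clumping").  Best-p-first is the unique
order-independent reading of keeping, within each correlated pair, the SNP
with the smaller association p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .sumstats_io import LdTable, SummaryStatsTable

logger = logging.getLogger("mrkit")

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_LD_R2_MAX = 0.001


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with the full decision log."""

    exposure_id: str
    snp_ids: list[str] = field(default_factory=list)
    #: snp_id -> "kept" | "removed-subthreshold" | "removed-ld-with:<snp>"
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"snp": s, "decision": d} for s, d in self.selection_log.items()],
            columns=["snp", "decision"],
        )


def select_instruments(
    table: SummaryStatsTable,
    ld: LdTable | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    ld_r2_max: float = DEFAULT_LD_R2_MAX,
) -> InstrumentSet:
    """Greedy best-p-first clumping at ``p_threshold`` and ``ld_r2_max``.

    A missing LD pair counts as r² = 0 (independent).  P-value ties break
    lexicographically by snp_id so the output is invariant to input row
    order.  An empty result is returned with a warning, not an error.
    """
    ld = ld or LdTable()
    log: dict[str, str] = {}
    candidates = []
    for rec in table:
        if rec.pval < p_threshold:
            candidates.append(rec)
        else:
            log[rec.snp_id] = "removed-subthreshold"

    candidates.sort(key=lambda r: (r.pval, r.snp_id))
    kept: list[str] = []
    remaining = candidates
    while remaining:
        best, rest = remaining[0], remaining[1:]
        kept.append(best.snp_id)
        log[best.snp_id] = "kept"
        remaining = []
        for rec in rest:
            if ld.r2(best.snp_id, rec.snp_id) > ld_r2_max:
                log[rec.snp_id] = f"removed-ld-with:{best.snp_id}"
            else:
                remaining.append(rec)

    if not kept:
        logger.warning("%s: no instruments at p < %g", table.trait_id, p_threshold)
    return InstrumentSet(exposure_id=table.trait_id, snp_ids=kept, selection_log=log)


def select_instruments_pooled(
    tables: list[SummaryStatsTable],
    ld: LdTable | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    ld_r2_max: float = DEFAULT_LD_R2_MAX,
) -> dict[str, InstrumentSet]:
    """Clump across the pooled candidate set of several exposures.

    Each SNP enters the pool with its smallest p-value over the exposures
    where it is significant; the clumped survivors are then attributed back
    to every exposure in which they reach ``p_threshold``.  This mirrors
    pruning pairwise LD "between all selected SNPs" rather than within each
    exposure separately; per-exposure clumping remains the default mode.
    """
    ld = ld or LdTable()
    best_p: dict[str, float] = {}
    for t in tables:
        for rec in t:
            if rec.pval < p_threshold:
                if rec.snp_id not in best_p or rec.pval < best_p[rec.snp_id]:
                    best_p[rec.snp_id] = rec.pval

    order = sorted(best_p, key=lambda s: (best_p[s], s))
    kept: list[str] = []
    removed: dict[str, str] = {}
    remaining = order
    while remaining:
        best, rest = remaining[0], remaining[1:]
        kept.append(best)
        remaining = []
        for s in rest:
            if ld.r2(best, s) > ld_r2_max:
                removed[s] = best
            else:
                remaining.append(s)

    kept_set = set(kept)
    out: dict[str, InstrumentSet] = {}
    for t in tables:
        log: dict[str, str] = {}
        snps: list[str] = []
        for rec in t:
            if rec.pval >= p_threshold:
                log[rec.snp_id] = "removed-subthreshold"
            elif rec.snp_id in kept_set:
                snps.append(rec.snp_id)
                log[rec.snp_id] = "kept"
            else:
                log[rec.snp_id] = f"removed-ld-with:{removed.get(rec.snp_id, '?')}"
        out[t.trait_id] = InstrumentSet(exposure_id=t.trait_id, snp_ids=snps, selection_log=log)
    return out
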