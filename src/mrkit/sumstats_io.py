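"""GWAS summary-statistics tables and LD tables: data model, readers, writers.

The unit of data is one SNP's association with one trait: effect allele,
other allele, effect-allele frequency, beta, standard error, p-value and
sample size.  Betas are on the log-odds scale for binary traits and in SD
units for continuous traits.  Files are tab- or comma-delimited text with a
header; gzip-compressed input is accepted transparently.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrkit")

VALID_ALLELES = frozenset("ACGT")

#: allele -> reverse-strand complement
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: unordered allele pairs that are their own strand complement
PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

#: canonical output column order for summary-statistics TSVs
CANONICAL_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

#: default input column map; users override for consortium-specific headers
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

REQUIRED_FIELDS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics or LD input."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait.

    ``eaf`` and ``n`` are optional (``None`` when the source GWAS does not
    report them); a missing ``eaf`` makes the record ineligible for
    palindromic strand resolution downstream.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> list[str]:
        """Return a list of hard-invariant violations (empty when valid)."""
        problems = []
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            problems.append("alleles must be single bases A/C/G/T")
        elif self.effect_allele == self.other_allele:
            problems.append("effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            problems.append("se must be finite and > 0")
        if not math.isfinite(self.beta):
            problems.append("beta must be finite")
        if not (0 < self.pval <= 1):
            problems.append("pval must lie in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            problems.append("eaf must lie strictly in (0, 1)")
        if self.n is not None and self.n <= 0:
            problems.append("n must be a positive integer")
        return problems

    def pval_is_consistent(self, factor: float = 2.0) -> bool:
        """Check p against the two-sided normal p implied by beta/se.

        Agreement within a multiplicative ``factor`` is accepted; failures
        are a validation warning, never an error (GWAS p-values frequently
        come from non-Wald tests or genomic-control-corrected statistics).
        """
        if self.se <= 0:
            return False
        implied = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
        if implied <= 0:  # underflow: z huge, any tiny reported p is fine
            return self.pval < 1e-300
        lo, hi = implied / factor, min(1.0, implied * factor)
        return lo <= self.pval <= hi

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS

    def flipped(self) -> "GwasRecord":
        """The same association expressed for the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "GwasRecord":
        """The same record with both alleles mapped to the opposite strand."""
        return replace(
            self,
            effect_allele=COMPLEMENT[self.effect_allele],
            other_allele=COMPLEMENT[self.other_allele],
        )


@dataclass
class SummaryStatsTable:
    """An ordered collection of :class:`GwasRecord` for one trait.

    ``snp_id`` is unique within a table; insertion order is preserved.
    """

    trait_id: str
    trait_type: str = "continuous"  # "continuous" | "binary"
    records: list[GwasRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"trait_type must be continuous or binary, got {self.trait_type!r}")
        self._index: dict[str, GwasRecord] = {}
        for rec in self.records:
            if rec.snp_id in self._index:
                raise SumstatsError(f"duplicate snp_id {rec.snp_id!r} in table {self.trait_id!r}")
            self._index[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> GwasRecord | None:
        return self._index.get(snp_id)

    def __getitem__(self, snp_id: str) -> GwasRecord:
        return self._index[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatsTable":
        """A new table containing the requested SNPs, in the requested order."""
        recs = [self._index[s] for s in snp_ids if s in self._index]
        return SummaryStatsTable(self.trait_id, self.trait_type, recs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LdTable:
    """Sparse symmetric pairwise r² lookup.

    A missing pair is treated as r² = 0 (the post-pruning independence
    convention); r²(i, i) = 1 is implied.
    """

    pairs: dict[frozenset, float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> frozenset:
        return frozenset((a, b))

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise SumstatsError(f"r² must lie in [0, 1], got {r2} for ({a}, {b})")
        if a == b:
            return
        key = self._key(a, b)
        # duplicate entries resolve to the maximum r² (conservative for pruning)
        self.pairs[key] = max(r2, self.pairs.get(key, 0.0))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _sniff_sep(path: str | Path) -> str:
    with _open_text(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
) -> SummaryStatsTable:
    """Read a summary-statistics table from a delimited text file.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row; ``.gz`` accepted.
    column_map
        Mapping from canonical field names (``snp``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to the
        column names in the file.  Defaults to the canonical names; no
        header sniffing is attempted, since silent mis-mapping is the
        dominant failure mode in MR tooling.

    Rows violating hard invariants (non-ACGT or identical alleles, se ≤ 0,
    p outside (0,1], eaf outside (0,1)) are dropped with a logged count.
    Missing required columns or zero surviving rows are fatal.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={cmap["snp"]: str},
                     float_precision="round_trip")

    missing = [f for f in REQUIRED_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise SumstatsError(f"{path}: missing required column(s) {missing} (after column_map)")

    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns

    records: list[GwasRecord] = []
    n_dropped = 0
    n_pval_warn = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            n_val = _parse_optional_float(row[cmap["n"]]) if has_n else None
            rec = GwasRecord(
                snp_id=str(row[cmap["snp"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pval=float(row[cmap["pval"]]),
                eaf=_parse_optional_float(row[cmap["eaf"]]) if has_eaf else None,
                n=int(n_val) if n_val is not None else None,
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if rec.validate():
            n_dropped += 1
            continue
        if not rec.pval_is_consistent():
            n_pval_warn += 1
        records.append(rec)

    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s), kept %d", path, n_dropped, len(records))
    if n_pval_warn:
        logger.warning(
            "%s: %d record(s) have p-values inconsistent with beta/se (normal approx, factor 2)",
            path, n_pval_warn,
        )
    if not records:
        raise SumstatsError(f"{path}: no valid summary-statistics rows")

    # unique snp_id enforced by the table constructor; drop later duplicates
    seen: set[str] = set()
    unique = []
    for rec in records:
        if rec.snp_id in seen:
            n_dropped += 1
            logger.warning("%s: duplicate snp_id %s, keeping first", path, rec.snp_id)
            continue
        seen.add(rec.snp_id)
        unique.append(rec)

    return SummaryStatsTable(trait_id or path.stem, trait_type, unique)


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table as TSV in canonical column order at full float precision.

    Missing optional fields (eaf, n) are emitted as empty cells, never "0".
    """
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for r in table.records:
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.effect_allele,
                    r.other_allele,
                    "" if r.eaf is None else repr(float(r.eaf)),
                    repr(float(r.beta)),
                    repr(float(r.se)),
                    repr(float(r.pval)),
                    "" if r.n is None else str(int(r.n)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ld_table(path: str | Path) -> LdTable:
    """Read a three-column (snp_a, snp_b, r2) pairwise LD file.

    The table is symmetric by construction; duplicate pairs keep the
    maximum r².  An r² outside [0, 1] is fatal.  An empty file yields a
    table on which every lookup returns 0.
    """
    path = Path(path)
    ld = LdTable()
    with _open_text(path) as fh:
        header = fh.readline()
        if not header:
            return ld
        sep = "\t" if header.count("\t") >= header.count(",") else ","
        first = header.rstrip("\n").split(sep)
        rows = fh.read().splitlines()
        # tolerate a missing header line: if the 3rd token parses as float, it is data
        try:
            ld.set(first[0], first[1], float(first[2]))
        except (IndexError, ValueError):
            pass
        for line in rows:
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 3:
                raise SumstatsError(f"{path}: malformed LD row {line!r}")
            ld.set(parts[0].strip(), parts[1].strip(), float(parts[2]))
    return ld


def write_ld_table(ld: LdTable, path: str | Path) -> None:
    lines = ["snp_a\tsnp_b\tr2"]
    for key in sorted(ld.pairs, key=sorted):
        a, b = sorted(key)
        lines.append(f"{a}\t{b}\t{ld.pairs[key]!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
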