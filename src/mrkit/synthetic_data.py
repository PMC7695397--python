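"""Synthetic two-sample MR summary statistics with known causal structure.

The generative model is the canonical linear structural model behind
summary-data MR: J independent SNPs (the post-LD-pruning regime) each carry
true effects b_j· on K exposures drawn from a zero-mean multivariate normal,
and a true outcome effect

    Σ_k θ_k · b_jk + α_j

where θ is the causal-effect vector and α_j is a direct (pleiotropic)
outcome effect present for a configurable fraction of SNPs.  Observed betas
add sampling noise with the standardized-trait GWAS standard error
SE = 1/sqrt(2·MAF·(1−MAF)·n), which is also the SE the records report.
Records can be emitted with swapped alleles (sign-negated) and/or
palindromic allele pairs to exercise harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .sumstats_io import GwasRecord, SummaryStatsTable, write_sumstats


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_dataset`.

    Defaults emulate the nine-risk-factor Alzheimer's-disease study design:
    nine exposures measured in large consortium GWAS (sample sizes of order
    10^5), an outcome GWAS of ~74k individuals, genome-wide-significant
    instruments plus sub-threshold decoys, and a small fraction of
    deliberately mis-oriented and palindromic records.
    """

    n_snps: int = 450
    n_exposures: int = 9
    #: true causal effects of exposures on the outcome (length K)
    theta: tuple = (0.25, -0.25, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    #: per-exposure SD of true SNP effects (scalar or length K)
    exposure_effect_scale: float = 0.04
    #: K×K correlation of true SNP effects across exposures (None = identity)
    exposure_corr: np.ndarray | None = None
    n_exp: int = 200_000
    n_out: int = 74_046
    maf_range: tuple = (0.05, 0.45)
    #: fraction of SNPs carrying a direct outcome effect α_j
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    #: fraction of SNPs assigned A/T or C/G allele pairs
    palindromic_frac: float = 0.2
    #: fraction of outcome records emitted with swapped alleles and negated beta
    flip_frac: float = 0.1
    #: fraction of SNPs whose true exposure effects are zero (instrument decoys
    #: that the genome-wide-significance filter must remove)
    decoy_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta = tuple(float(t) for t in self.theta)
        if len(self.theta) != self.n_exposures:
            raise ValueError("theta must have length n_exposures")
        if not all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")
        for name in ("pleiotropy_frac", "palindromic_frac", "flip_frac", "decoy_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.exposure_corr is not None:
            C = np.asarray(self.exposure_corr, dtype=float)
            if C.shape != (self.n_exposures, self.n_exposures):
                raise ValueError("exposure_corr must be K×K")
            if not np.allclose(C, C.T):
                raise ValueError("exposure_corr must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("exposure_corr must be positive semi-definite")
            self.exposure_corr = C

    def to_yaml(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        if d["exposure_corr"] is not None:
            d["exposure_corr"] = np.asarray(d["exposure_corr"]).tolist()
        d["theta"] = list(d["theta"])
        d["maf_range"] = list(d["maf_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    theta: np.ndarray  # (K,)
    b: np.ndarray  # (J, K) true SNP-exposure effects
    alpha: np.ndarray  # (J,) true direct outcome effects
    maf: np.ndarray  # (J,)
    snp_ids: list[str] = field(default_factory=list)
    flipped: np.ndarray | None = None  # (J,) bool: outcome record emitted swapped
    palindromic: np.ndarray | None = None  # (J,) bool

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.b, columns=[f"b_exp{k + 1}" for k in range(self.b.shape[1])])
        df.insert(0, "snp", self.snp_ids)
        df["alpha"] = self.alpha
        df["maf"] = self.maf
        df["flipped"] = self.flipped
        df["palindromic"] = self.palindromic
        return df


#: non-palindromic unordered allele pairs
_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PAL_PAIRS = [("A", "T"), ("C", "G")]


def _se_standardized(maf: np.ndarray, n: float) -> np.ndarray:
    """Standard error of a per-allele effect on a standardized trait."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[SummaryStatsTable], SummaryStatsTable, SimTruth]:
    """Simulate K exposure tables, one outcome table, and the ground truth.

    The seed fully determines the output; per-trait noise uses independent
    child streams spawned from the master seed so adding an exposure does
    not perturb the others.
    """
    cfg = config
    J, K = cfg.n_snps, cfg.n_exposures
    master = np.random.default_rng(cfg.seed)
    # independent child streams: structure, per-trait noise, bookkeeping
    streams = master.spawn(K + 3)
    rng_struct, rng_out, rng_book = streams[0], streams[1], streams[2]
    rng_exp = streams[3:]

    maf = rng_struct.uniform(*cfg.maf_range, size=J)
    scale = np.broadcast_to(np.atleast_1d(np.asarray(cfg.exposure_effect_scale, float)), (K,))
    corr = np.eye(K) if cfg.exposure_corr is None else np.asarray(cfg.exposure_corr, float)
    cov = np.diag(scale) @ corr @ np.diag(scale)
    b = rng_struct.multivariate_normal(np.zeros(K), cov, size=J, method="cholesky")

    n_decoy = int(round(cfg.decoy_frac * J))
    decoy = np.zeros(J, dtype=bool)
    if n_decoy:
        decoy[rng_struct.choice(J, size=n_decoy, replace=False)] = True
        b[decoy] = 0.0

    alpha = np.zeros(J)
    n_pleio = int(round(cfg.pleiotropy_frac * J))
    if n_pleio:
        idx = rng_struct.choice(J, size=n_pleio, replace=False)
        alpha[idx] = rng_struct.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)

    by_true = b @ np.asarray(cfg.theta) + alpha

    snp_ids = [f"rs{100000 + j}" for j in range(J)]
    n_pal = int(round(cfg.palindromic_frac * J))
    palindromic = np.zeros(J, dtype=bool)
    if n_pal:
        palindromic[rng_book.choice(J, size=n_pal, replace=False)] = True
    pair_choice = rng_book.integers(0, 4, size=J)
    pal_choice = rng_book.integers(0, 2, size=J)

    n_flip = int(round(cfg.flip_frac * J))
    flipped = np.zeros(J, dtype=bool)
    if n_flip:
        flipped[rng_book.choice(J, size=n_flip, replace=False)] = True

    se_x = _se_standardized(maf, cfg.n_exp)  # (J,) same formula per exposure
    se_y = _se_standardized(maf, cfg.n_out)

    def allele_pair(j: int) -> tuple[str, str]:
        if palindromic[j]:
            return _PAL_PAIRS[pal_choice[j]]
        return _NONPAL_PAIRS[pair_choice[j]]

    exposures: list[SummaryStatsTable] = []
    for k in range(K):
        bx_obs = b[:, k] + rng_exp[k].normal(0.0, se_x)
        px = _two_sided_p(bx_obs, se_x)
        recs = [
            GwasRecord(
                snp_id=snp_ids[j],
                effect_allele=allele_pair(j)[0],
                other_allele=allele_pair(j)[1],
                beta=float(bx_obs[j]),
                se=float(se_x[j]),
                pval=float(px[j]),
                eaf=float(maf[j]),
                n=cfg.n_exp,
            )
            for j in range(J)
        ]
        exposures.append(SummaryStatsTable(f"exposure_{k + 1}", "continuous", recs))

    by_obs = by_true + rng_out.normal(0.0, se_y)
    py = _two_sided_p(by_obs, se_y)
    out_recs = []
    for j in range(J):
        ea, oa = allele_pair(j)
        beta, eaf = float(by_obs[j]), float(maf[j])
        if flipped[j]:
            ea, oa, beta, eaf = oa, ea, -beta, 1.0 - eaf
        out_recs.append(
            GwasRecord(
                snp_id=snp_ids[j],
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=float(se_y[j]),
                pval=float(py[j]),
                eaf=eaf,
                n=cfg.n_out,
            )
        )
    outcome = SummaryStatsTable("outcome", "binary", out_recs)

    truth = SimTruth(
        theta=np.asarray(cfg.theta),
        b=b,
        alpha=alpha,
        maf=maf,
        snp_ids=snp_ids,
        flipped=flipped,
        palindromic=palindromic,
    )
    return exposures, outcome, truth


def write_dataset(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    truth: SimTruth,
    config: SimConfig,
    outdir: str | Path,
) -> None:
    """Dump a simulated dataset as sumstats TSVs + truth TSV + config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for table in exposures:
        write_sumstats(table, outdir / f"{table.trait_id}.tsv")
    write_sumstats(outcome, outdir / "outcome.tsv")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "sim_config.yaml")


def make_toy_fixture() -> tuple[list[SummaryStatsTable], SummaryStatsTable, SimTruth]:
    """A deterministic 20-SNP, 3-exposure dataset used in docs and tests.

    Hand-chosen structure: strong instruments (|z| ≫ 5), true causal
    effects θ = (0.5, −0.2, 0), at least two palindromic SNPs and two
    allele-swapped outcome records, no pleiotropy, modest noise.
    """
    cfg = SimConfig(
        n_snps=20,
        n_exposures=3,
        theta=(0.5, -0.2, 0.0),
        exposure_effect_scale=0.08,
        n_exp=300_000,
        n_out=150_000,
        maf_range=(0.1, 0.4),
        palindromic_frac=0.2,  # 4 SNPs
        flip_frac=0.15,  # 3 records
        decoy_frac=0.0,
        seed=20240917,
    )
    return simulate_dataset(cfg)
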