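"""Full-workflow orchestration: one call runs the whole analysis.

Stages, in order: per-exposure instrument selection → allele harmonization
→ univariable estimators (IVW fixed effects, maximum likelihood, weighted
median) → MR-Egger pleiotropy test → bi-directional MR and Steiger
directionality → multivariable IVW → Bayesian model averaging.  Each stage
writes one TSV; a structured run log records every threshold, seed and
drop count actually used.  Effects are labeled significant at the
Bonferroni-corrected level alpha/n_tests, suggestive between that and
alpha (strict inequalities at both boundaries), and null otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .harmonization import (DEFAULT_PALINDROME_WINDOW, HarmonizationError,
                            harmonize)
from .iv_selection import (DEFAULT_LD_R2_MAX, DEFAULT_P_THRESHOLD,
                           select_instruments)
from .mr_bma import BmaConfig, run_bma
from .mr_estimators import (ESTIMATORS, METHOD_LABELS, EstimationError,
                            mr_egger, weighted_median)
from .mvmr import mvmr_ivw
from .directionality import bidirectional_mr, steiger_test
from .sumstats_io import LdTable, SummaryStatsTable, SumstatsError, read_ld_table, read_sumstats

logger = logging.getLogger("mrkit")

# exit-code classes for the CLI
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_NUMERIC_ERROR = 4


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one full pipeline run depends on."""

    exposure_paths: list = field(default_factory=list)
    outcome_path: str = ""
    ld_path: str | None = None
    column_map: dict | None = None
    p_threshold: float = DEFAULT_P_THRESHOLD
    ld_r2_max: float = DEFAULT_LD_R2_MAX
    palindrome_eaf_window: tuple = DEFAULT_PALINDROME_WINDOW
    proxy_r2_min: float = 0.8
    estimators: tuple = ("ivw", "ml", "wm")
    bma: BmaConfig = field(default_factory=BmaConfig)
    alpha_bonferroni: float = 0.05
    n_tests: int | None = None  # None: number of exposures supplied
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "mr_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        bma = BmaConfig(**raw.pop("bma", {}))
        try:
            cfg = cls(bma=bma, **raw)
        except TypeError as exc:
            raise ConfigError(f"invalid run config: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.exposure_paths or not self.outcome_path:
            raise ConfigError("exposure_paths and outcome_path are required")
        if self.n_tests is not None and self.n_tests < 1:
            raise ConfigError("n_tests must be >= 1")
        for p in [*self.exposure_paths, self.outcome_path,
                  *( [self.ld_path] if self.ld_path else [] )]:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


def classify_significance(pval: float, alpha: float = 0.05, n_tests: int = 1) -> str:
    """Bonferroni-style label: 'significant' | 'suggestive' | 'null'.

    Strict inequalities at both boundaries: significant iff
    p < alpha/n_tests, suggestive iff alpha/n_tests ≤ p < alpha.
    """
    if not (0.0 < pval <= 1.0):
        raise ValueError(f"pval must lie in (0, 1], got {pval}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if pval < alpha / n_tests:
        return "significant"
    if pval < alpha:
        return "suggestive"
    return "null"


def _estimate_row(exposure_id: str, est, alpha: float, n_tests: int) -> dict:
    return {
        "Exposure": exposure_id,
        "Methods": METHOD_LABELS.get(est.method, est.method),
        "nsnp": est.n_snp,
        "OR": est.or_,
        "OR_lci95": est.or_lci95,
        "OR_uci95": est.or_uci95,
        "P_value": est.pval,
        "significance": classify_significance(est.pval, alpha, n_tests),
    }


def run_full_pipeline_tables(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LdTable | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run every analysis stage on in-memory tables; return the bundle.

    The returned dict maps stage names to pandas DataFrames (plus the
    structured ``log`` dict); :func:`run_full_pipeline` adds file I/O.
    """
    cfg = config or RunConfig(exposure_paths=["<memory>"], outcome_path="<memory>")
    ld = ld or LdTable()
    n_tests = cfg.n_tests or len(exposures)
    alpha = cfg.alpha_bonferroni
    log: dict = {
        "p_threshold": cfg.p_threshold,
        "ld_r2_max": cfg.ld_r2_max,
        "palindrome_eaf_window": list(cfg.palindrome_eaf_window),
        "proxy_r2_min": cfg.proxy_r2_min,
        "alpha_bonferroni": alpha,
        "n_tests": n_tests,
        "bonferroni_threshold": alpha / n_tests,
        "seed": cfg.seed,
        "n_boot": cfg.n_boot,
        "bma_prior_inclusion": cfg.bma.prior_inclusion,
        "bma_prior_scale": cfg.bma.prior_scale,
        "estimators": list(cfg.estimators),
        "exposures": {},
    }

    # stage 1-2: instruments + per-exposure harmonization
    selected: dict[str, SummaryStatsTable] = {}
    harmonized: dict[str, object] = {}
    for table in exposures:
        iv = select_instruments(table, ld, cfg.p_threshold, cfg.ld_r2_max)
        exp_log = {"n_candidates": len(table), "n_instruments": len(iv)}
        if not iv.snp_ids:
            logger.warning("%s: skipped (no instruments)", table.trait_id)
            exp_log["n_harmonized"] = 0
            log["exposures"][table.trait_id] = exp_log
            continue
        sub = table.subset(iv.snp_ids)
        try:
            ds = harmonize(sub, outcome, cfg.palindrome_eaf_window)
        except HarmonizationError as exc:
            logger.warning("%s: harmonization failed (%s)", table.trait_id, exc)
            exp_log["n_harmonized"] = 0
            log["exposures"][table.trait_id] = exp_log
            continue
        exp_log["n_harmonized"] = ds.n_snps
        exp_log["n_dropped"] = len(iv.snp_ids) - ds.n_snps
        log["exposures"][table.trait_id] = exp_log
        selected[table.trait_id] = sub
        harmonized[table.trait_id] = ds

    if not harmonized:
        raise HarmonizationError("no exposure yielded usable harmonized instruments")

    # stage 3: univariable estimators (main results table)
    uni_rows, egger_rows, forest_rows = [], [], []
    for trait_id, ds in harmonized.items():
        bx, sx = ds.bx[:, 0], ds.sx[:, 0]
        for key in cfg.estimators:
            fn = ESTIMATORS[key]
            kwargs = {"n_boot": cfg.n_boot, "seed": cfg.seed} if fn is weighted_median else {}
            try:
                est = fn(bx, sx, ds.by, ds.sy, **kwargs)
            except EstimationError as exc:
                logger.warning("%s %s: %s", trait_id, key, exc)
                continue
            row = _estimate_row(trait_id, est, alpha, n_tests)
            uni_rows.append(row)
            forest_rows.append({k: row[k] for k in
                                ("Exposure", "Methods", "OR", "OR_lci95", "OR_uci95")})
        # stage 4: Egger pleiotropy test
        try:
            egg = mr_egger(bx, sx, ds.by, ds.sy)
            egger_rows.append({
                "Exposure": trait_id,
                "Egger_intercept": egg.intercept,
                "se": egg.intercept_se,
                "pvalue": egg.intercept_pval,
            })
        except EstimationError as exc:
            logger.warning("%s egger: %s", trait_id, exc)

    # stage 5: bi-directional MR + Steiger
    bidir_rows, steiger_rows = [], []
    for table in exposures:
        if table.trait_id not in harmonized:
            continue
        ds = harmonized[table.trait_id]
        st = steiger_test(ds)
        steiger_rows.append({
            "Exposure": table.trait_id,
            "snp_r2.exposure": st.r2_exposure,
            "snp_r2.outcome": st.r2_outcome,
            "Correct_causal_direction": st.correct_direction,
            "Steiger_pvalue": st.format_pval(),
        })
        both = bidirectional_mr(table, outcome, ld, cfg.p_threshold, cfg.ld_r2_max,
                                cfg.palindrome_eaf_window, cfg.n_boot, cfg.seed)
        for direction, ests in both.items():
            for est in ests:
                bidir_rows.append({
                    "direction": direction,
                    "Exposure": table.trait_id if direction == "forward" else outcome.trait_id,
                    "Outcome": outcome.trait_id if direction == "forward" else table.trait_id,
                    "Methods": METHOD_LABELS.get(est.method, est.method),
                    "nsnp": est.n_snp,
                    "OR": est.or_,
                    "OR_lci95": est.or_lci95,
                    "OR_uci95": est.or_uci95,
                    "pvalue": est.pval,
                })

    # stage 6: multivariable IVW on the instrument union
    mvmr_rows = []
    mvmr_est = None
    if len(harmonized) >= 2:
        union_tables = [selected[t] for t in harmonized]
        try:
            joint = harmonize(union_tables, outcome, cfg.palindrome_eaf_window,
                              mode="multivariable")
            mvmr_est = mvmr_ivw(joint)
            for k, trait in enumerate(mvmr_est.exposure_ids):
                mvmr_rows.append({
                    "Exposure": trait,
                    "nsnp": mvmr_est.n_snp,
                    "OR": mvmr_est.or_[k],
                    "OR_lci95": mvmr_est.or_lci95[k],
                    "OR_uci95": mvmr_est.or_uci95[k],
                    "P_value": mvmr_est.pval[k],
                    "significance": classify_significance(mvmr_est.pval[k], alpha, n_tests),
                })
            log["mvmr_min_singular_value"] = mvmr_est.min_singular_value
        except (EstimationError, HarmonizationError) as exc:
            logger.warning("multivariable IVW skipped: %s", exc)

    # stage 7: MR-BMA ranking
    bma_a_rows, bma_b_rows = [], []
    if len(harmonized) >= 2:
        joint = harmonize([selected[t] for t in harmonized], outcome,
                          cfg.palindrome_eaf_window, mode="multivariable")
        bma = run_bma(joint, cfg.bma)
        for rank, k in enumerate(bma.ranking, start=1):
            bma_a_rows.append({
                "rank": rank,
                "Risk factor": bma.factor_ids[k],
                "MIP": bma.mip[k],
                "Model averaged causal estimate": bma.mace[k],
            })
        for subset, pp, _ in bma.top_models(10):
            bma_b_rows.append({
                "Risk factors combination": ",".join(bma.factor_ids[k] for k in subset),
                "Posterior probability": pp,
            })

    return {
        "univariable": pd.DataFrame(uni_rows),
        "egger": pd.DataFrame(egger_rows),
        "bidirectional": pd.DataFrame(bidir_rows),
        "steiger": pd.DataFrame(steiger_rows),
        "mvmr": pd.DataFrame(mvmr_rows),
        "bma_factors": pd.DataFrame(bma_a_rows),
        "bma_models": pd.DataFrame(bma_b_rows),
        "forest": pd.DataFrame(forest_rows),
        "mvmr_estimate": mvmr_est,
        "log": log,
    }


OUTPUT_FILES = {
    "univariable": "univariable_mr.tsv",
    "egger": "egger_pleiotropy.tsv",
    "bidirectional": "bidirectional_mr.tsv",
    "steiger": "steiger_directionality.tsv",
    "mvmr": "mvmr_ivw.tsv",
    "bma_factors": "bma_factor_ranking.tsv",
    "bma_models": "bma_model_posteriors.tsv",
    "forest": "forest_plot_data.tsv",
}


def run_full_pipeline(config: RunConfig) -> dict:
    """Load inputs from ``config`` paths, run all stages, write all TSVs."""
    config.validate()
    exposures = [read_sumstats(p, config.column_map) for p in config.exposure_paths]
    outcome = read_sumstats(config.outcome_path, config.column_map, trait_type="binary")
    ld = read_ld_table(config.ld_path) if config.ld_path else LdTable()

    bundle = run_full_pipeline_tables(exposures, outcome, ld, config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, fname in OUTPUT_FILES.items():
        bundle[key].to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
    cfg_dump = asdict(config)
    cfg_dump.pop("outdir", None)  # the log already lives inside outdir
    cfg_dump["palindrome_eaf_window"] = list(cfg_dump["palindrome_eaf_window"])
    cfg_dump["estimators"] = list(cfg_dump["estimators"])
    (outdir / "run_log.yaml").write_text(
        yaml.safe_dump({"config": cfg_dump, "run": bundle["log"]}, sort_keys=True),
        encoding="utf-8",
    )
    return bundle
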