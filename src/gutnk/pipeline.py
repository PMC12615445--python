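"""End-to-end analysis: feature assembly, scoring, association and survival
for a cohort, plus the file-level ``run_pipeline`` that chains every stage
into one reproducible run directory.

The healthy-donor (HD) subjects always define the reference distribution;
scores for every subject (HD included) are computed against it.  Survival
stages are restricted to pre-treatment subjects not lost to follow-up,
mirroring the prognostic design the package implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .association import (PRINTED_MODELS, fit_logistic, roc_auc,
                          spearman_correlation)
from .compositional import TaxaCountTable, clr_transform, ratio_panel
from .diversity import alpha_diversity_table
from .scoring import (BinRule, dysbiosis_scores, exhaustion_scores,
                      fit_reference)
from .survival import (km_estimate, logrank_test, median_survival,
                       stratify_by_cutoff)
from .synthetic import Cohort, apply_loss_to_followup, default_config, generate_cohort

__all__ = [
    "DEFAULT_DYSBIOSIS_TAXA",
    "ScoringConfig",
    "RunConfig",
    "compute_features",
    "score_cohort",
    "associate_scores",
    "survival_analysis",
    "run_pipeline",
]

logger = logging.getLogger("gutnk")

# Taxa whose CLR abundance enters the dysbiosis score by default: genera
# expanded or depleted in disease per differential-abundance analysis.
DEFAULT_DYSBIOSIS_TAXA = (
    "Prevotella", "Escherichia-Shigella", "Ruminococcus",
    "Christensenellaceae R-7", "Phascolarctobacterium", "Faecalibacterium",
)

# The four alpha metrics entering the dysbiosis score.
DYSBIOSIS_ALPHA = ("shannon", "pielou", "simpson", "strong")


@dataclass(frozen=True)
class ScoringConfig:
    cut_lo: float = 66.7
    cut_hi: float = 90.0
    pseudocount: float = 0.5
    log_base: float = 2.0
    exhaustion_mode: str = "one_sided"
    dysbiosis_mode: str = "two_sided"
    dysbiosis_taxa: Sequence[str] = DEFAULT_DYSBIOSIS_TAXA
    dysbiosis_aggregate: str = "sum"


def compute_features(taxa: TaxaCountTable, cfg: ScoringConfig | None = None
                     ) -> pd.DataFrame:
    """Per-subject microbiota features: alpha metrics, dysbiosis-taxa CLR
    abundances, and the five-ratio panel."""
    cfg = cfg or ScoringConfig()
    alpha = alpha_diversity_table(taxa.counts, log_base=cfg.log_base)
    clr = clr_transform(taxa, pseudocount=cfg.pseudocount)
    clr_cols = {f"clr:{t}": clr[taxa.resolve(t)] for t in cfg.dysbiosis_taxa}
    ratios = ratio_panel(taxa, pseudocount=cfg.pseudocount)
    return pd.concat([alpha, pd.DataFrame(clr_cols), ratios], axis=1)


def _dysbiosis_panel(cfg: ScoringConfig) -> list[str]:
    return list(DYSBIOSIS_ALPHA) + [f"clr:{t}" for t in cfg.dysbiosis_taxa]


def score_cohort(cohort: Cohort, cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Exhaustion and dysbiosis scores for every subject of a cohort.

    Returns one row per subject: ``s_dim``, ``s_bright``, ``global_score``,
    ``dysbiosis_score``, the microbiota features and the NK panel columns,
    ready for association and survival stages.
    """
    cfg = cfg or ScoringConfig()
    taxa = TaxaCountTable(counts=cohort.taxa, taxonomy=cohort.taxonomy)
    features = compute_features(taxa, cfg)
    hd = cohort.metadata.index[cohort.metadata["group"] == "HD"]
    if len(hd) < 2:
        raise ValueError("need at least two HD subjects to fit the reference")

    panel_ref = fit_reference(cohort.nk_panel.loc[hd])
    exh = exhaustion_scores(cohort.nk_panel, panel_ref,
                            BinRule(cfg.exhaustion_mode, cfg.cut_lo, cfg.cut_hi))

    dys_panel = _dysbiosis_panel(cfg)
    dys_ref = fit_reference(features.loc[hd, dys_panel])
    dys = dysbiosis_scores(features[dys_panel], dys_ref,
                           BinRule(cfg.dysbiosis_mode, cfg.cut_lo, cfg.cut_hi),
                           aggregate=cfg.dysbiosis_aggregate)

    return pd.concat([exh, dys, features, cohort.nk_panel], axis=1)


def associate_scores(scores: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Correlations, refit risk models and AUCs on a scored cohort."""
    out: dict = {}
    rho, p = spearman_correlation(scores["dysbiosis_score"], scores["global_score"])
    out["spearman"] = {"dysbiosis_vs_global": {"rho": rho, "p": p}}
    for subset_col in ("s_dim", "s_bright"):
        r, pv = spearman_correlation(scores["dysbiosis_score"], scores[subset_col])
        out["spearman"][f"dysbiosis_vs_{subset_col}"] = {"rho": r, "p": pv}

    # cervical-cancer risk: HD vs pre-treatment, printed model features
    cc_mask = metadata["group"].isin(["HD", "CC_pre"])
    labels = (metadata.loc[cc_mask, "group"] == "CC_pre").astype(int)
    model = PRINTED_MODELS["cc_risk_2var"]
    feats = pd.DataFrame({
        "PD-1|CD56bright": scores.loc[cc_mask, "PD-1|CD56bright"],
        "Escherichia/Ruminococcus": scores.loc[cc_mask, "Escherichia/Ruminococcus"],
    })
    out["cc_risk"] = {
        "printed_odds_ratios": model.odds_ratios(),
        "auc_printed_features": roc_auc(
            feats.to_numpy() @ np.array(list(model.coefficients.values())),
            labels.to_numpy()),
    }
    refit = fit_logistic(feats, labels.to_numpy(), name="cc_risk_refit")
    out["cc_risk"]["refit"] = {
        "intercept": refit.intercept,
        "coefficients": dict(refit.coefficients),
        "odds_ratios": refit.odds_ratios(),
        "converged": refit.converged,
    }
    return out


def survival_analysis(scores: pd.DataFrame, metadata: pd.DataFrame,
                      marker: str, marker2: str | None = None) -> dict:
    """Cutoff-stratified KM / log-rank analysis on evaluable pre-treatment
    subjects; optional second marker restricts to concordant extremes."""
    from .survival import combined_strata

    evaluable = metadata[(metadata["group"] == "CC_pre")
                         & (metadata["lost_to_followup"] == 0)]
    if evaluable.empty:
        raise ValueError("no evaluable pre-treatment subjects")
    labels = evaluable["event"].to_numpy(dtype=int)
    values = scores.loc[evaluable.index, marker]
    strata, cutoff = stratify_by_cutoff(values, labels)
    result: dict = {"marker": marker, "cutoff": cutoff,
                    "n_evaluable": int(len(evaluable))}

    if marker2 is not None:
        strata2, cutoff2 = stratify_by_cutoff(scores.loc[evaluable.index, marker2], labels)
        joint = combined_strata(strata, strata2)
        result.update({"marker2": marker2, "cutoff2": cutoff2,
                       "n_concordant": int(len(joint))})
        hi_ids = joint.index[joint == "high/high"]
        lo_ids = joint.index[joint == "low/low"]
    else:
        hi_ids = strata.index[strata == "high"]
        lo_ids = strata.index[strata == "low"]

    if len(hi_ids) == 0 or len(lo_ids) == 0:
        raise ValueError("one stratum is empty; cannot compare survival")
    hi = evaluable.loc[hi_ids]
    lo = evaluable.loc[lo_ids]
    variant = "mantel-haenszel" if marker2 is not None else "oe"
    lr = logrank_test(hi["time_months"], hi["event"],
                      lo["time_months"], lo["event"], hr_variant=variant)
    km_hi = km_estimate(hi["time_months"], hi["event"])
    km_lo = km_estimate(lo["time_months"], lo["event"])
    result.update({
        "log_rank": {"chi_square": lr.chi_square, "p": lr.p_value,
                     "hr": lr.hazard_ratio, "hr_ci": [lr.ci_lower, lr.ci_upper],
                     "variant": lr.variant},
        "high": {"n": int(len(hi)), "deaths": int(hi["event"].sum()),
                 "median_survival": median_survival(km_hi)},
        "low": {"n": int(len(lo)), "deaths": int(lo["event"].sum()),
                "median_survival": median_survival(km_lo)},
    })
    return result


@dataclass
class RunConfig:
    """Full-pipeline configuration; simulated inputs when paths are None."""

    outdir: Path
    seed: int = 0
    taxa_path: Path | None = None
    taxonomy_path: Path | None = None
    panel_path: Path | None = None
    metadata_path: Path | None = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    survival_markers: Sequence[str] = ("TIGIT+TIM-3|CD56bright", "Proteobacteria/Firmicutes")
    n_lost_to_followup: int = 4


def run_pipeline(config: RunConfig) -> Path:
    """Simulate (or load), score, associate and run survival; write a run
    directory with scores.tsv, assoc.json, survival.json and a log file."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("gutnk pipeline start; seed=%d", config.seed)
        paths = (config.taxa_path, config.panel_path, config.metadata_path)
        if any(p is not None for p in paths) and not all(p is not None for p in paths):
            raise ValueError("provide taxa, panel and metadata paths together, or none")
        if config.taxa_path is None:
            cohort = generate_cohort(default_config(seed=config.seed))
            cohort = apply_loss_to_followup(cohort, config.n_lost_to_followup,
                                            seed=config.seed + 1)
            gio.write_taxa_table(cohort.taxa, outdir / "taxa.tsv", seed=config.seed)
            gio.write_taxonomy(cohort.taxonomy, outdir / "taxonomy.tsv")
            gio.write_nk_panel(cohort.nk_panel, outdir / "nk_panel.csv", seed=config.seed)
            gio.write_metadata(cohort.metadata, outdir / "metadata.tsv", seed=config.seed)
            logger.info("simulated cohort: %d subjects", len(cohort.subjects))
        else:
            taxonomy = gio.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else {}
            taxa = gio.read_taxa_table(config.taxa_path, taxonomy)
            panel = gio.read_nk_panel(config.panel_path)
            metadata = gio.read_metadata(config.metadata_path)
            from .synthetic import Cohort, CohortConfig
            cohort = Cohort(taxa=taxa.counts, taxonomy=dict(taxonomy),
                            nk_panel=panel.loc[taxa.counts.index],
                            metadata=metadata.loc[taxa.counts.index],
                            config=CohortConfig())
            logger.info("loaded cohort: %d subjects", len(cohort.subjects))

        scores = score_cohort(cohort, config.scoring)
        with open(outdir / "scores.tsv", "w", encoding="utf-8") as fh:
            fh.write(gio.provenance_header(config.seed, {"config": gio.config_hash(
                {"cut_lo": config.scoring.cut_lo, "cut_hi": config.scoring.cut_hi,
                 "pseudocount": config.scoring.pseudocount})}))
            scores.to_csv(fh, sep="\t")
        logger.info("scored %d subjects", len(scores))

        assoc = associate_scores(scores, cohort.metadata)
        gio.write_json(assoc, outdir / "assoc.json")
        logger.info("association done; rho=%.3f",
                    assoc["spearman"]["dysbiosis_vs_global"]["rho"])

        surv: dict = {}
        for marker in config.survival_markers:
            try:
                surv[marker] = survival_analysis(scores, cohort.metadata, marker)
            except ValueError as exc:
                surv[marker] = {"error": str(exc)}
        if len(config.survival_markers) >= 2:
            m1, m2 = config.survival_markers[:2]
            try:
                surv[f"{m1} & {m2}"] = survival_analysis(scores, cohort.metadata, m1, m2)
            except ValueError as exc:
                surv[f"{m1} & {m2}"] = {"error": str(exc)}
        gio.write_json(surv, outdir / "survival.json")
        logger.info("pipeline complete")
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
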