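"""Synthetic cohort generator with the statistical structure the analysis
assumes.

The generator emulates a three-group cross-sectional design — healthy donors
(HD), newly diagnosed cervical-cancer patients (CC_pre) and patients after
radio-chemotherapy (CC_post), default sizes 28/27/22 — producing three
aligned tables:

* a genus-level count table drawn from a log-normal relative-abundance
  vector pushed through a multinomial at fixed sequencing depth (default
  40,000 reads, matching typical denoised-ASV depth), with per-group
  log-fold shifts planted on disease-associated genera (Prevotella and
  Escherichia-Shigella enriched in disease, Ruminococcus and
  Christensenellaceae depleted, Phascolarctobacterium strongly enriched
  after treatment);
* an NK checkpoint panel of percent-positive values for six inhibitory
  receptors on CD56dim and CD56bright subsets, plus co-expression pairs and
  subset frequencies, with additive group shifts and Gaussian noise, clamped
  to [0, 100];
* subject metadata with group label, latent severity, and exponential
  survival administratively censored at a 15-month horizon.

A single latent severity factor per subject (standard normal) shifts both
the dysbiosis-direction taxa and the checkpoint percentages (strength
``latent_coupling``) and scales the death hazard (``survival_link``), which
is the minimal mechanism producing the positive dysbiosis-exhaustion
correlation and the survival association the analysis is designed to
detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .scoring import CHECKPOINT_MARKERS, NK_SUBSETS

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "apply_loss_to_followup",
    "default_config",
    "GROUPS",
    "COEXPRESSION_PAIRS",
    "PANEL_MARKERS",
    "DEFAULT_TAXONOMY",
]

GROUPS = ("HD", "CC_pre", "CC_post")

COEXPRESSION_PAIRS = (
    "PD-1+BTLA", "PD-1+LAG-3", "PD-1+TIM-3", "PD-1+TIGIT",
    "TIGIT+TIM-3", "NKG2A+TIGIT",
)
# "frequency" is the subset's share of total NK cells, carried alongside the
# checkpoint percentages because the risk models consume it.
PANEL_MARKERS = CHECKPOINT_MARKERS + COEXPRESSION_PAIRS + ("frequency",)

# Genus panel: the named disease-informative taxa plus filler genera, with a
# phylum map spanning the five dominant gut phyla.
DEFAULT_TAXONOMY: dict[str, str] = {
    "Prevotella": "Bacteroidota",
    "Bacteroides": "Bacteroidota",
    "Parabacteroides": "Bacteroidota",
    "Escherichia-Shigella": "Proteobacteria",
    "Bilophila": "Proteobacteria",
    "Ruminococcus": "Firmicutes",
    "Christensenellaceae R-7": "Firmicutes",
    "Faecalibacterium": "Firmicutes",
    "Roseburia": "Firmicutes",
    "Phascolarctobacterium": "Firmicutes",
    "Erysipelotrichaceae UCG-003": "Firmicutes",
    "Streptococcus": "Firmicutes",
    "Blautia": "Firmicutes",
    "Subdoligranulum": "Firmicutes",
    "Anaerostipes": "Firmicutes",
    "Lachnospiraceae": "Firmicutes",
    "Oscillibacter": "Firmicutes",
    "Bifidobacterium": "Actinobacteriota",
    "Collinsella": "Actinobacteriota",
    "Akkermansia": "Verrucomicrobiota",
}

# HD-baseline mean log relative abundance (natural log of an unnormalised
# weight; normalisation happens per sample).  Levels approximate healthy gut
# genus-level relative abundances.
_BASELINE_LOG_ABUNDANCE: dict[str, float] = {
    "Faecalibacterium": np.log(0.155),
    "Bacteroides": np.log(0.086),
    "Prevotella": np.log(0.037),
    "Blautia": np.log(0.040),
    "Roseburia": np.log(0.023),
    "Subdoligranulum": np.log(0.025),
    "Ruminococcus": np.log(0.0135),
    "Lachnospiraceae": np.log(0.060),
    "Bifidobacterium": np.log(0.025),
    "Collinsella": np.log(0.008),
    "Anaerostipes": np.log(0.0085),
    "Streptococcus": np.log(0.006),
    "Parabacteroides": np.log(0.012),
    "Phascolarctobacterium": np.log(0.008),
    "Christensenellaceae R-7": np.log(0.010),
    "Erysipelotrichaceae UCG-003": np.log(0.004),
    "Akkermansia": np.log(0.007),
    "Escherichia-Shigella": np.log(0.0029),
    "Bilophila": np.log(0.0020),
    "Oscillibacter": np.log(0.0045),
}

# Group log-fold shifts on mean log abundance.  Where group-level relative
# abundances are known (e.g. Prevotella 3.72 -> 10.55 percent pre-treatment,
# Escherichia-Shigella 0.29 -> 3.29 pre / 4.68 post) the shift is the
# natural log of the relative-abundance ratio; taxa identified only
# directionally by differential-abundance analysis carry moderate shifts of
# matching sign (Phascolarctobacterium's strong post-treatment enrichment
# toned to the relative-abundance scale).
DEFAULT_EFFECT_MAP: dict[tuple[str, str], float] = {
    ("CC_pre", "Prevotella"): np.log(10.55 / 3.72),
    ("CC_pre", "Escherichia-Shigella"): np.log(3.29 / 0.29),
    ("CC_pre", "Bilophila"): 1.0,
    ("CC_pre", "Streptococcus"): 1.0,
    ("CC_pre", "Phascolarctobacterium"): 0.8,
    ("CC_pre", "Ruminococcus"): np.log(0.53 / 1.35),
    ("CC_pre", "Christensenellaceae R-7"): -0.8,
    ("CC_pre", "Faecalibacterium"): np.log(12.43 / 15.53),
    ("CC_pre", "Roseburia"): np.log(1.64 / 2.31),
    ("CC_post", "Prevotella"): 1.0,
    ("CC_post", "Escherichia-Shigella"): np.log(4.68 / 0.29),
    ("CC_post", "Bilophila"): 1.2,
    ("CC_post", "Streptococcus"): 1.2,
    ("CC_post", "Phascolarctobacterium"): 2.0,
    ("CC_post", "Bacteroides"): np.log(21.67 / 8.56),
    ("CC_post", "Anaerostipes"): np.log(1.73 / 0.85),
    ("CC_post", "Collinsella"): 1.0,
    ("CC_post", "Oscillibacter"): 1.0,
    ("CC_post", "Ruminococcus"): np.log(0.30 / 1.35),
    ("CC_post", "Christensenellaceae R-7"): -1.8,
    ("CC_post", "Akkermansia"): np.log(0.09 / 0.72),
    ("CC_post", "Faecalibacterium"): np.log(7.55 / 15.53),
    ("CC_post", "Roseburia"): np.log(0.78 / 2.31),
    ("CC_post", "Subdoligranulum"): np.log(1.42 / 2.50),
}

# Severity direction per genus: +1 pushed up by worsening dysbiosis, -1
# depleted.  Only taxa in this map respond to the latent factor.
SEVERITY_DIRECTIONS: dict[str, float] = {
    "Prevotella": 1.0,
    "Escherichia-Shigella": 1.0,
    "Bilophila": 1.0,
    "Streptococcus": 1.0,
    "Ruminococcus": -1.0,
    "Christensenellaceae R-7": -1.0,
    "Faecalibacterium": -1.0,
    "Roseburia": -1.0,
}

# HD baseline percent-positive per (marker, subset) and additive group
# shifts; within-group noise SD and severity scale are config fields.
_BASE_PANEL: dict[tuple[str, str], float] = {
    **{(m, s): v for (m, s), v in {
        ("PD-1", "CD56dim"): 5.0, ("PD-1", "CD56bright"): 6.0,
        ("LAG-3", "CD56dim"): 4.0, ("LAG-3", "CD56bright"): 5.0,
        ("BTLA", "CD56dim"): 12.0, ("BTLA", "CD56bright"): 14.0,
        ("TIM-3", "CD56dim"): 30.0, ("TIM-3", "CD56bright"): 22.0,
        ("TIGIT", "CD56dim"): 38.0, ("TIGIT", "CD56bright"): 28.0,
        ("NKG2A", "CD56dim"): 35.0, ("NKG2A", "CD56bright"): 55.0,
        ("PD-1+BTLA", "CD56dim"): 2.0, ("PD-1+BTLA", "CD56bright"): 2.5,
        ("PD-1+LAG-3", "CD56dim"): 1.5, ("PD-1+LAG-3", "CD56bright"): 2.0,
        ("PD-1+TIM-3", "CD56dim"): 2.5, ("PD-1+TIM-3", "CD56bright"): 2.5,
        ("PD-1+TIGIT", "CD56dim"): 3.0, ("PD-1+TIGIT", "CD56bright"): 3.0,
        ("TIGIT+TIM-3", "CD56dim"): 14.0, ("TIGIT+TIM-3", "CD56bright"): 10.0,
        ("NKG2A+TIGIT", "CD56dim"): 18.0, ("NKG2A+TIGIT", "CD56bright"): 20.0,
        ("frequency", "CD56dim"): 91.0, ("frequency", "CD56bright"): 7.0,
    }.items()},
}

DEFAULT_CHECKPOINT_EFFECTS: dict[tuple[str, str, str], float] = {
    # (group, marker, subset) -> additive shift in percent positive
    ("CC_pre", "PD-1", "CD56dim"): 3.0, ("CC_post", "PD-1", "CD56dim"): 8.0,
    ("CC_pre", "PD-1", "CD56bright"): 9.0, ("CC_post", "PD-1", "CD56bright"): 7.0,
    ("CC_pre", "LAG-3", "CD56dim"): 3.0, ("CC_post", "LAG-3", "CD56dim"): 7.0,
    ("CC_pre", "LAG-3", "CD56bright"): 7.0, ("CC_post", "LAG-3", "CD56bright"): 7.5,
    ("CC_pre", "BTLA", "CD56dim"): 6.0, ("CC_post", "BTLA", "CD56dim"): 7.0,
    ("CC_pre", "BTLA", "CD56bright"): 2.0, ("CC_post", "BTLA", "CD56bright"): 3.0,
    ("CC_pre", "TIM-3", "CD56dim"): 1.5, ("CC_post", "TIM-3", "CD56dim"): 3.0,
    ("CC_pre", "TIM-3", "CD56bright"): 7.0, ("CC_post", "TIM-3", "CD56bright"): 8.0,
    ("CC_pre", "TIGIT", "CD56dim"): 1.5, ("CC_post", "TIGIT", "CD56dim"): 3.0,
    ("CC_pre", "TIGIT", "CD56bright"): 4.0, ("CC_post", "TIGIT", "CD56bright"): 7.0,
    ("CC_pre", "NKG2A", "CD56dim"): 0.5, ("CC_post", "NKG2A", "CD56dim"): 1.0,
    ("CC_pre", "NKG2A", "CD56bright"): 1.0, ("CC_post", "NKG2A", "CD56bright"): 2.0,
    ("CC_pre", "PD-1+BTLA", "CD56dim"): 1.0, ("CC_post", "PD-1+BTLA", "CD56dim"): 4.0,
    ("CC_pre", "PD-1+BTLA", "CD56bright"): 3.5, ("CC_post", "PD-1+BTLA", "CD56bright"): 3.0,
    ("CC_pre", "PD-1+LAG-3", "CD56dim"): 1.0, ("CC_post", "PD-1+LAG-3", "CD56dim"): 3.5,
    ("CC_pre", "PD-1+LAG-3", "CD56bright"): 4.0, ("CC_post", "PD-1+LAG-3", "CD56bright"): 3.0,
    ("CC_pre", "PD-1+TIM-3", "CD56dim"): 1.0, ("CC_post", "PD-1+TIM-3", "CD56dim"): 3.5,
    ("CC_pre", "PD-1+TIM-3", "CD56bright"): 3.0, ("CC_post", "PD-1+TIM-3", "CD56bright"): 2.5,
    ("CC_pre", "PD-1+TIGIT", "CD56dim"): 0.5, ("CC_post", "PD-1+TIGIT", "CD56dim"): 4.0,
    ("CC_pre", "PD-1+TIGIT", "CD56bright"): 3.5, ("CC_post", "PD-1+TIGIT", "CD56bright"): 3.0,
    ("CC_pre", "TIGIT+TIM-3", "CD56dim"): 0.5, ("CC_post", "TIGIT+TIM-3", "CD56dim"): 4.5,
    ("CC_pre", "TIGIT+TIM-3", "CD56bright"): 4.0, ("CC_post", "TIGIT+TIM-3", "CD56bright"): 6.0,
    ("CC_pre", "NKG2A+TIGIT", "CD56dim"): -5.0, ("CC_post", "NKG2A+TIGIT", "CD56dim"): -5.0,
    ("CC_pre", "NKG2A+TIGIT", "CD56bright"): -5.0, ("CC_post", "NKG2A+TIGIT", "CD56bright"): -5.0,
    ("CC_pre", "frequency", "CD56dim"): 2.0, ("CC_post", "frequency", "CD56dim"): -2.0,
    ("CC_pre", "frequency", "CD56bright"): -1.5, ("CC_post", "frequency", "CD56bright"): 1.5,
}


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_hd: int = 28
    n_pre: int = 27
    n_post: int = 22
    taxonomy_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_TAXONOMY))
    effect_map: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    checkpoint_effects: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CHECKPOINT_EFFECTS))
    latent_coupling: float = 0.6
    survival_link: float = 0.9       # log-hazard per unit severity
    baseline_hazard: float = 0.034   # events/month; ~40% mortality by 15 mo
    horizon_months: float = 15.0
    sequencing_depth: int = 40_000
    genus_log_sd: float = 0.8        # within-group SD of log abundance
    # dysbiotic communities are individually more uneven: log-abundance
    # dispersion is inflated per group, lowering evenness/diversity and
    # raising dominance in patients
    group_dispersion: Mapping[str, float] = field(
        default_factory=lambda: {"HD": 1.0, "CC_pre": 1.5, "CC_post": 1.8})
    taxa_severity_scale: float = 0.8   # log-units per unit coupling*severity
    panel_noise_sd: float = 4.0      # percent-positive within-group SD
    panel_severity_scale: float = 6.0  # percent per unit coupling*severity
    seed: int = 0

    @property
    def n_genera(self) -> int:
        return len(self.taxonomy_map)

    def validate(self) -> None:
        if min(self.n_hd, self.n_pre, self.n_post) < 0 or \
                self.n_hd + self.n_pre + self.n_post < 1:
            raise ValueError("group sizes must be non-negative and sum to >= 1")
        if not (0.0 <= self.latent_coupling <= 1.0):
            raise ValueError("latent_coupling must lie in [0, 1]")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be positive")
        genera = set(self.taxonomy_map)
        for (group, genus) in self.effect_map:
            if group not in GROUPS:
                raise ValueError(f"effect_map references unknown group {group!r}")
            if genus not in genera:
                raise ValueError(f"effect_map references unknown genus {genus!r}")
        for (group, marker, subset) in self.checkpoint_effects:
            if group not in GROUPS:
                raise ValueError(f"checkpoint_effects: unknown group {group!r}")
            if marker not in PANEL_MARKERS:
                raise ValueError(f"checkpoint_effects: unknown marker {marker!r}")
            if subset not in NK_SUBSETS:
                raise ValueError(f"checkpoint_effects: unknown subset {subset!r}")


def default_config(**overrides) -> CohortConfig:
    return replace(CohortConfig(), **overrides)


@dataclass
class Cohort:
    """Three aligned tables sharing one ordered subject-ID set."""

    taxa: pd.DataFrame                # subjects x genera counts
    taxonomy: dict[str, str]
    nk_panel: pd.DataFrame            # subjects x "marker|subset" percents
    metadata: pd.DataFrame            # group, severity, time_months, event, lost_to_followup
    config: CohortConfig

    @property
    def subjects(self) -> list[str]:
        return list(self.metadata.index)

    def __post_init__(self) -> None:
        ids = list(self.metadata.index)
        if list(self.taxa.index) != ids or list(self.nk_panel.index) != ids:
            raise ValueError("taxa, nk_panel and metadata must share one ordered subject set")


def _panel_col(marker: str, subset: str) -> str:
    return f"{marker}|{subset}"


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort; deterministic given (config, seed)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genera = list(config.taxonomy_map)
    groups = (["HD"] * config.n_hd + ["CC_pre"] * config.n_pre
              + ["CC_post"] * config.n_post)
    n = len(groups)
    ids = [f"S{i:03d}" for i in range(1, n + 1)]

    severity = rng.standard_normal(n)

    # --- taxa counts: log-normal weights -> softmax -> multinomial --------
    mu = np.array([_BASELINE_LOG_ABUNDANCE.get(g, np.log(0.003)) for g in genera])
    group_arr = np.asarray(groups)
    shift = np.zeros((n, len(genera)))
    for j, genus in enumerate(genera):
        for group in ("CC_pre", "CC_post"):
            lfc = config.effect_map.get((group, genus), 0.0)
            if lfc:
                shift[group_arr == group, j] += lfc
        direction = SEVERITY_DIRECTIONS.get(genus)
        if direction is not None:
            shift[:, j] += (config.latent_coupling * severity
                            * config.taxa_severity_scale * direction)
    disp = np.array([config.group_dispersion.get(g, 1.0) for g in groups])
    log_w = mu[None, :] + shift + (rng.normal(0.0, config.genus_log_sd,
                                              size=shift.shape)
                                   * disp[:, None])
    w = np.exp(log_w - log_w.max(axis=1, keepdims=True))
    p = w / w.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(config.sequencing_depth, p[i]) for i in range(n)])
    taxa = pd.DataFrame(counts, index=ids, columns=genera)
    taxa.index.name = "subject"

    # --- NK panel ---------------------------------------------------------
    panel = {}
    for marker in PANEL_MARKERS:
        for subset in NK_SUBSETS:
            vals = np.full(n, _BASE_PANEL[(marker, subset)])
            for group in ("CC_pre", "CC_post"):
                vals[group_arr == group] += config.checkpoint_effects.get(
                    (group, marker, subset), 0.0)
            if marker != "frequency":
                vals += (config.latent_coupling * severity
                         * config.panel_severity_scale)
            vals += rng.normal(0.0, config.panel_noise_sd, size=n)
            panel[_panel_col(marker, subset)] = np.clip(vals, 0.0, 100.0)
    nk_panel = pd.DataFrame(panel, index=ids)
    nk_panel.index.name = "subject"

    # --- survival: exponential hazard scaled by severity, censored --------
    hazard = config.baseline_hazard * np.exp(config.survival_link * severity)
    raw_t = rng.exponential(1.0 / hazard)
    event = (raw_t <= config.horizon_months).astype(int)
    time_months = np.minimum(raw_t, config.horizon_months)
    time_months = np.maximum(time_months, 1e-6)  # keep times strictly positive

    metadata = pd.DataFrame(
        {
            "group": groups,
            "severity": severity,
            "time_months": time_months,
            "event": event,
            "lost_to_followup": np.zeros(n, dtype=int),
        },
        index=ids,
    )
    metadata.index.name = "subject"

    return Cohort(taxa=taxa, taxonomy=dict(config.taxonomy_map),
                  nk_panel=nk_panel, metadata=metadata, config=config)


def apply_loss_to_followup(cohort: Cohort, n_lost: int, seed: int = 0) -> Cohort:
    """Flag ``n_lost`` random pre-treatment subjects as lost to follow-up.

    Returns a new cohort; all other flags and tables are untouched.  Lost
    subjects are excluded from survival analyses downstream.
    """
    if n_lost < 0:
        raise ValueError("n_lost must be non-negative")
    pre_ids = cohort.metadata.index[cohort.metadata["group"] == "CC_pre"]
    if n_lost > len(pre_ids):
        raise ValueError(
            f"n_lost={n_lost} exceeds the {len(pre_ids)} pre-treatment subjects")
    metadata = cohort.metadata.copy()
    if n_lost:
        rng = np.random.default_rng(seed)
        lost = rng.choice(pre_ids.to_numpy(), size=n_lost, replace=False)
        metadata.loc[lost, "lost_to_followup"] = 1
    return Cohort(taxa=cohort.taxa, taxonomy=cohort.taxonomy,
                  nk_panel=cohort.nk_panel, metadata=metadata,
                  config=cohort.config)
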