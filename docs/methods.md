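# Methods

## Composite percentile-bin scores

Both composite scores follow the same recipe: Z-score each feature against
the healthy-donor (HD) reference, classify into an ordinal bin 1/2/3 at
empirical percentile thresholds of that reference, and aggregate.

The reference (`fit_reference`) stores, per feature, the HD mean, the HD
standard deviation with ddof = 1, and the sorted HD values. Percentile
thresholds use linear interpolation on the empirical reference (numpy's
default); ties in reference values are handled by the interpolation's
position averaging. A feature that is constant across HD subjects is
rejected outright — a zero SD leaves the Z-score undefined, and silently
flooring the SD would manufacture spurious bins — so degenerate panel
features must be excluded (or jittered) by the caller.

Binning (`bin_score`) compares the subject's z to the z-values of the
reference at the `cut_lo` and `cut_hi` percentiles: at or below the low
threshold → 1, at or below the high threshold → 2, above → 3 (boundary
values stay in the lower bin). In `two_sided` mode the comparison is |z|
against the percentiles of the reference's own |z| values, so departures in
either direction from the HD centre are penalised — appropriate for
dysbiosis, where both loss and gain relative to the healthy configuration
are abnormal. Defaults are cut_lo = 66.7 and cut_hi = 90; the exact cuts
are study-specific tuning parameters, so they are mandatory arguments of
`BinRule` with these documented defaults rather than hard-coded constants.

Exhaustion uses `one_sided` binning (higher checkpoint expression is worse)
over six markers per NK subset, summed to S_subset ∈ [6, 18]; the global
score is the mean of the CD56dim and CD56bright sums. The dysbiosis score
uses `two_sided` binning over four α-diversity metrics (Shannon, Pielou,
Simpson, Strong) plus CLR abundances of a configurable taxa panel (default:
Prevotella, Escherichia-Shigella, Ruminococcus, Christensenellaceae R-7,
Phascolarctobacterium, Faecalibacterium), aggregated by sum (range [k, 3k]
for k features); a mean-normalised variant (`aggregate="mean"`) is exposed
for comparing panels of different sizes. Co-expression percentages are
deliberately not part of the composite — they are carried as plain features
for the risk models and survival stratification only.

Consequences worth knowing: an HD-typical subject does not score zero but
the floor (k × 1), because bin 1 is the "within reference" class; and with
one-sided exhaustion binning the score is monotone in every marker's
percent-positive, which the tests verify.

## α-diversity

Five metrics on a sample's genus counts, with richness S counting only taxa
observed in that sample: Shannon H = −Σ p log_b p, Simpson D = 1 − Σ p²,
Pielou J = H / log_b S (undefined at S = 1), Simpson evenness
(1/Σp²)/S, and Strong dominance Dw = max_i (b_i/N − i/S) over descending
rank order. Shannon and Pielou default to log base 2 to match the
q2-diversity convention dominant in the amplicon ecosystem; the base is a
parameter, and since scores Z-standardise the metrics downstream it cancels
there anyway.

## Compositional layer

CLR per sample over the full feature set of the table supplied:
`ln(count + pseudocount)` centred by the row's mean log. The pseudocount
defaults to 0.5, a symmetric additive zero-replacement; it is exposed
because zero-handling choices measurably move CLR values of rare taxa.
Phylum ratios are computed on the phylum-aggregated table's CLR, genus
ratios on the genus-level CLR — the geometric mean always spans the full
composition at that level, never a selected sub-panel, because
sub-compositional selection changes CLR coordinates. A ratio is a CLR
difference and hence exactly the natural log of the pseudocounted abundance
ratio; "Escherichia" is aliased to the SILVA genus label
"Escherichia-Shigella" when resolving panel names.

## Risk models and ROC utilities

The two published two-variable logistic models are fixtures with
coefficients exactly as printed and features on their native scales
(percent-positive 0–100; CLR-difference ratio in natural-log units); they
are immutable, and refits are separate `RiskModel` objects produced by
maximum likelihood (statsmodels `Logit`) with Wald standard errors and
OR CIs exp(β ± 1.96·SE). Stepwise or tree-based feature selection is out of
scope: feature sets are fixed inputs. Perfect or quasi-separation is
flagged (`converged=False`) rather than raised, with the last-iterate
coefficients reported; the flag also trips when coefficients drift beyond
|β| > 30 or standard errors are non-finite, which catches separations the
optimizer's own convergence flag misses.

Spearman correlation uses scipy's t-approximation for n > 10 and an exact
permutation enumeration of the rank correlation for n ≤ 10, where the
approximation is unreliable. ROC AUC is the tie-aware rank statistic
(scikit-learn). The Youden cutoff scans midpoints between adjacent distinct
scores, calls a subject positive when its value strictly exceeds the
threshold, and breaks ties in J toward the lowest cutoff; anti-informative
markers (J ≤ 0 everywhere) are returned as-is for the caller to inspect.

## Survival

Kaplan–Meier product-limit with the simultaneous-event tie convention (all
deaths at a time t reduce the same risk set); median survival is the
smallest event time with S(t) ≤ 0.5, `None` if never reached. The log-rank
test accumulates per-event-time 2×2 tables (observed vs hypergeometric
expected deaths, variance with the (n−d)/(n−1) tie correction). Two
hazard-ratio summaries are exposed because both circulate in applied work:
the O/E ratio (default) and the one-step Mantel–Haenszel estimate
exp((O−E)/V); CIs use the log-scale normal approximation with
SE = √(1/E_a + 1/E_b) for O/E and √V for Mantel–Haenszel. The per-table
machinery is implemented in-package because the O/E and Mantel–Haenszel
summaries need the O, E and V components directly; lifelines serves as an
independent cross-check of the KM curve and the log-rank statistic in the
test suite. Note the O/E estimator is biased toward 1 when risk sets
deplete heavily; the recovery simulations therefore run with moderate
administrative censoring (≈70%/33% event fractions), where it is nearly
unbiased.

Stratification places the Youden cutoff on the marker using survival status
as the label (the published design), assigns "high" above the cutoff, and
the combined analysis keeps only subjects concordant on both markers
(high/high vs low/low), which sharpens contrast at a real cost in n.
Subjects flagged lost to follow-up are excluded before any estimation.

## Synthetic cohort generator

The generator's defaults are the study conditions: 28 HD, 27 pre-treatment,
22 post-treatment subjects; 40,000 reads per sample; a 15-month horizon.

*Taxa.* Twenty genera spanning Firmicutes, Bacteroidota, Proteobacteria,
Actinobacteriota and Verrucomicrobiota, with HD baseline mean log
abundances set to realistic healthy gut levels (Faecalibacterium ≈ 15%,
Bacteroides ≈ 9%, Prevotella ≈ 4%, Escherichia-Shigella ≈ 0.3%, …). Per
subject, log weights = baseline + group log-fold shift + severity coupling
+ Gaussian noise (SD 0.8); softmax-normalised weights feed a multinomial at
fixed depth. Group shifts are calibrated as the natural log of known
group-level relative-abundance ratios where available (e.g. Prevotella
3.72 → 10.55% pre-treatment, Escherichia-Shigella 0.29 → 3.29% pre /
4.68% post, Ruminococcus 1.35 → 0.53%), with moderate shifts of the
reported sign for taxa identified only directionally
(Phascolarctobacterium's strong post-treatment enrichment toned to +2.0 on
the relative-abundance scale, since bias-corrected differential-abundance
LFCs overstate relative shifts). Disease groups additionally carry
overdispersed log abundances (noise SD × 1.5 pre, × 1.8 post): with mean
shifts alone, patient communities were not less diverse than HD, whereas
inflated inter-individual dispersion — the realistic signature of
dysbiosis — lowers per-sample evenness and diversity and raises Strong
dominance, reproducing the observed direction of every α-metric.

*NK panel.* Baseline HD percent-positive per (marker, subset) set to
realistic flow-cytometry levels (e.g. PD-1 ≈ 5–6%, TIGIT ≈ 28–38%, NKG2A
bright ≈ 55%); additive group shifts follow the reported directions
(checkpoints up in patients; CD56dim co-expression exacerbated
post-treatment; PD-1 on CD56bright slightly lower post than pre;
NKG2A⁺TIGIT⁺ reduced in patients), with Gaussian noise (SD 4) and clamping
to [0, 100]. Within-group variances are not reported anywhere, so these are
free parameters of `CohortConfig` with the defaults above. Subset
frequencies (CD56dim ≈ 91%, CD56bright ≈ 7% of NK cells) ride along as
panel features because the mortality model consumes them; they are not
coupled to severity.

*Latent severity.* One standard-normal scalar per subject shifts the
dysbiosis-direction taxa (±0.8 log units × coupling × severity), shifts
every checkpoint (6% × coupling × severity), and scales the death hazard —
the minimal shared-cause mechanism that makes dysbiosis and exhaustion
rank-correlated and prognostic. The default coupling is 0.6; under it the
Monte-Carlo expectation of Spearman(dysbiosis, global exhaustion) over 50
replicate 1,000-subject cohorts is 0.317 (SD 0.028), the value frozen into
the test suite.

*Survival.* Exponential times with hazard 0.034/month × exp(0.9 ×
severity) — about 40% mortality by 15 months at severity 0, matching a
cohort where 9 of 23 evaluable patients die within the horizon — censored
administratively at 15 months. Survival times are generated for every
subject for table uniformity, but analyses restrict to pre-treatment
subjects, and `apply_loss_to_followup` flags a configurable number of
pre-treatment subjects (default pipeline: 4 of 27, leaving 23 evaluable)
for exclusion.

What passing tests on this generator do **not** show: real 16S data have
hundreds of sparse genera, sequencing-depth variation, compositional
zero-inflation and covariate structure (age, BMI, stage, bowel habit) that
the 20-genus, fixed-depth, single-latent-factor model deliberately omits;
group effects here are cross-sectional plants, not longitudinal treatment
effects. Tests on this cohort validate the *machinery* — score algebra,
estimator correctness, directional recovery of planted structure — not
field performance of the biomarkers.

## Problem sizes and numerical choices

Simulation-based checks use 100 subjects/group for distributional
direction, 500/group for correlation recovery, 5,000 for logistic
coefficient recovery, and 1,000/group for hazard-ratio recovery — sizes at
which Monte-Carlo error is comfortably inside the asserted bands. Oracle
equivalence checks (diversity, CLR, bins, AUC, Youden, KM, log-rank) run
100 random small instances against naive loop implementations at 1e-12.
Seeds are fixed everywhere; `generate_cohort` is bitwise reproducible given
(config, seed). Degenerate inputs fail loudly by design: all-zero count
vectors, S = 1 for Pielou, constant reference features, single-class
labels, zero-event survival comparisons and empty strata all raise with the
offending feature or subject named.

## Known limitations

The percentile cuts, the dysbiosis aggregation rule (sum vs mean) and the
sidedness of the α-diversity features are exposed configuration, since the
methodology leaves room for study-specific choices; defaults are documented
above. The O/E hazard ratio is a crude summary (no proportional-hazards
model is fitted; Cox regression is out of scope), CIs for it are
approximate, and with ≤ 23 evaluable subjects all survival quantities carry
wide uncertainty. Printed-model evaluation assumes features were entered on
raw scales; if a study standardised its predictors the coefficients would
not transfer.
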