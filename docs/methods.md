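# Methods

This note documents the models and procedures implemented in
`karyoscreen`, the assumptions behind them, the parameters that matter,
and the choices made where the design was genuinely open.

## Arm-level aneuploidy calling

Input is segmented copy-number data (SEG format: sample, chromosome,
start, end, optional marker count, mean log2 copy ratio). A chromosome
arm is represented by the interval from the first to the last
protein-coding gene on the arm, and an arm-level event is called for a
sample when at least a fraction `arm_fraction_threshold` (default 0.67)
of that interval — measured in base pairs — is covered by segments whose
mean log2 ratio is at or beyond `±seg_mean_threshold` (default 0.3) in
one direction. Qualifying segments are intersected with the arm and
unioned before measuring, so overlapping segments are not double
counted.

Numerical conventions:

* **Inclusive boundaries.** `|seg_mean| ≥ 0.3` qualifies a segment and
  `fraction ≥ 0.67` calls an event. The thresholds are magnitude cutoffs
  without stated strictness; the inclusive reading is the conservative
  one and is frozen in `CallerConfig`.
* **Closed-start, open-end intervals** in base pairs. Abutting segments
  then sum exactly to the arm length, and the union arithmetic is exact
  integer arithmetic — the brute-force per-base oracle agrees to
  machine precision, not merely 1e-9.
* **Gaps count as unaltered.** Absent evidence cannot support an event.
  The caller therefore under-calls arms with sparse segment coverage
  (a known behaviour of whole-arm calling on real cell-line data, e.g.
  for 17q) rather than extrapolating.
* **Measure = base pairs, not marker count.** The marker-count column is
  parsed but not used as the measure; base-pair length is the documented
  denominator (the gene-bounded arm length), and using it keeps the
  caller independent of platform marker density.
* **Segment means are used as-is** — no re-centering to ploidy. Callers
  working from ploidy-uncentered data should re-center upstream.
* **Autosomes only** by default: sex-chromosome segments are parsed and
  chromosome labels normalized (`chr17` → `17`), but X/Y arms are
  excluded from calling. Acrocentric p-arms (13p, 14p, 15p, 21p, 22p)
  carry no protein-coding genes and are omitted from the arm table with
  a warning, leaving 39 callable autosome arms.

With the default threshold of 0.67 > 0.5, loss and gain calls are
mutually exclusive; both altered fractions are always reported.

## Prevalence normalization

Cancer types are unequally represented in any aggregate cohort, so raw
per-arm loss counts conflate prevalence with sampling. For cancer type
*c* with *N_c* samples, *P_c = N_c / Σ_c N_c*; the raw loss count
*C_raw* of an arm within type *c* is normalized as
*C_norm = C_raw / P_c*, and arms are ranked by Σ_c *C_norm* — summation
over cancer types is the aggregate used, and the table labels it
explicitly (`arm_normalized_total`). Losses and gains are never mixed
in one count; the screens downstream are loss-focused.

## Survival screen

For each combination of treatment unit (compound name, or mechanism of
action once MOAs are assigned) and arm — optionally further split by
cancer type — patients with non-missing survival, treatment, and
arm-status data are partitioned into **Loss** (status = loss on the
arm) and **Other** (euploid and polyploid; gains sit in Other by
default, with a config switch to exclude them). Combinations where
either group has fewer than `min_group_n = 10` patients are skipped,
not errored. Progression-free survival in months is paired with the
disease-specific death flag as the event indicator. Groups are compared
by the two-sided two-group log-rank test; Kaplan–Meier medians are
reported per group, with "NR" (not reached, stored as `inf`) when the
curve never crosses 0.5.

Significance is the **nominal p < 0.05**; Benjamini–Hochberg q-values
over the whole emitted family are always attached so users can filter
by FDR instead — the permissive nominal gate is the screen's counting
rule, the q-value the stricter option.

Direction classification compares group medians, treating NR as +∞.
When both medians are NR the curves are compared at the last time
observed in both; an exact tie is labelled `indeterminate` and excluded
from direction counts. Patients with multiple treatments contribute to
every matching combination independently (no exclusivity rule is
imposed). Survival is truncated at 60 months for plotting only;
testing uses full follow-up by default, with
`ScreenConfig.truncate_at_landmark` exposing administrative censoring
at the landmark for sensitivity analyses.

KM estimation and the log-rank test are delegated to `lifelines`; BH to
`statsmodels`. The test suite checks both against independent
hand-computed oracles (explicit product-limit and O−E/V summations, the
step-up formula).

## WGD versus arm loss

Genome-doubling counts are binarized (≥1 doubling → WGD). Within each
(cancer type, arm) stratum of at least 30 eligible samples, patients
are stratified into Euploid/Loss × WGD/non-WGD and exactly three
predefined pairs are compared by log-rank: Euploid non-WGD vs Loss
non-WGD, Euploid WGD vs Loss non-WGD, Euploid WGD vs Loss WGD.
"Euploid" means no loss on the tested arm — the same definition as the
screen's Other group — not genome-wide euploidy.

The pan-cohort Cox model regresses progression-free survival (event =
disease-specific death, the same outcome pairing as the screen) on two
binary covariates: the WGD flag and an any-arm-loss flag (1 iff at
least one arm is called loss). Ties use the Efron approximation.
Coefficients, hazard ratios, 95% CIs, z statistics and two-sided p are
reported per covariate; degenerate designs (no events, constant
covariate) raise informative errors rather than returning divergent
estimates.

## Landmark analysis

Within each (subtype, arm), samples are split Loss vs No Loss; groups
below 5 samples omit the arm. Kaplan–Meier curves are fitted per group
and read at the fixed landmark t₀ = 60 months, giving
ΔS = S_NoLoss(60) − S_Loss(60). When a group's follow-up ends before
t₀ the last observed survival value is carried forward and the result
flags the extrapolation (`extrapolated_*`), so downstream consumers can
drop extrapolated values if they prefer NA semantics.

## Viability screen

The drug-sensitivity screen mirrors the survival screen on cell lines:
per (compound or MOA, arm[, cancer type]), viability readouts of Loss
lines are compared with Other lines by one-way ANOVA (for two groups,
F is exactly the squared pooled-variance t, an identity the tests check
numerically). The same minimum group size of 10, nominal 0.05 gate and
family-wide BH q-values apply. Direction comes from group means:
`lower_viability_in_loss` marks preferential cytotoxicity in the
aneuploid state. The observation unit is one (cell line, compound,
dose) readout; multiple doses enter as separate observations by
default, with `collapse_doses="mean"` averaging per line first.
Viability values are taken as provided (log-fold-change convention,
pre-processed upstream); no dose–response fitting is attempted.

## Cross-dataset integration

Clinical treatments lack MOA labels; assignment consumes a
replicate-response table (five boolean responses per treatment–MOA
pair) and takes the majority vote. Using a file of replicate responses
rather than querying any external service keeps the step reproducible
and offline. Over-generic labels (anti-tumor, anti-cancer,
anti-neoplastic) and non-compound treatments (e.g. radiation) are
dropped. Cell-line cancer types are derived from the tissue suffix of
the line name (`LN18_CENTRAL_NERVOUS_SYSTEM` → `CNS`) via a
user-editable mapping table; unmapped suffixes are excluded. The
overlap step inner-joins the two screens on (MOA, arm, cancer type)
and keeps triples significant on both sides with concordant direction:
improved survival in Loss patients and lower viability in Loss lines.

## Synthetic data

The generator emulates the statistical structure the screens assume,
not the marginal distributions of any real dataset:

* arm losses are independent Bernoulli events per (sample, arm) with
  configurable per-(cancer type, arm) frequencies;
* SEG emission writes one full-arm segment per (sample, arm) at mean
  −1 / 0 / +1 plus Gaussian noise, so with zero noise the caller
  round-trips the planted matrix exactly (fragmentation behaviour is
  tested with hand-built fixtures instead);
* survival is exponential with baseline hazard 0.03/month (median PFS
  ≈ 23 months, a realistic advanced-cancer figure) multiplied by the
  planted hazard ratio for every (treatment, arm) exposure the patient
  carries, with independent exponential censoring at 0.01/month and
  administrative censoring at 60 months;
* viability is Gaussian around 0 with sd 0.5 (log-fold-change scale)
  plus the planted shift in Loss lines;
* WGD flags are independent Bernoulli at probability 0.3, roughly the
  fraction of genome-doubled tumors in large pan-cancer series.

All draws descend from one integer seed through stream-separated
generators, so each output is reproducible independently of call
order. Not modelled: inter-arm correlation (real aneuploidy is highly
co-occurrent), focal events inside arms, cancer-type-specific survival
baselines, dose–response structure, and batch effects. Passing tests
therefore demonstrate that the statistical machinery recovers planted
effects under its own assumptions — not that those assumptions hold in
TCGA- or PRISM-scale data.

## Verification problem sizes

The end-to-end property checks run at sizes chosen to make the
binomial/sampling bounds tight while keeping the suite quick: the
noise-free round trip uses 200 samples × 39 arms; the per-base fraction
oracle 100 randomized arms up to 1 Mb; the null screens ~1,014
combinations with ~50 patients (or lines) per group, where the nominal
rejection fraction must land in [0.03, 0.07]; power checks plant 100
effects (hazard ratio 3, or a −1 shift at sd 0.5) at ~100 per group and
require ≥95% detection with the correct direction; Cox recovery uses
100 replicates of n = 2,000 with a planted any-loss hazard ratio of
2.0, requiring the mean estimate in [1.9, 2.1] and ≥90% CI coverage.

## Known limitations

* The caller has no probe-level smoothing or re-centering; SEG means
  off-center by ploidy will bias calls.
* The 67% rule uses base-pair length; marker-weighted calling is not
  implemented.
* Log-rank and ANOVA p-values are asymptotic; at the minimum group
  size of 10 they are approximate, which is why the inclusion rule
  exists at all.
* Overlap detection requires exact (MOA, arm, cancer type) key
  equality; fuzzy matching of related mechanisms is out of scope.
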