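# Methods

This note records the statistical procedure `urimex` implements, the
choices made where the procedure's published description left the design
open, and what the synthetic-data generator does and does not emulate.

## Data model

A study is a peak table (samples × compounds, non-negative areas) plus a
sample sheet (method/arm label, pre/post/none spike group, replicate index,
treatment tags, optional creatinine value) and a spike-mixture definition
(compound, class, nominal ppm; the default mixture is 10 compounds at
50 ppm: six amino acids, three organic acids, one fatty acid).

Missing cells, empty strings and explicit zeros all mean "not detected" and
are stored as exactly 0. This matches how deconvolution exports encode
absence and lets detection calls, CVs and recovery averages treat absence
numerically. Long CSV (`Sample,Compound,Area`) is the canonical dialect;
wide is a convenience. Sample/compound order is first-appearance order and
survives a round trip bit-exactly (reads use pandas'
`float_precision="round_trip"`). Compound names match case-insensitively
after trimming, with no fuzzy matching — a silent mis-join is worse than a
hard error.

## Normalization

Two divisions, in a fixed order enforced by a state flag on the table:

1. **Internal standard** (3-phenylbutyric acid, added at 50 ppm to every
   sample): each sample's areas are divided by its IS area. A zero IS area
   is a failed injection and is rejected naming the sample. The IS feature
   is removed afterwards — its ratio is identically 1 and it is an
   instrument control, not an analyte.
2. **Creatinine** (urine dilution correction): each sample's values are
   divided by its creatinine value. The default source is the sample
   sheet (an external measurement), because organic-acid extractions
   routinely fail to detect creatinine in the table itself, which would
   make in-table normalization impossible for those arms; the in-table
   source is available (`creatinine_source="peak_table"`) and consumes the
   creatinine feature.

Applying a step to a table in the wrong state is an error, never a silent
double division. The composition equals a single division by
IS × creatinine (asserted in tests). No log transform is applied at this
stage: CV and recovery are defined on the ratio scale.

## Repeatability

CV is the sample (n−1) standard deviation over the mean, in percent,
computed per compound across a method's pre-spike replicates (3 by
design). With only three replicates the unbiased-variance convention is
the metabolomics default. Compounds with zero mean have no defined CV and
are excluded from the detected count; the method score is
100·|{c : CV(c) < threshold}| / n_detected with threshold 50% by default
(strict inequality). If every compound is absent the result is an explicit
"no detected compounds" error, not 0/0.

The PCA scores view autoscales by default (mean-centre, unit variance,
n−1 SD) with zeros entering as zeros (no imputation); zero-variance
compounds are dropped with a warning before scaling. The decomposition is
deterministic (full SVD) with a fixed sign convention — the
largest-magnitude loading per component is made positive — so repeated
runs are bit-identical. Per-group 95% confidence regions in the PC1–PC2
plane use the Hotelling T² scale 2(n−1)/(n−2)·F₀.₉₅(2, n−2) around the
group's score covariance; groups with fewer than 3 samples get no ellipse
(warned). The original analysis delegated PCA to an external service
without stating settings, so scaling is an explicit, recorded flag here.

## Coverage

The published description states the detection rule two ways that disagree
for a compound seen in exactly 1 of 3 replicates: "not detected in at
least 50% of all samples" versus a zero-average formula. The fraction rule
is authoritative here (`detection_fraction`, default 0.5, detected iff the
nonzero fraction ≥ 0.5); the literal zero-average rule is available as
`detection_fraction="any"`. Detection uses pre-spike samples only (spike
compounds would otherwise inflate coverage); arms without spike groups
fall back to all their samples. The universe is data-defined — the union
of all methods' detections, with never-detected columns dropped — and its
size N is reported next to every percentage rather than hard-coding the
reference study's 220.

`detection_matrix_from_unique_lists` reconstructs a detection matrix from
the bundled published unique-compound lists. The lists contain two naming
inconsistencies that would make the printed cardinalities (0/13/1/7/91
per method, 58 for the organic-acid group) unattainable in any single
matrix if taken literally; the fixture therefore ships one alias (the
group list reports malonic acid under its diethyl-ester derivative name)
and the constructor treats a name occurring in both the direct-analysis
unique list and the group list as two distinct chromatographic features
(the group-side copy is suffixed) — the lists' own "[1]/[2]" suffixes
already show that one name can denote multiple peaks. A 71-compound shared
core pads the universe to 220; with it, the direct-analysis method's
26.4% undetected also emerges as (220−162)/220.

## Recovery

Per spike compound, % recovery = 100·(pre-spike average / post-spike
average), means taken over the replicate groups on the normalized scale
(the published order of operations puts all statistics after
normalization; a raw-scale run is possible by passing an unnormalized
table). A zero post-spike average yields recovery 0 — matching how such
cells are printed — with flags distinguishing 0/0 (never seen) from x/0.
No endogenous-background subtraction is applied: the statistic is the raw
ratio, and rows with recovery > 100% are flagged as endogenous-suspect
rather than corrected. The method score averages over **all** spike
compounds including zeros.

`round_half_up` exists because printed tables use decimal half-up
rounding: a mean of 22.215 must display as 22.22, while binary-float
`round` would give 22.21. The helper quantizes a few digits below the
target first so float noise around a decimal half-case cannot flip the
direction.

## Ranking

Criterion directions are fixed: repeatability higher-better, coverage
(% undetected) lower-better, recovery higher-better. Coverage is scored by
% undetected, not unique-compound counts — the two orderings concur on the
reference data, and a single well-defined score avoids double counting;
unique counts are carried as a secondary column. Ranks use the competition
(minimum) convention on ties, keeping rank sums integer-valued; ties are
flagged loudly in the report since the reference tables contain none. The
cumulative score is the equal-weight rank sum; ordering ties break
alphabetically for determinism. When any arm lacks pre/post spike groups
(e.g. a drying comparison), recovery is recorded as "not assessed" and
dropped from the rank matrix for all arms, since ranks must cover every
arm; the reduced criterion set is recorded in the report.

Between-group signal ratios (`group_mean_ratio`) quantify effects like
urea suppression: mean signal in group A over mean in group B, with 0/+
→ 0 and +/0 → infinity with a flag.

## Synthetic-data generator

The generator emulates the reference design: per study, endogenous
compound levels are drawn once from a lognormal (median 1, ln-dispersion
1) over a class-labelled panel (defaults: 30 amino acids, 60 organic
acids, 20 fatty acids, 50 sugars, 40 other ≈ 200 endogenous compounds),
plus a high-abundance urea channel (level 50), a creatinine channel
(between-sample ln-spread 0.2, also written to the sample sheet as the
external measurement) and the internal standard (level 1). Observed area =
(endogenous × class recovery × censoring + spike) × mean-one lognormal
noise whose CV is the profile's `replicate_cv`. Censoring is a hard zero
with probability 1 − detection probability, applied to the endogenous part
only (the 50 ppm spike is far above the detection limit). Pre-spike
samples receive the spike before extraction (× class recovery), post-spike
after (full strength) — this encodes the design's meaning and makes true
recovery identifiable; spike compounds carry no endogenous background by
default so the noise-free estimate equals the configured fraction exactly.
Per-method Poisson "artifact" compounds model method-specific spurious
features. Urease/drying arms multiply urea by `urea_attenuation` and all
endogenous signal by `collateral_attenuation` (urease reduces overall
metabolic signal, not just urea). One `numpy.random.default_rng(seed)`
drives everything; identical seeds give bit-identical studies.

Default profiles (`part_a_profiles`, `urease_profiles`) encode the
qualitative contrasts of the study arms — OA arms biased to organic/fatty
acids with poor amino-acid/sugar detection and higher noise (the
acetonitrile arm noisiest but with the best OA extraction), the
direct-analysis arm broad and quiet; urease arms attenuate urea tenfold at
the cost of collateral signal, detection and noise. These are design
choices made once, documented here, and shape only the qualitative
ordering, which is what the property tests assert.

What the generator does **not** emulate: chromatography physics (retention
time, peak shape, co-elution), derivatization chemistry, batch effects, or
real compound identities beyond the named channels. Passing tests
therefore demonstrate the pipeline's statistical correctness and the
identifiability of its parameters under the stated noise model, not
instrument-level realism.

## Problem sizes and numerics

The test suite and acceptance script run at the study's own design sizes
(3 pre + 3 post replicates per arm; 5 arms) with desk-scale compound
panels (5–60 per class as each check requires), 500 seeded repetitions for
the recovery parameter-recovery check and 100 seeded studies for the
dominance check — chosen as the package's own verification sizes, small
enough to run anywhere in seconds. Numeric tie-breaks, degenerate-input
behaviour (zero IS, zero mean, empty detection, 0/0 recovery) and the
fixed PCA sign convention are all specified above and asserted in tests.

## Known limitations

- The reference study's raw-data-dependent percentages (e.g. 82.4%
  CV < 50 for the direct-analysis method) depend on its deposited raw
  data, which this package does not require; only the printed-table
  quantities are reproduced exactly, the rest via seeded properties.
- Recovery estimation is slightly biased upward (≈1 percentage point at
  10% replicate CV) because the estimate is a ratio of noisy means after
  division by a noisy internal standard; this is inherent to the ratio
  statistic, not corrected, and well inside the tested tolerance.
- Competition ranks with equal weights are the only aggregation offered;
  no significance testing of rank differences is attempted.
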