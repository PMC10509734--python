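# Methods

This note documents the models, defaults and design choices behind
`pcnkit`, the way the package's own maintainers would want them recorded.

## Cohort definition

A patient is a *new CRC case* for diagnosis year Y when their earliest
admission carrying any C18–C21 code falls in Y and no C18–C21 code appears
in the preceding washout window.  Washout is measured backwards in days
(5 years = 1826 days; `round(years * 365.25)`), which is leap-day safe and
explicit.  The *index hospitalization* is the earliest admission with admit
date in `[first_crc, first_crc + 28 days]`, both endpoints inclusive — the
simplest faithful reading of "within 4 weeks"; the window length is
configurable because the inclusive/exclusive convention is genuinely
ambiguous.  Same-day admissions are ordered by discharge date.

Exclusion checks run in a fixed order and the first failure is the recorded
reason: prevalent CRC, under 18, nonresident, incomplete (no index
admission in the window), sex conflict, bare history code.  One reason
(`no_crc_in_year`) exists beyond that list so that patients with no CRC
code at all — possible in arbitrary input files — still land in exactly one
of {cohort, exclusion log}; the partition property is asserted in tests.

Design choices that were genuinely open:

* **C19 (rectosigmoid junction) groups with rectum.**  This makes the
  colon/rectum/anus/multiple partition reproducible from C18/C19–C20/C21;
  it is configurable in `classify_cancer_site`'s mapping.
* **Sex conflict** means more than one recorded sex value, or a
  sex-specific diagnosis (default list: N40 male-only, N80 female-only)
  conflicting with the recorded sex.  The code list is a config knob; no
  canonical list exists for discharge data.
* **Residence** is a pass-through predicate: a *missing* region excludes
  (nonresident), the recorded value `unknown` passes — registry address
  logic cannot be reproduced from anonymized records, and small
  unknown-region strata are legitimately part of cohorts.
* **History codes**: Z08, Z51.0, Z51.1, Z85 in the pre-diagnosis period
  are acceptable only alongside a known-site primary malignancy code
  (C00–C75, C81–C97) somewhere in that prior history; otherwise the
  patient may be a relapse of an unknown primary and is excluded.

## Comorbidity extraction

The look-back scan unions all 3-digit stems from admissions in
`[first_crc − lookback, first_crc]` plus the index admission, then filters:

1. chronic codes only (below);
2. ICD-10 chapters XV–XXII dropped, implemented as first letter in
   O–Z — at 3-digit granularity the letter test reproduces the chapter
   ranges exactly and is trivially auditable by regex;
3. C18–C21 dropped;
4. *index-only complications* dropped: codes in the complication set that
   appear at the index admission and nowhere in the look-back.  The default
   set maps the named complication groups to C77–C79 (secondary
   malignancy), D50–D64 (anemias), E41 (marasmus), D70 (agranulocytosis),
   E70–E90 (metabolic disorders) and K56 (intestinal obstruction).  The
   named-condition-to-code mapping is a documented judgment call and fully
   overridable in `ExtractionSpec`.

The chronic classification ships as a curated, editable text file
(`src/pcnkit/data/chronic3.txt`) listing 3-digit stems and ranges, curated
under the rule that a 3-digit category counts as chronic when any of its
children is a chronic condition.  Users with access to an institutional
chronic-condition table can point `ChronicMap.from_file` at their own file;
unknown codes classify as not chronic and are collected for audit.

Both look-back endpoints are inclusive.  The 3-year sensitivity variant
uses the same spec with `lookback_years=3`; tests assert the cellwise
monotonicity (every 3-year cell is also set at 5 years).

## Prevalence statistics

* **Interval**: Wald, `p ± z·sqrt(p(1−p)/N)`, clipped to [0, 1].  Chosen
  because it reproduces every published prevalence/CI triple used as a
  worked example in the acceptance tests; Wilson is available behind
  `method="wilson"` for small-count work.
* **Panel screen**: a disease stays when a one-sided score test of
  H0: p = 1% (null-variance denominator) gives P < .025 in at least one
  subgroup.  An exact binomial oracle brackets the score test in tests.
* **Subgroup contrast**: symmetric relative difference
  `|p1−p2| / ((p1+p2)/2)` (the signed variant is also exposed; sign
  conventions follow group-1 − group-2 with group 1 ∈ {female, rural,
  rectal}).  Significance needs relative difference > 0.1 *and* a
  Bonferroni-adjusted two-proportion Z-test below α = .05, with m = size of
  the retained panel, not all codes ever seen.  *Enriched* additionally
  needs a ≥ 1.5× prevalence ratio ("≥ 0.5-fold increase").
* **Age trend**: Cochran-Armitage with scores 1..5 over the bands 18-49,
  50-59, 60-69, 70-79, ≥80; normal reference for the standardized
  statistic, one-sided (increasing) and two-sided p reported.  Written
  in-package because no installed library exposes the test directly; a
  permutation oracle validates it on small tables.
* **Age standardization**: direct, `Σ w_band · p_band` with weights from a
  caller-supplied standard population (by construction, the pooled cohort
  as standard leaves pooled prevalence unchanged).
* **Age-profile clustering**: K-means on the 5-dimensional band-prevalence
  vectors; k chosen by silhouette over k ∈ 2..8 unless fixed.  Rows are
  fitted in sorted-index order, making the result invariant to input row
  order; the k-selection criterion is configurable since no single
  criterion is canonical.
* **Rounding**: report percentages round half-up to one decimal (banker's
  rounding would not reproduce printed tables).

## PCN construction and metrics

Edge statistics are computed on all unordered pairs of non-empty columns:
cosine `n_ab/sqrt(n_a n_b)`, phi as the Pearson correlation of the binary
indicators (verified against a direct correlation oracle at 1e−12), and a
t test with df N−2; |phi| = 1 maps to p = 0 by convention; N < 3 is an
error.

The cosine cutoff is calibrated so that the cosine network and the
significant-phi network have the same number of edges: M = #(phi > 0 and
p < α), cutoff = M-th largest cosine.  Only *positively* correlated pairs
count (comorbidity is positive co-occurrence) and α defaults to 0.05
two-sided; both are config knobs.  Ties at the cutoff are all kept — the
realized edge count may then exceed M and is reported; with tie-free cosine
values the equality is exact and is asserted in tests.

Metrics: density 2|E|/(|V|(|V|−1)); degree median and IQR; average
neighbor degree over connected nodes; betweenness centrality on the
*unweighted* graph (the verbal definition counts shortest paths, not
weights), normalized; PageRank with damping 0.85 and the cosine as edge
weight; *important nodes* are those at or above the 90th percentile of
PageRank.  The degree tail is fitted by maximum likelihood to a shifted
exponential above a configurable threshold, with a parametric-bootstrap
Kolmogorov-Smirnov p (200 replicates by default).  Note the KS machinery
treats degrees as continuous; for small tails of integer degrees the
discretization inflates the statistic, so the fit is a descriptive check,
not a sharp test.

## Subgroup comparison

Per-subgroup PCNs re-run the >1% screen and the cutoff calibration inside
the subgroup — networks are independently constructed, which changes
comparability in a documented way (a subgroup's cutoff reflects its own
phi significance at its own N).  The union of two PCNs' edge sets is
partitioned into shared (|Δcosine| < 0.05), enriched in one side
(Δ ≥ 0.05), and unique to one side; the 0.05 default is approximately half
of the smallest comorbid strength a calibrated PCN retains, and is a config
knob.  Sex-axis comparisons first drop a configurable sex-specific disease
list (prostate/male genital, gynecological and breast codes, plus ovarian/
testicular dysfunction).  Structure comparison reports per-network
descriptives and one-sided Welch t-tests (α = .025) on per-node degree and
neighbor-degree vectors, defaulting to all nodes (a flag restricts to
connected nodes); degenerate edgeless networks are described but excluded
from testing, and zero-variance vectors short-circuit to t = 0, p = 0.5
when equal.

## Synthetic record generator

The generator emulates the structure of longitudinal discharge data for a
single-year incident CRC cohort:

* **Subgroup mix** (defaults): sex 58.9% male; region 54.0% rural / 45.7%
  urban / 0.3% unknown; site 44.1% colon / 52.5% rectum / 2.7% anus / 0.7%
  multiple; age bands 11.4 / 18.7 / 28.1 / 29.0 / 12.8% across 18-49
  through ≥80 — the composition observed in large provincial CRC cohorts.
* **Disease panel** (defaults): 22 chronic conditions with realistic
  prevalences (hypertension 29%, prostate hyperplasia 22% male-only, COPD
  14.2% male-skewed, diabetes 12.5%, …), age-rising risk ratios for
  degenerative conditions and subgroup risk ratios for the planted
  sex/region/site effects.
* **Associations**: vertex-disjoint pairs sampled jointly at a target odds
  ratio.  Given marginals `pa, pb` and odds ratio ψ, the joint cell p11 is
  the root of the standard quadratic `ψ(pa−p11)(pb−p11) =
  p11(1−pa−pb+p11)`; sampling draws A then B from its exact conditional.
  The vertex-disjoint restriction keeps the generator exact without
  specifying a full joint distribution; overlapping pairs are rejected at
  validation.  Because the odds ratio is planted *within* each
  subgroup/age cell, the recorded "realized OR" truth is the
  Mantel-Haenszel common OR across cells (the pooled marginal OR is
  legitimately larger when both prevalences rise with age).
* **Admissions**: look-back admission count is Poisson (mean 2.5 — a
  configurable convention, not calibrated to any published admission
  histogram) with dates uniform in the 1826 days before the index
  admission; the index admission is uniform in the final study year and
  carries the sentinel C18–C21 code.  Each latent disease is coded on at
  least one uniformly chosen look-back admission, sometimes duplicated,
  and with probability 0.5 also at the index admission — extraction must
  deduplicate anyway.
* **Contaminants** are mutations of valid patients, generated at
  configurable rates: a C18 admission planted in the first study year
  (prevalent case), a bare Z85/Z51.x/Z08 in the look-back with primary
  C-codes stripped from that admission, a flipped sex field, an under-18
  age, or a complication code injected at the index admission only (this
  last one does not exclude the patient; it must vanish from the
  comorbidity matrix).  Every patient's latent disease vector and intended
  disposition are written to a JSON-lines truth file, enabling closed-loop
  tests: the cohort stage must exclude each contaminant for exactly its
  recorded reason, and the extracted comorbidity set of every included
  patient must equal the latent truth.

What the generator does **not** model: coding noise and miscoding,
outpatient records, hospital-level clustering, costs and lengths of stay
beyond a uniform 2–14 days, non-stationary incidence, and correlations
beyond the planted vertex-disjoint pairs.  Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration under
known truth — not that real discharge data meet these assumptions.

## Problem sizes and runtime choices

The test suite and the acceptance script size their simulations so a full
run completes in minutes on a single CPU: the end-to-end study uses 10,000
patients (yielding ~9,200 cohort members), the planted-pair recovery
experiment uses 20,000-patient cohorts with 12 diseases (20 seeds in the
test suite, 5 in the script), oracle equivalences use 1,000 random
matrices and dozens of small graphs.  These sizes put Monte-Carlo error
well inside the asserted tolerances; all tolerances (4 binomial/log-OR
standard errors for calibration, 1e−12 for the phi oracle, 1e−8 for
PageRank, twice the nominal α for null-edge rates) are stated in the tests
next to their assertions.

## Known limitations

* The chronic-condition table is a curated default, not an institutional
  standard; results shift with the classification used.
* The Wald interval degrades for very rare conditions (n close to 0); use
  the Wilson option there.
* Betweenness and PageRank are computed on each PCN as constructed;
  cross-subgroup comparability of centrality is limited because cutoffs
  are calibrated per subgroup.
* The degree-tail KS check treats integer degrees as continuous (see
  above).
* `identify_new_cases` assumes the record set covers the full washout
  before the diagnosis year; it does not model left-truncation.
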