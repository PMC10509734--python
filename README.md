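# pcnkit

Comorbidity-pattern analysis for newly diagnosed colorectal cancer (CRC)
cohorts built from longitudinal hospital discharge records: cohort
construction, chronic-comorbidity extraction, prevalence and enrichment
statistics, and phenotypic comorbidity networks (PCNs) with subgroup
comparison.

## The problem

Patients newly diagnosed with CRC frequently carry other chronic
conditions, and those conditions do not occur independently: hypertension
travels with ischemic heart disease, COPD with heart failure, diabetes with
lipoprotein disorders.  Classic comorbidity indices (Charlson, Elixhauser)
compress this structure into a score over a dozen conditions.  `pcnkit`
instead analyzes the *entire spectrum* of chronic ICD-10 diagnoses at
3-digit granularity and represents their co-occurrence as a weighted
network, so that disparities between subgroups (sex, age at diagnosis,
urban/rural residence, colon/rectum site) can be read off both single-
disease prevalences and pairwise coexistence strengths.

Because real provincial discharge data cannot be redistributed, the package
ships a first-class synthetic record generator with known ground truth
(planted prevalences, planted pairwise odds ratios, planted near-miss
exclusion cases), which makes every stage of the pipeline testable
closed-loop.

## The method

**Cohort.** A *new case* is a patient whose earliest C18–C21 admission
falls in the diagnosis year with no CRC code in the preceding 5-year
washout.  The *index hospitalization* is the earliest admission within 28
days after the first CRC diagnosis.  Patients under 18, with inconsistent
sex, without a recorded region, or with a bare cancer-history code (Z08,
Z51.0, Z51.1, Z85) and no known-site primary malignancy are excluded.

**Comorbidities.** Admissions in the 5-year look-back plus the index
admission are scanned; codes are truncated to 3 digits, filtered to chronic
conditions, stripped of ICD-10 chapters XV–XXII and of C18–C21, and a
configurable set of CRC-complication codes (secondary malignancy, anemias,
marasmus, agranulocytosis, metabolic disorders, intestinal obstruction) is
dropped when first seen at the index admission.  The result is a binary
patients × diseases matrix with column sums `n_a` and cohort size `N`.

**Edges.** For each disease pair *(a, b)*:

```
cosine_ab = n_ab / sqrt(n_a · n_b)
phi_ab    = (N·n_ab − n_a·n_b) / sqrt(n_a·n_b·(N−n_a)·(N−n_b))
t         = phi_ab · sqrt(N−2) / sqrt(1 − phi_ab²)     (df = N−2)
```

The cosine index measures comorbid strength independent of cohort size;
the phi coefficient (Pearson correlation of the binary indicators) supplies
significance.  The cosine cutoff is *calibrated*: if M pairs have
significantly positive phi, the cutoff is the M-th largest cosine value, so
the cosine network and the significant-phi network have equal edge counts.
Network structure is summarized by density, degree median (IQR), average
neighbor degree, betweenness centrality, and cosine-weighted PageRank
(damping 0.85, top decile = most important comorbidities).

**Subgroups.** Per-subgroup PCNs are built independently (own prevalence
screen, own cutoff).  Edges are partitioned into *shared* (|Δcosine| <
0.05), *enriched* (both networks, |Δcosine| ≥ 0.05) and *unique*; enriched
plus unique edges are the *abundant connections* of a subgroup.

## Worked example

```python
from pcnkit import synthdata
from pcnkit.cohort import records_from_frame, build_timelines, identify_new_cases
from pcnkit.comorbidity import build_matrix
from pcnkit.network import pairwise_stats, calibrate_cosine_cutoff, build_pcn, network_metrics
from pcnkit.prevalence import prevalence_ci, percent

rs = synthdata.generate_population(synthdata.default_config(5000, seed=1))
records, _ = records_from_frame(rs.to_frame())
tls = build_timelines(records)
cohort, excl = identify_new_cases(tls, 2020)
matrix = build_matrix(cohort, tls)
print(f"cohort: {len(cohort)} new cases ({len(excl)} excluded)")

est = prevalence_ci(int(matrix.data["I10"].sum()), matrix.n, code="I10")
p, lo, hi = est.as_percent()
print(f"hypertension (I10): {est.n}/{est.total}, {p}% (95% CI {lo}%-{hi}%)")

st = pairwise_stats(matrix)
cutoff = calibrate_cosine_cutoff(st)
pcn = build_pcn(st, cutoff)
m = network_metrics(pcn)
print(f"PCN: {pcn.number_of_nodes()} nodes, {pcn.number_of_edges()} edges "
      f"(cosine cutoff {cutoff:.3f}), density {m.density:.3f}")
print(f"most important (PageRank top decile): {', '.join(m.important_nodes)}")
```

prints

```
cohort: 5000 new cases (0 excluded)
hypertension (I10): 1456/5000, 29.1% (95% CI 27.9%-30.4%)
PCN: 22 nodes, 28 edges (cosine cutoff 0.111), density 0.121
most important (PageRank top decile): I10, J44, E11
```

The 5,000 simulated patients all pass the filters (no contamination was
configured); hypertension lands at its planted ~29% prevalence with a Wald
interval; the calibrated PCN keeps 28 edges — exactly the number of
significantly positive phi pairs — and flags hypertension, COPD and
diabetes as the network's most influential nodes.

The same pipeline is available from the shell:

```sh
pcnkit all --out run --seed 1 --n-patients 5000
```

which writes the cohort, exclusion log, comorbidity matrix, prevalence and
subgroup-difference tables, the PCN (GraphML + edge list), network metrics,
abundant-connection and structure-comparison tables, and a run manifest.

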