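# Methods

## The cohort model

The unit of analysis is an elderly (75+) primary-care patient described by
five categorical variables — age class (75–79 / 80–84 / 85–89 / 90+),
gender, marital status (Married / Unmarried / Widowed), family status
(NoCriticalFamily / ElderlyCouple / ElderlyCaregiver / LivingAlone /
ElderlyInstitutionalized) and the GP frailty status (NF / PFSN / PFHN / FR)
— plus fourteen dichotomous clinical categories derived from the ICD-9-CM
diagnoses of hospital discharges in the 12 months before the index date.
The real registry behind this design is privacy-restricted, so the package
treats the *published conditional prevalence structure* as the ground truth
and samples synthetic cohorts from it.

### Generator

Sampling order per patient: gender → age class | gender → frailty |
(age, gender) → marital and family status | (frailty, gender) →
hospitalization | frailty → multi-morbid vs single-category profile →
category set → discharge record(s). All draws come from one
`numpy.random.Generator` seeded by `(seed, attempt)`, so output is
byte-identical for a fixed config.

Calibration of the default config (`data/default_cohort.yaml`):

- **Known margins** are encoded directly: frailty by age class, frailty by
  gender, hospitalization per status (0.142 / 0.157 / 0.229 / 0.235),
  multi-morbidity per status (0.067 / 0.096 / 0.130 / 0.144, converted to a
  rate conditional on hospitalization by dividing by the hospitalization
  rate), and the sixteen named-profile rates whose per-status sums close
  the multi-morbidity budget.
- **Joint frailty by (age, gender)** is not published; the default
  factorizes `p(f|a,g) ∝ p(f|a)·p(f|g)/p(f)` and renormalizes each cell.
  This reproduces both published one-way margins approximately (exactly
  under independence) and is overridable.
- **Gender split and age-by-gender**: the overall female share (0.597)
  follows from requiring the by-gender frailty rows to mix to the overall
  row. The age marginal [0.40, 0.30, 0.20, 0.10] is the (essentially
  unique) solution making the frailty-by-age rows mix to the overall
  frailty margin; per-gender age rows tilt women older while preserving
  that marginal.
- **Marital/family conditionals** are unpublished; the defaults are
  calibrated stand-ins that reproduce the qualitative associations the
  analysis is supposed to recover (FR/PFSN skew toward Widowed,
  LivingAlone and ElderlyInstitutionalized; NF toward Married and
  NoCriticalFamily), with all weights in the YAML config, not in code.
- **Injury and poisoning** single-category weight is boosted to 0.55 for
  hospitalized PFSN/FR women, emulating the dominance of injury-related
  single-diagnosis admissions in the socially frail female stratum.
- **Codes**: each category carries a short list of toy 3-digit ICD-9-CM
  roots (licensed grouper tables are out of scope); emitted codes append a
  random decimal subcode so the longest-prefix matcher is exercised.

A coverage guard applies to cohorts of ≥ 5,000 patients: the whole cohort
is resampled (deterministically, next sub-seed) until every reachable
modality occurs at least once, and a `CoverageError` after five attempts
signals a degenerate configuration. Below that size coverage is not
enforceable and the guard is off.

What the generator does *not* emulate: within-patient correlation beyond
the profile table (diseases are drawn per admission, not accumulated over a
life course), repeat admissions (one discharge per hospitalized patient by
default; `discharges_per_patient` splits the category set over several),
seasonality of admission dates (uniform over the window), and any
continuous covariates. Passing recovery tests therefore demonstrates that
the pipeline inverts the generator's conditional structure — not that real
registry data would show the same communities.

## Record linkage

Exact join on the de-identified patient code; duplicate registry ids abort
(they violate the de-identification contract). The discharge window is
half-open, `[index − 365 d, index)`, with the index date 2007-01-01 by
default. Main and secondary diagnoses are treated identically. Codes are
grouped by longest-prefix match after stripping the decimal point;
unmatched codes are collected and counted, never turned into an "other"
category. The flag table preserves registry row order and row count
regardless of discharge content.

## Network construction

One patient node per row; modality nodes only for *observed* modalities, so
a full cohort yields `n + 32` nodes (28 characteristics + 4 frailty
statuses). Patient–modality edges have weight 1; modality–modality edges
carry the co-occurrence count. The graph is a weighted simple graph rather
than a multigraph — co-occurrence multiplicity lives in the weight, and an
`unweighted=True` build collapses all weights to 1. Patient–patient edges
and self-loops are structurally impossible. Exports: GEXF 1.3, GraphML and
a nodes/edges CSV pair that round-trips losslessly.

## Centralities

- **Degree** is the raw incident-edge count; weights are ignored.
- **PageRank** runs power iteration with damping 0.85 (the common default,
  overridable), weight-proportional transitions, uniform teleport, dangling
  mass spread uniformly, and an L1 stopping tolerance of 1e-10; values sum
  to 1 and non-convergence raises with the residual.
- **Betweenness** uses Brandes' accumulation over *unweighted* shortest
  paths by default — co-occurrence weights are similarity counts, not
  distances — with endpoints excluded and undirected pairs halved;
  `weighted_paths=True` switches to Dijkstra over distance `1/w`, and
  `normalized=True` divides by `(n−1)(n−2)/2`.

## Community detection

Modularity uses the weighted Newman–Girvan form; the single-community
partition gives exactly 0, and an edgeless graph raises (the `W = 0`
denominator makes Q undefined). The optimizer is the classic two-phase
scheme: greedy single-node moves (sweep order shuffled by the seeded RNG,
ties between equal gains resolved to the lowest community label so runs are
reproducible), then aggregation into a weighted super-graph with
self-loops, iterated until no move improves Q by more than 1e-12. Because
a single greedy pass can stall in a local optimum on small graphs, the
optimizer performs 8 independent restarts (sub-seeds spawned from the main
seed) and keeps the best-Q partition; on random graphs with up to 8 nodes
this matches the exhaustively enumerated optimal partition in ≈ 96–99 % of
seeded trials. Resolution is fixed at 1.0 by default and exposed.

## Decile scoring

`score(v) = min(10, 1 + floor(10 · #{u : value(u) < value(v)} / N))` — an
empirical-CDF cut into tenths where ties share the lower score, chosen
because it is deterministic and order-independent. Totals range 3–30 and
deviation = 30 − total ranges 0–27. The decile population defaults to the
*modality nodes*: modality nodes are hubs connected to hundreds of
patients, so against the full node population every modality lands in the
top decile of every measure and all deviations degenerate to zero, which
would make the community comparison vacuous. `deciles_over="all"` retains
the whole-population variant for sensitivity analysis. Community-level
centrality is summarized as the mean deviation over the community's
modality nodes; patient nodes are excluded, and a community with no
modality nodes reports NaN.

## Reporting

The composition matrix is emitted under both normalizations — row
percentages per frailty status (each status row sums to 100) and the
frailty mix within each community — since either reading may be wanted.
Multi-morbidity profiles are keyed by the exact flagged category set;
the fifteen named profiles are reported individually and all remaining
sets aggregate to "Other multi-morbid profiles". The prevalence ratio of a
community is its multi-morbid proportion over the whole cohort's, × 100.

## Problem sizes and test design

Tests exercise full-size cohorts (n = 24,000) where the claim is about the
cohort itself (margin recovery within 3 binomial SE, chi-square
goodness-of-fit at α = 0.001 across five seeds, the 24,028-node
arithmetic), and smaller cohorts (150–6,000) where the claim is structural
(linkage round-trips against the generator's own draw log, brute-force
co-occurrence weights, community recovery across seeds). Exact betweenness
is O(n·m) and is the one expensive stage on full cohorts; pipeline-level
tests that do not assert on betweenness disable it, and the
`--no-betweenness` CLI flag does the same. Oracles are brute-force
enumerations (simple-path censuses, dense linear solves, exhaustive set
partitions) plus networkx as an independent reference implementation.

## Known limitations

- The factorized frailty joint is an assumption, not an estimate; real
  age-gender-frailty interaction terms are unavailable.
- The published community structure of the real registry (its Q, its four
  communities, its exact deviations) is not a reproduction target: it
  depends on unavailable raw data and on unrecorded tool settings. The
  package claims recovery of *generated* structure only.
- The clinical vocabulary defaults to the 14 categories the analysis
  tabulates; the grouping layer accepts any root→category file for other
  vocabularies.
- Exact betweenness on a 24,000-patient graph is computationally heavy in
  pure Python; rank-level results on modality nodes are stable under the
  sparser measures, but no approximate-betweenness sampler is provided.
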