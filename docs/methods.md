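# Methods

## Problem and model

The package maps the cancer-context sub-interactome of a fixed set of
metabolic target enzymes — here the seventeen enzymes catalyzing the
multi-step transformation of cholesterol precursors.  The object of
interest is the set of direct physical protein partners of each enzyme,
assembled from many partially overlapping interaction databases, then
narrowed and annotated with tumor-specific evidence.  Four statistical
primitives carry the analysis: a consensus vote across source
databases, a compartment-overlap test, tumor/normal fold-change and
Pearson co-expression statistics, and median-split survival models.

## Consensus selection (round 1)

Each source database ("browser") is an entry in a registry carrying its
parsing dialect and its own confidence policy: an exclusive
`min_confidence` bound (browsers publish these as "score > x"), an
allowed-evidence term set, or a minimum publication count.  A record is
kept iff it satisfies every threshold of *its own* source; sources with
no stated policy accept everything.  After normalizing both interactors
to canonical gene symbols through a user-supplied mapping table
(unmapped records are excluded and reported, never passed through raw),
an enzyme–partner pair is retained when it is asserted by at least
`min_sources` distinct browsers (default 3; duplicate assertions within
one browser count once).  Browsers are treated as independent even
where they index the same primary experiments, because the selection
rule is defined at the browser level; the threshold is configurable for
sensitivity analysis.  The consensus rule is applied per
(enzyme, partner) pair.  Self-interactions are excluded by default
(`keep_self` retains them); edges between two target enzymes are kept
and flagged rather than dropped, since pathway enzymes may physically
cluster, and such pairs are anchored on the lexicographically smaller
enzyme so input orientation can never change the output.

## Localization concordance (round 2)

Compartment annotations are flat term sets from a controlled vocabulary
with a synonym map ("ERM" → "endoplasmic reticulum membrane"); loading
fails loudly on any term outside the vocabulary.  "Similar
localization" is operationalized as non-empty compartment intersection
(the `overlap` policy); a stricter `membrane_system` policy additionally
requires a shared membrane term when both proteins are membrane
proteins.  No ontology traversal is performed — the filter stays at the
annotation granularity of its inputs and is therefore fully auditable.
Edges whose partner lacks a profile default to `keep_with_flag`:
annotation-coverage gaps are surfaced, not silently destructive.  The
package ships the compartment profiles of the seventeen enzymes; twelve
are membrane proteins (≈ 70 %) and five (MVK, PMVK, MVD, FDPS, LSS) are
soluble (≈ 30 %).

## Network classification

Partners are classified by the number of distinct enzymes they bind:
`unique` (= 1, List A) versus `common` (≥ 2), with connector tiers
tier2 (= 2) and tier3plus (≥ 3).  List B is the union of unique and
common partners.  The common threshold is configurable because
different studies draw the unique/common line differently.  Venn cells
are enumerated sparsely (only occupied membership patterns), keeping
the partition linear in the partner count for up to 30 enzymes.
Exports (SIF, GraphML, edge TSV) are round-trip safe; SIF retains
topology only, by the nature of the format.

## Differential expression and co-expression

Fold change is computed from pseudo-counted group medians on the linear
scale: with values stored as log2(x + 1) and pseudo-count 1, FC reduces
exactly to 2^(difference of log-scale medians), so the statistic is
monotone, order-invariant and swaps to its reciprocal under label
exchange.  Significance uses a two-sided Mann–Whitney test on the log2
matrix (robust to the heavy right tails of TPM-scale data; Welch's t is
available behind a flag).  A gene is a DEG when FC ≥ 3 and p ≤ 0.01;
BH q-values are reported for context but the gate uses the raw p — the
FC condition dominates selection in practice.  Co-expression tasks
exist only for (enzyme, partner, cohort) triples where the enzyme is a
DEG in that cohort.  Pearson R is computed over tumor samples by
default (the question is about the tumor state; pooling tumor and
normal samples would manufacture correlation from the group shift) and
banded with closed lower bounds: |R| < 0.4 none, 0.4 ≤ |R| < 0.6
average, |R| ≥ 0.6 strong; R ≤ −0.4 carries a negative flag.  Values
above the nominal 0.7 upper edge of the strong band remain "strong" —
there is no category above it, and any other choice would discard
information.  No multiplicity adjustment is applied to co-expression by
default, matching the raw-cutoff screening design; a BH option exists.

## Survival screening

Samples are dichotomized at the median score with ties assigned to the
low group (deterministic, and preserves the 50/50 intent).  The
Kaplan–Meier estimator, the two-group log-rank test (hypergeometric
variance at each distinct event time, two-sided p from χ²₁) and the
binary-covariate Cox model are implemented in the package; the Cox fit
is a Newton iteration on the Breslow partial likelihood (score
tolerance 1e−8, ≤ 50 iterations), with the 95 % CI from observed
information.  Breslow tie handling is the simplest consistent choice;
numeric parity with any specific web tool is not promised.  Monotone
likelihoods (all events on one side) return a flagged infinite-HR
result instead of crashing.  Signature scores are per-sample means of
log2 expression over the signature genes present.  Two gates are
reported per unit and cohort: `passes_default` (BH q ≤ 0.05 across
units) and the strict filter, raw p < 0.001 ∧ (HR ≤ 0.5 ∨ HR ≥ 2)
∧ n ≥ 200 — the strict gate deliberately uses the raw p, which is how
the strictest selection is defined in this screening design.  A hazard
ratio of 0.4 for the high-expression group reads as a 2.5-fold higher
mortality hazard in the low-expression group.  Times are months
throughout; day-scale inputs are converted at load.

## Enrichment and annotation

ORA p-values are the upper hypergeometric tail P(X ≥ k) for overlap k
between the query and a term of size K in a universe of size N
(identical to the one-sided Fisher exact test, which the test suite
uses as an independent oracle).  The universe defaults to all genes the
collection annotates, configurable to a user list, because background
choice is a known free parameter of ORA.  Per-collection raw-p gating
(no FDR) is available for sources conventionally screened that way.
The modifying-protein class map (kinases, phosphatases, ubiquitin
ligases, deubiquitinases, proteases) is shipped as an editable curated
table — the literature-described core plus close family members — with
no automated family inference; unmapped partners classify as "none".
Cancer-driver and essential-gene flags derive only from supplied
tables, never from hard-coded lists.  BH adjustment is the standard
step-up procedure (statsmodels), order-preserving with q ≥ p.

## Synthetic data: what it emulates and what it does not

The generator suite emulates the full input surface: per-source edge
tables in both dialects, a localization table, log2(TPM+1)-scale
tumor/normal matrices, survival tables and GMT collections.  Design
choices that make the recorded truth an *exact* oracle:

- Planted consensus edges are forced into ≥ `min_sources` randomly
  chosen sources and reported by the others with `detection_prob`;
  noise pairs are drawn without replacement from the non-planted pairs
  and confined to ≤ `min_sources` − 1 sources, so no noise edge can
  ever reach the threshold.  `noise_edge_rate` is the expected number
  of spurious assertions per source.
- Concordant partners receive one compartment from *each* enzyme they
  bind (so a full concordant fraction passes every edge); discordant
  partners receive compartments disjoint from all of their enzymes.
  The realized concordant edge set is evaluated explicitly and
  recorded, so the oracle stays exact even under partner reuse.
- Expression noise is homoscedastic normal (sd 1) on the log2 scale;
  DEG genes shift the tumor mean by log2(FC), which the median-ratio
  statistic recovers exactly in expectation; correlated pairs are drawn
  bivariate-normal at the target ρ among tumor samples, one pair per
  gene per cohort.
- Survival times are exponential (hazard λ low group, λ·HR high group)
  with scores well separated across the median so the split recovers
  the planted groups; censoring is administrative-uniform on
  [0, t_max], with t_max solved by bisection from the closed-form
  censoring probability to meet the configured fraction.
- Each generator draws from its own stream (master seed + fixed
  offset), so outputs are reproducible and mutually independent.

Default study conditions: 17 enzymes, 13 sources, threshold 3,
detection probability 0.9, five spurious assertions per source, five
cohorts with tumor/normal sizes 118/339 (THYM), 92/318 (READ), 179/171
(PAAD) and 100/100 for the two cohorts whose sizes are not fixed by the
study design, five enzymes planted as DEGs at FC 3.2–4, and a survival
cohort of 1000 samples at HR 0.4 with 30 % censoring.  Correlated pairs
are planted per experiment because their identities depend on the
chosen edge set.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: TCGA batch effects and library-size
artifacts, negative-binomial count noise, heteroscedasticity,
confounded censoring, non-proportional hazards, identifier ambiguity
beyond simple aliasing, and correlated redundancy between source
databases (real browsers share IMEx records; the independence of the
consensus vote is an assumption of the screening design, not a fact the
synthetic data can test).

## Numerical and degenerate-input choices

Constant genes give p = 1 (no evidence) rather than an error; zero
variance in a correlation returns a flagged degenerate result with band
"none"; a constant score vector makes the median split a configuration
error; a screen unit whose fit degenerates is carried with NaN
statistics and both gates false.  Band boundaries are closed from
below.  Cox iteration escaping |β| > 50 is reported as an infinite-HR
monotone-likelihood result.  All file formats are plain text; the
report bundle carries a manifest with config hash, seed, row counts and
sha256 checksums, and a rerun with the same config and seed reproduces
identical checksums.

## Problem sizes used in verification

The recovery and calibration checks run at deliberately compact sizes
chosen to make Monte-Carlo error small relative to the tested margins:
consensus oracle fixtures of ≤ 500 records over 13 sources (20
fixtures), DEG recovery at 100/100 samples over 20 seeds, band recovery
at 200 tumor samples over 20 seeds per ρ, the Cox envelope at n = 1000
(reported as the geometric mean over 20 replicates), the log-rank size
over 1000 null replicates at n = 200, and 50 random ORA/Fisher
configurations.

## Known limitations

The unique/common partner arithmetic of a published screen is not in
general derivable from its text; the classification threshold here is
explicit and configurable instead.  The consensus rule has a per-pair
and a per-partner reading; the package implements per-pair and exposes
the distinction rather than guessing.  GEPIA2-style tools do not
document their exact DEG test or Cox tie handling, so numeric parity
with any specific web service is out of scope; the implementations here
are the standard textbook estimators, cross-checked against independent
libraries in the test suite.
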