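# sterolnet

Cancer-context sub-interactome mapping for the seventeen enzymes of the
cholesterol biosynthesis pathway (HMGCR, MVK, PMVK, MVD, FDPS, FDFT1,
SQLE, LSS, DHCR24, CYP51A1, TM7SF2, MSMO1, NSDHL, HSD17B7, EBP, SC5D,
DHCR7).

The package is aimed at systems-biology practitioners who want to map
the direct protein partners of a target-enzyme set from heterogeneous
PPI databases and then ask which of those interactions matter in
tumors.  It chains six analysis stages behind one configuration:

1. **Multi-source consensus (round 1).**  Interaction assertions are
   parsed from PSI-MITAB 2.5 or plain TSV exports of a registry of 13
   interactome browsers, filtered by each browser's own confidence
   policy (e.g. HIPPIE score > 0.6, BioPlex interaction probability
   > 0.9, FunCoup confidence > 0.9, APID ≥ 1 publication), normalized
   to canonical gene symbols, and an enzyme–partner edge is kept iff it
   is asserted by at least *k* = 3 independent browsers.
2. **Localization concordance (round 2).**  An edge survives only if
   enzyme and partner share at least one annotated subcellular
   compartment (NextProt-style terms with a synonym map).
3. **Network classification.**  Partners bound by one enzyme are
   *unique* (List A); multi-enzyme partners are *common* connectors
   (tier2 = two enzymes, tier3plus = three or more); exports in SIF,
   GraphML and TSV.
4. **DEG-conditioned co-expression.**  A gene is a DEG when the
   pseudo-counted tumor/normal median fold change satisfies FC ≥ 3 with
   p ≤ 0.01 (two-sided Mann–Whitney on the log2(TPM+1) matrix).
   Pairwise Pearson co-expression is computed only in cohorts where the
   enzyme is a DEG and banded as average (0.4 ≤ |R| < 0.6) or strong
   (|R| ≥ 0.6), with negative correlations (R ≤ −0.4) flagged.
5. **Prognostic screening.**  Median-split Kaplan–Meier curves,
   two-group log-rank tests and binary-covariate Cox hazard ratios
   (Breslow ties, Newton iteration), with a BH-FDR default gate
   (q ≤ 0.05) and the strict filter p < 0.001 ∧ (HR ≤ 0.5 ∨ HR ≥ 2)
   ∧ n ≥ 200.  Multi-gene signatures are scored as the per-sample mean
   log2 expression.
6. **Enrichment and annotation.**  Upper-tail hypergeometric ORA
   against GMT collections with BH adjustment, curated
   modifying-protein classes (kinases, phosphatases, ubiquitin ligases,
   deubiquitinases, proteases), and cancer-driver / common-essential
   flags from user-supplied tables.

A first-class synthetic-data module generates all inputs with planted,
recorded ground truth — consensus edges forced into ≥ *k* sources with
noise confined below the threshold, fold changes, Pearson correlations
and hazard ratios at their target values — so every stage has an exact
or statistical recovery test without any external download.

## Worked example

```python
from sterolnet import SyntheticConfig, PipelineConfig, generate_inputs, run_pipeline

cfg = SyntheticConfig(
    seed=1, n_partners=60, detection_prob=1.0, noise_edge_rate=3.0,
    concordant_fraction=1.0,
    planted_consensus_edges=[("SQLE", "PTN0001"), ("SQLE", "PTN0002"),
                             ("EBP", "PTN0003"), ("MVK", "PTN0004"),
                             ("EBP", "PTN0001"), ("HMGCR", "PTN0005")],
    planted_rho={("SQLE", "PTN0001", "THYM"): 0.65,
                 ("EBP", "PTN0003", "THYM"): -0.45},
)
generate_inputs(cfg, "ex/in")
bundle = run_pipeline(PipelineConfig(input_dir="ex/in", output_dir="ex/out", seed=1))
```

Output (abridged):

```
network: {'n_enzymes': 4, 'n_partners': 5, 'n_unique': 4, 'n_common': 1, 'tiers': {'tier2': 1, 'none': 4}}
retrieval grand total: 32
DEGs called: 23 of 110 gene x cohort tests
enzyme partner cohort      r    band  negative
   EBP PTN0003   THYM -0.414 average      True
  SQLE PTN0001   THYM  0.552 average     False
 unit cohort    n    hr  logrank_p  passes_strict
score   SURV 1000 0.427        0.0           True
     term  k  K            p            q
T_PLANTED  4 10 1.799288e-08 8.996438e-07
```

Reading this: 32 raw enzyme–partner pairs were retrieved across the 13
sources; the six planted edges survive the two selection rounds and
PTN0001, bound by both SQLE and EBP, is classified as a tier2
connector.  The five enzymes planted as DEGs (FC 3.2–4) are recalled in
the five cohorts, which licenses the co-expression tasks: the planted
negative correlation in THYM is recovered with its flag, and the
positive pair lands at R = 0.55 (the planted 0.65 minus sampling noise
at 118 tumor samples).  The survival unit planted at HR = 0.4 is
estimated at 0.427 and passes the strict prognostic filter, and the
planted gene-set term tops the enrichment table at q ≪ 0.05.

The same flow is available from the shell:

```sh
sterolnet generate --seed 1 --out ex/in
sterolnet run --inputs ex/in --out ex/out --seed 1
```

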