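# mendiag

A toolkit for molecular diagnosis of Mendelian diseases from targeted
gene-panel sequencing.  It implements two methods used downstream of variant
calling on a clinical panel:

* **MPPS** — an ensemble pathogenicity classifier for nonsynonymous SNVs
  that combines 17 published deleteriousness scores (PolyPhen-2 HDIV/HVAR,
  MutationTaster, SIFT, LRT, FATHMM, MutationAssessor, M-CAP, PROVEAN,
  VEST3, MetaSVM, MetaLR, fathmm-MKL, CADD, DANN, GERP++, phyloP100way).
* **AADSM** — an automated annotation-and-diagnosis pipeline that filters a
  patient's VCF, scores the surviving variants, ranks candidate Mendelian
  diseases against the patient's phenotype terms and writes JSON + HTML
  reports.

It is aimed at clinical bioinformaticians who have per-variant raw scores
(e.g. from a dbNSFP-style annotation) and want a reproducible, auditable
prioritization, plus the evaluation statistics (accuracy, Prediction
Coverage, genotype concordance) used to validate such pipelines.

## The ensemble

Individual deleteriousness predictors are unreliable in different parts of
the genome and frequently emit no score at all.  The ensemble addresses both
problems:

1. **Region weights.** From a truth set of pathogenic and neutral variants,
   each tool *t* gets, per genomic bin *r* (10 Mb by default), a weight
   `w_dmg(t, r)` — the fraction of truth-pathogenic variants in *r* that it
   calls on the damaging side — and analogously `w_ben(t, r)` over
   truth-neutral variants.
2. **Trio selection.** For a query variant in region *r*, the 3 tools with
   the highest `w_dmg` and the 3 with the highest `w_ben` form the damaging
   and benign trios.
3. **Weighted categorical score.** Each tool's raw score maps to a category
   with points p ∈ {damaging: +10, possibly damaging: +5, unclassified: 0,
   possibly benign: −5, benign: −10}; a trio's score is
   `Σᵢ wᵢ pᵢ / Σᵢ wᵢ ∈ [−10, +10]`.  Conserved positions (GERP++ and
   phyloP100way both above threshold) receive +1, clamped at +10.
4. **Iterative agreement.** If both trio scores agree in sign (|score| ≥ 1),
   the variant is classified; otherwise the next-best rank triple of tools
   is tried, up to 5 rounds over the 15 functional predictors.  A variant
   on which no round agrees is flagged *mis-classified* but still classified
   by the fall-back rule, so Prediction Coverage — predicted variants over
   variants evaluated — is 100% by construction.

The disease ranking in AADSM scores each candidate disease as
`variant_support · (1 + phenotype_match) + 2 · [inheritance consistent]`,
where `variant_support` is the best variant score in the disease's genes and
`phenotype_match` is the fraction of the disease's phenotype terms the
patient shows.

## Worked example

Simulate a labeled benchmark, fit region weights, classify, and benchmark
every tool against the ensemble:

```bash
mendiag simulate --preset benchmark --seed 7 --out demo --n-pathogenic 300 --n-neutral 300
mendiag mpps-fit --truth demo/truth.tsv --vcf demo/benchmark.vcf \
    --tools demo/tools.tsv --out demo/weights.tsv --seed 7
mendiag mpps-predict --vcf demo/benchmark.vcf --weights demo/weights.tsv \
    --tools demo/tools.tsv --out demo/predictions.tsv
```

which prints

```
fitted weights for 17 (region, tool) rows -> demo/weights.tsv
classified 600/600 variants -> demo/predictions.tsv
```

`600/600` is the ensemble's Prediction Coverage: every variant received a
damaging/benign classification even though each simulated tool withheld its
score for up to 30% of variants.  `demo/predictions.tsv` holds both trio
scores, the classification, the round at which the trios agreed and the
mis-classified flag per variant.

Diagnose a simulated patient end to end:

```bash
mendiag simulate --preset cohort --seed 8 --out cohort --n-patients 2
mendiag diagnose --vcf cohort/patients/P0000.vcf \
    --phenotypes cohort/patients/P0000.phenotypes.txt \
    --db cohort/db --out reports
```

```
P0000: 2 variants retained; top disease: Disease 63
```

The two retained variants are the patient's implanted compound-het causal
pair (all common background variants were filtered out); `reports/P0000.html`
shows the ranked diseases with the score components behind each rank, and
`reports/P0000.json` is the same report machine-readable.

The same operations are available as a library (`mendiag.mpps`,
`mendiag.aadsm`, `mendiag.evalkit`, `mendiag.synthdata`), including an
sklearn-style `MppsClassifier` with `fit`/`predict`.

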