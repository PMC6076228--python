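# Methods

This note records the models and procedures the package implements, the
defaults that matter, what the simulator does and does not emulate, and the
design choices made where the design was genuinely open.

## Ensemble pathogenicity classification

**Inputs.** Raw scores from 17 deleteriousness predictors per nonsynonymous
SNV.  The package never re-implements the predictors; their scores arrive
via a dbNSFP-style TSV or pre-attached to variant records.

**Categorical mapping.** Each raw score maps to one of five categories
(damaging / possibly damaging / unclassified / possibly benign / benign)
via per-tool thresholds.  Each tool carries a damaging cut-off and a benign
cut-off with a direction flag (SIFT, LRT, FATHMM and PROVEAN are
lower-is-damaging); scores between the cuts split at the midpoint into the
two "possibly" categories.  Defaults follow each tool's published operating
point (SIFT 0.05, PolyPhen-2 HDIV 0.957/0.452, CADD phred 20/10, M-CAP
0.025, FATHMM −1.5, PROVEAN −2.5, MetaSVM 0, DANN 0.96, …); every threshold
is overridable because no single operating point suits all panels.  An
absent score is always `unclassified` (0 points) — this is what makes
missingness harmless to coverage.

**Weights.** The weight of a tool in a region is the fraction of correct
predictions it makes there, on the 0–1 scale, computed separately over
truth-pathogenic variants (damaging-side weight) and truth-neutral variants
(benign-side weight).  Denominators are variants on which the tool emitted a
prediction; a tool silent in a region contributes no evidence rather than
counting as wrong — coverage is tracked as its own statistic.  Regions are
fixed 10 Mb bins keyed `(chrom, floor(pos / 10 Mb))`; a bin needs at least
`min_n = 50` predicted truth variants of each class for its own row,
otherwise it inherits the genome-wide fallback row (always present).  A
truth set containing a single class yields prior weights 0.5 for the
missing class, with a warning.  Both granularity and `min_n` are parameters;
the defaults trade regional resolution against weight variance (binomial
s.e. ≤ 0.07 at n = 50).

**Scoring.** Category points are damaging +10, possibly damaging +5,
unclassified 0, possibly benign −5, benign −10.  A trio's score is the
weight-normalized sum Σwᵢpᵢ/Σwᵢ, which stays inside [−10, +10] for any
weights (an unnormalized weighted sum would not); all-zero weights score 0.
The conservation bonus (+1, clamped at +10) applies when GERP++ ≥ 2.0 and
phyloP100way ≥ 1.6, both configurable; an absent conservation score means
not conserved.  The bonus is applied to both trio scores (a config switch
restricts it to the damaging side).

**Agreement protocol.** Round *r* uses the rank triple 3(r−1)+1..3r of the
15 functional predictors on each side, ranked by the side's weight with
alphabetical tie-breaks.  A side is decided when |score| ≥ 1 — scores inside
(−1, +1) are treated as noise, not evidence.  Agreement of both sides ends
the loop; five rounds exhaust the ranked list.  A variant with no agreeing
round is flagged mis-classified and receives the fall-back classification
sign((score_dmg + score_ben)/2) from round 1, with an exact zero resolving
to damaging — the conservative direction for a result a clinician will
review.  Every variant therefore gets an output, and batch prediction
coverage is 100% by construction; the mis-classified flag preserves the
distinction for anyone who wants the stricter reading of coverage.

**Conservation scores in trios.** GERP++ and phyloP100way are excluded from
candidate trios by default and reserved for the conservation bonus,
resolving their double role in the 17-tool list; a switch restores them to
the candidate pool.

## Diagnosis pipeline

**Filtering.** Variants at population allele frequency ≥ 0.01 are dropped
unless a curated DM/DM? class rescues them; synonymous variants are dropped
unless flagged within 2 bp of a splice site; with a panel manifest,
variants outside the captured intervals (exons ± 10 bp) are dropped.
Filtering removes common variants rather than down-weighting them: the
frequency penalty in the scorer exists for configurations that relax the
filter.

**Variant score.** Integer points, summed: rarity (absent or AF < 1e−4: 4;
< 0.005: 2; < 0.01: 1; ≥ 0.01: −6), variant type (whole-gene/multi-exon CNV:
4), consequence (nonsense/frameshift/splicing: 4; in-frame indel: 3;
missense: 2; synonymous: −4), curated class (DM: 4; DM?: 2; DP/DFP: 1), and
the ensemble call (damaging: +2; benign: −2).  The inputs to the score are
fixed by the method; the magnitudes are package defaults chosen to preserve
the intended rank drivers with a transparent scale, and are fully
overridable (`ScoringRules`).

**Disease rank.** For each disease with ≥ 1 scored variant in its genes:
`total = variant_support · (1 + phenotype_match) + 2 · [inheritance_consistent]`,
with `phenotype_match = |patient ∩ disease terms| / |disease terms|` (0 when
the disease has no terms), `variant_support` the best variant total among
the disease's genes, and inheritance consistency judged per mode — AR needs
two heterozygous hits in the gene or one hom/hemi; XL needs a hemi or hom
hit; AD any hit; unknown mode is never consistent.  Ties break by disease
id ascending, and the ranking is capped at `max_rank` (default 100).
Phenotype matching is exact term overlap — the database accepts any
controlled vocabulary (HPO ids included) and no ontology expansion is
attempted; this is the main place a production deployment would extend the
package.  The multiplicative combination makes phenotype evidence scale
variant evidence rather than compete with it; it is this package's own
formula.

**Reports.** One JSON document (round-trippable) and one HTML page per
patient, listing ranked diseases, ranked variants with score components,
and provenance (package version, config hash, timestamp — overridable for
byte-reproducible output).  HTML is rendered with stdlib templating.

## Evaluation statistics

Per-tool accuracy is the percentage of correct predictions over the truth
variants *with* a prediction (a flag switches to all-variants
denominators); Prediction Coverage is predicted/total · 100; both reported
rounded half-up to two decimals.  Benchmarks fit ensemble weights on a
seeded 50/50 split disjoint from the evaluation split, and refuse
overlapping splits unless resubstitution is explicitly allowed.  Genotype
concordance compares unordered allele pairs over the loci shared by two
call sets (phase ignored), with zero shared loci an error rather than a
vacuous 100%.

## Synthetic data

The simulator emulates: truth sets placed uniformly over a positional
genome (22 autosomes + X as integer intervals — no operation needs
nucleotide context); per-tool prediction profiles drawn conditionally
independently given the truth label, with per-tool (optionally per-region)
sensitivity/specificity, missingness, and softening to "possibly"
categories; raw scores back-computed at the midpoint of the target
category's threshold band so the categorical mapping inverts the simulation
exactly; gene–phenotype–disease databases whose diseases follow the
19-category panel proportions, with 1–2 genes, an inheritance mode and a
mostly-unique phenotype term set each; and patients carrying an implanted
causal variant honoring the disease's inheritance mode (absent from
population databases, curated DM) among common, curated-absent background
variants with AF in [0.01, 0.5] — removable by the default filter by
construction.

It does **not** emulate: realistic mutation spectra or linkage
disequilibrium, sequencing error, correlated tool errors (real predictors
share training data and features), shared phenotype terms between related
diseases, ontology structure, or incomplete penetrance.  Passing tests
therefore show the pipeline's logic is correct under its stated model —
weights recover generating accuracies, the ensemble beats its best
conditionally independent member, implanted diseases are recovered — not
that the same numbers would be achieved on real cohorts, where tool errors
correlate and phenotype vocabularies are noisy in structured ways.

## Problem sizes and numerics

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which the binomial error bands make the checks sharp:
2,000-variant benchmarks for coverage and accuracy recovery (s.e. ≈ 0.8
points at p = 0.85), 2,000 truth variants per class per region for weight
recovery (3-point tolerance ≈ 4 s.e.), and 100-patient cohorts for
implanted-disease recovery.  Scores are plain float64 arithmetic; the only
rounding anywhere is the half-up 2-decimal formatting of reported
percentages, done in exact decimal arithmetic.  Determinism: every
stochastic function takes a seed and is a pure function of (parameters,
seed); classification itself is fully deterministic.

## Known limitations

Exact-term phenotype matching (no ontology); no ACMG criteria engine; no
pedigree/trio joint analysis; CNV handling is whole-gene/multi-exon events
via symbolic alleles only; the panel manifest (gene list and intervals) is
user-supplied or synthetic; the category thresholds for several tools have
no single published consensus and should be revisited per deployment.
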