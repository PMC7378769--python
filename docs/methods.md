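# Methods

## Scope and data flow

The package analyzes somatic variant calls from tumor/matched-normal
panel sequencing of *TP53* (and hotspot loci of a small set of other
cancer genes) in a cohort of BRCA1/2-carrier HGSOC patients. Inputs are a
tumor VCF (or TSV), a matched-normal VCF, a per-sample metadata table
(pathology tumor-cell percentage, BRCA carrier gene, optional p53 IHC
staining percentage), plain-table annotation resources, and a
reference-cohort category-count table. The stages are: ingestion and
normalization → somatic retention filtering → GOF/LOF classification →
LOH/clonality inference → IHC concordance → cohort summary and reference
comparison. Each stage is a pure function over explicit data structures;
the CLI and `run_pipeline` only compose them.

## Variant identity and HGVS normalization

Variants are keyed by (sample, chrom, pos, ref, alt) in 1-based VCF
convention; no liftover is attempted. Protein changes are normalized to
one-letter HGVS short form (`p.Arg175His` → `R175H`; `Ter`/`X` → `*`)
because hotspot matching is exact string equality — substring matching
would conflate e.g. R273H with R273C. The panel's transcript/codon
numbering is taken as authoritative from the annotations; codon numbers
are never re-derived from genomic coordinates.

## Retention filter

Cutoffs (configurable via `FilterParams`): minimum 6 alt reads, tumor
VAF ≥ 5%, germline if present in the matched normal at VAF ≥ 20%,
population AF < 0.5% for the rare-missense/splice-region rule. Both VAF
comparisons are inclusive; the alt-read rule keeps exactly-6 reads
("fewer than six" is the discard condition). The 5% tumor cutoff applies
to *raw* VAF — purity normalization enters only at the LOH stage. A
missing population AF passes the rare rule, since genuinely rare somatic
variants typically lack population-catalogue records. Rejections carry
exactly one primary reason, assigned in the fixed order min_alt_reads →
min_vaf → germline → variant_type, which makes rejection tallies
reproducible. Matched-normal lookup is by exact key; fuzzy indel matching
is a known limitation. Duplicate re-sequencing of low-VAF samples is a
data-provenance fact, representable as an input flag column, not a
computation.

## Classification

Rule order: hotspot-list missense → GOF; nonsense/frameshift → LOF;
everything else → unclassified. Stop-lost/start-lost variants are
retained by the filter but are deliberately *not* LOF (they do not
truncate the protein); they land in unclassified, as do splice-site,
splice-region and inframe-deletion variants. The bundled hotspot list
expands the compact spellings (R248Q/W, R273C/H/L) to eleven explicit
protein changes at load time. Evidence-based GOF promotion (an
unclassified missense mutant with ≥ 1 recorded GOF activity) is recorded
in a separate field; the rule-based category is never overwritten, so
both tallies are always available. Domain localization uses canonical
p53 residue ranges (TAD 1–61, spacer 62–93, DBD 94–312, tetramerization
323–356), overridable via a boundary table.

## LOH inference

Copy-neutral LOH is the only copy-number model: a fraction *k* of tumor
cells carries two mutant alleles and no wild-type allele, the remainder
one of each, giving normVAF = (1+k)/2. Amplifications and deletions are
out of model and surface as `anomalous` rather than being forced into a
k estimate. Band edges are inclusive; the defaults (0.50 ± 0.05,
1.00 ± 0.08, subclonal below 0.45) promote observed empirical spreads
around the two theoretical points into an explicit decision rule, and are
exposed in `BandParams`. Values in (0.55, 0.92) are anomalous rather than
interpolated to intermediate k, reflecting the empirical absence of
intermediate LOH fractions for *TP53* in this tumor type; subclonal
normalized VAFs (< 0.45) are interpreted as the variant being confined to
a tumor subclone, where k is undefined. Per variant, the raw k̂ =
2·normVAF − 1 is retained unclipped; summary statistics clip k̂ to the
parameter space [0, 1], since k is a cell fraction — this clip matters
for recovery statistics at low purity, where binomial noise pushes raw k̂
outside [0, 1] symmetrically. Samples with two *TP53* variants get one
LOH call per variant; a sample is LOH-positive if any call is clonal-LOH.
LOH rates per category/consequence use clonal calls as the denominator
(LOH-positive / (LOH-positive + no-LOH)); subclonal and anomalous calls
are tabulated separately.

## IHC

High ⇔ pct ≥ 70, Low ⇔ 0 < pct ≤ 10, Negative ⇔ pct = 0, Intermediate
otherwise. The published prose merges Negative into Low (≤ 10); the
contingency table separates them, so the package keys Negative on exactly
0% and documents that no explicit threshold for "negative" was stated.
Low-or-Negative staining as a LOF predictor is reported with two
reference classes side by side: specificity against GOF-variant samples
only, and against all non-LOF variant samples — the published 73% figure
corresponds to the GOF-only definition. In the concordance join a
multi-variant sample takes the precedence GOF > LOF > unclassified;
patient-level category tallies in the cohort summary use LOF > GOF >
unclassified (severity of functional loss). The two joins serve different
questions (protein accumulation vs. category frequency), so the package
keeps both precedences, each configurable.

## Cohort comparison

Category percentages are reported under two denominators — all enrolled
patients and TP53-mutant patients — because published summaries mix them;
every table is labelled with its denominator. The reference comparison is
a 2×2 chi-square (category vs. not × cohort vs. reference); the
uncorrected statistic is the default and the Yates-corrected one is
always reported alongside, with a warning when an expected cell is < 1.
For the truncating-variant frequency of 30/99 against a reference of
261/1249, the uncorrected test gives p ≈ 0.029 and Yates p ≈ 0.039
(30/95 gives ≈ 0.015); the package reports these computed values as-is.

## Synthetic cohort generator

The generator emulates the study conditions: 99 patients (BRCA1 fraction
78/99), 95/99 TP53-mutant, 2/95 with a second *TP53* variant, category
mix 22:30:45, LOF split equally nonsense/frameshift, unclassified split
38:6:1 missense:splice:inframe, purity uniform on [10%, 95%] reported in
whole percent, amplicon depth lognormal with median 1087 and sigma fitted
to the quartiles 735–2037 (clipped to the observed range 163–7273), LOH
mixture P(k=1) = 65/94 and P(k=0) = 29/94 with no intermediate k, 6/99
patients carrying concomitant oncogene variants (APC, BAX, KRAS, CDKN2A,
CTNNB1; one third subclonal at normalized VAF uniform on [0.23, 0.37]),
germline contaminants (a common *TP53* polymorphism at allele fraction
0.5 in tumor and normal) at rate 0.10/patient, low-VAF artifacts at rate
0.05/patient, and IHC measured for 68/99 patients with staining-class
probabilities conditional on the sample's category (matched to the
published contingency proportions) and within-class percentages uniform
on the class interval. Read counts are Binomial(depth, f·(1+k)/2). An
optional flag perturbs the reported purity with Normal(0, 6%) noise to
emulate inter-pathologist disagreement; it is off by default so the truth
table and metadata agree.

What the generator does **not** emulate: sequencing error and FFPE
artifacts beyond a flat low-VAF artifact class, copy-number variation
(the generative model is copy-neutral, matching the inference model),
fuzzy indel representation, multi-nucleotide variants, and real genomic
coordinates (positions are stable synthetic identifiers). Passing
recovery tests therefore demonstrates internal consistency of the
generative/inference pair and correctness of the decision rules — not
robustness to the full error structure of real FFPE panel data.

## Numerical and testing choices

Exact inversion of the normalized-VAF formula is tested to 1e-9 over a
(k, purity) grid. The chi-square implementation is checked against an
independent closed-form 2×2 oracle (explicit expected-count formula) to
1e-9, uncorrected and Yates. k-recovery is evaluated on clonal variants
with depth ≥ 500 and purity ≥ 0.3 — below that, binomial noise on
k̂ = 2·VAF/f − 1 is intrinsically larger than the 0.1 tolerance — using a
400-patient simulation so the Monte-Carlo standard error of the rate is
well under 1%; the suite's other end-to-end checks use 40- and 99-patient
cohorts, which keep the full test run in a few seconds. Generator
determinism is verified by hashing all output files under a fixed seed.
Degenerate inputs: empty cohorts yield empty/all-zero tables, zero-count
denominators yield NaN metrics flagged as undefined, a 2×2 table with a
degenerate margin reports p = 1 with a warning rather than a division
error.

## Known limitations

Purity is a pathology input; no sequencing-based purity estimation is
attempted. Copy-number events are detected only negatively (anomalous
band). The matched-normal germline rule requires the same allele
representation in both files. The evidence-promotion path depends
entirely on the supplied annotation table; with no table, all missense
variants outside the hotspot list remain unclassified.
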