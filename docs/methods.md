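# Methods

## Scope and model

`fetalis` implements post-annotation interpretation for targeted prenatal
exome sequencing: from called variants (VCF) plus an annotation sidecar to a
per-case diagnostic tier. Read alignment, variant calling and the annotation
step itself are upstream of the package; the sidecar table is the contract
that replaces an integrated annotator, which keeps the pipeline reproducible
and testable offline. Mitochondrial genes are outside the panel universe by
design.

The central safety property is structural exclusion of incidental findings:
a variant can only be reported if its gene is (i) in the closed 758-gene
panel and (ii) in the phenotype-prioritized subset for the reported
ultrasound findings. Both gates are hard set restrictions, asserted in the
test suite across every fixture and synthetic scenario.

## Phenotype prioritization

Phenotype terms form a single-rooted DAG over is_a edges only (part_of and
other relations are ignored; obsolete terms are dropped and alt_ids resolve
to their primary term). Information content is computed from the panel's own
gene-term annotations: IC(t) = −ln(n_t/N) in natural-log units, with n_t the
number of panel genes annotated to t or any descendant (a gene reachable via
several descendants counts once) and N the number of annotated panel genes.
The root therefore has IC 0, IC is monotone non-decreasing from root to
leaf, and terms with no annotated gene carry an +inf sentinel and are
excluded from similarity maxima rather than smoothed.

Similarity is Resnik's: the IC of the most informative common ancestor. The
gene score aggregates one-sidedly from findings to gene — the mean over the
1–3 finding terms of the best similarity to any gene annotation. The mean
makes the score symmetric in the findings and insensitive to annotation
count; a max-of-max would let one lucky term dominate, and a symmetric
best-match average is unnecessary for gating a fixed 758-gene universe (the
gene side is curated, not noisy). The p-value machinery used by full
phenotype-to-disease ranking systems is likewise omitted: the gate here is
deliberately permissive (any gene with score > 0 is admitted; the threshold
is configurable) and the variant-level filters do the narrowing. Hard gating
— discarding rather than down-ranking variants in unmatched genes — is the
package's reading of the workflow it models; it is also what makes the
no-incidental-findings guarantee structural. Equal-scoring genes rank
alphabetically, a pure artifact decision for determinism.

## Frequency filtering

Two staged gates in fixed order: the local population database, then the
international sources (1000 Genomes / EVS / ExAC analogs). Each source is
compared independently (no pooling), with thresholds by inheritance mode of
the gene: 5×10⁻⁴ for dominant genes, 5×10⁻³ for recessive, dual-mode and
X-linked genes. These defaults are not published constants; they are chosen
so that bona fide rare pathogenic alleles (observed at 1.6×10⁻⁵–9.1×10⁻⁵ or
absent from all sources in the validation series) pass comfortably while
"relatively common" population alleles (≥1%) fail; both are configuration
keys. A frequency absent from a source counts as 0.0 for filtering but the
absence is recorded, so reports distinguish novel from rare. Documented
known-pathogenic alleles are never frequency-excluded. The two stages
commute set-wise; the order only shapes the audit counts.

## Variant classification

Classes in strict precedence: known_pathogenic (exact normalized-coordinate
hit in the known-pathogenic table) → obligatory_pathogenic (nonsense,
frameshift, canonical ±2 splice-site) → probable_pathogenic → vous →
likely_benign. The composite in-silico score (EMA score) is 100 × the
arithmetic mean of the available normalized predictor scores, absent (not
zero) when no predictor is present; the probable threshold defaults to 70.
A predicted splice disruption at an exon-boundary base (distance 0) also
reaches probable_pathogenic regardless of the amino-acid-level prediction —
the mechanism that catches missense variants at exon edges whose real
effect is on splicing.

Two deliberately conservative defaults: in-frame indels are *not* obligatory
pathogenic (configurable flag) because over-calling is the costlier error
prenatally; and synonymous variants without a splice prediction default to
likely_benign rather than VOUS to keep the manual-review list small (the
workflow targets 1–3 candidates per case).

Known-pathogenic records key on normalized genomic coordinates, not HGVS,
to avoid transcript ambiguity; HGVS strings are carried for reporting only.
Allele normalization is reference-free parsimony trimming (shared suffix,
then prefix); full left-alignment across repeat tracts would require the
reference sequence, which the offline design excludes.

## Case tiering

Per prioritized gene, by inheritance mode:

* **Dominant (AD).** One known/obligatory pathogenic variant is a diagnosis.
  Confirmed de novo (absent from both tested parents) or segregation in an
  affected relative → `definitive`; otherwise `highly_likely`. A
  probable-class (in-silico only) dominant candidate inherited from an
  apparently unaffected parent is demoted to VOUS
  (`inherited_dominant_downgrade`, on by default) — dominant causality from
  an unaffected carrier parent is weak evidence at prenatal stakes.
* **Recessive (AR).** A homozygous qualifying allele, or a
  compound-heterozygous pair in which every allele is ≥ probable_pathogenic
  AND either one allele is known/obligatory or trans phase is confirmed by
  parental genotypes (one maternal-only plus one paternal-only allele).
  Trans-confirmed or homozygous → `definitive`; an unphased pair anchored by
  a known/obligatory allele → `highly_likely`; two unphased in-silico
  probables remain review candidates only. A pair traced to a single parent
  is cis-or-artifact and is not a diagnosis.
* **X-linked (XL).** For a male fetus, heterozygous chrX calls are
  normalized to hemizygous; one hemizygous known/obligatory variant
  suffices (de novo → definitive, else highly_likely). No validation-series
  exemplar exercises this path; it is included for completeness. Female or
  unknown sex falls back to the biallelic rule.
* **Dual-mode (AD_AR).** Both models are evaluated and every qualifying
  model is reported, best tier first. The dominant-downgrade rule does not
  apply to dual-mode genes, whose recessive arm must still see inherited
  probable alleles as carrier alleles.

Case tier is the best diagnosis tier; with no diagnosis but at least one
VOUS-or-better candidate in a phenotype-matched gene the case is `vous`;
otherwise `negative`. A reported family history is surfaced in the report
but never changes the tier — it informs counseling, not classification.
Candidates are ranked by (class precedence, gene phenotype score, composite
score) descending.

The definitive/highly-likely boundary — segregation-confirmed versus not —
is an inference from the diagnostic language of the validation series, not
a published rule, and is encoded as such.

## Fixtures and the synthetic generator

The bundled cohort encodes the 14-fetus validation series: the printed
variants (HGVS verbatim), zygosities, parental carrier states,
known-pathogenic status and finding terms, with genomic coordinates placed
synthetically on toy loci (the source prints HGVS, not coordinates, and the
package downloads nothing). The bundled 758-gene panel is a synthetic
stand-in for the curated clinical list — 16 exemplar genes with
literature-consistent annotations plus 742 generated placeholder entries —
and the 40-term mini ontology covers skeletal, cardiac, brain, renal,
growth and digestive finding branches. Predictor scores for the exemplar
variants are fixture values constructed to realize the reported composite
scores (e.g. 75/100); the real constituent predictors of the production
score are unpublished.

The scenario generator spikes one causal configuration per mode (dominant
known / obligatory / de novo, recessive compound-het / homozygous,
VOUS-only, negative) into a background of seeded random panel variants.
Backgrounds draw allele frequencies log-uniformly over [10⁻⁴, 0.5]; any
draw inside the survivable range (≤ the recessive threshold) is forced to a
synonymous consequence, so by construction only the spiked signal survives
the pipeline, and the truth record (tier + causal keys) accompanies every
case. Output is fully determined by (mode, seed) and materializes
byte-identically.

What the fixtures do **not** emulate: real per-exome variant volumes
(~2,200 panel variants per sample), sequencing coverage and quality noise,
annotation ambiguity, population substructure in frequencies, or
turnaround-time constraints. Passing tests therefore validate the
interpretation logic — gating, filtering, classification, segregation,
tiering — not variant-calling robustness at production scale. Test problem
sizes (up to 200 background variants per synthetic case; 100 seeded
scenarios in the recovery study) were chosen as comfortably exercising the
combinatorics of the rules while keeping the suite quick to run.

## Numerical and degenerate-input choices

* IC uses natural log; ties in gene ranking break alphabetically; candidate
  ranking ties break on gene then coordinate key.
* A gene with no phenotype annotations scores 0 with a warning rather than
  erroring; an empty prioritized set yields a negative result with a note.
* Multi-allelic VCF records decompose to one record per alt allele; a 1/2
  genotype yields two heterozygous records. Records where no requested
  sample carries the alt are dropped.
* Declared parental origin contradicting parental genotypes (allele in
  neither parent) logs a segregation-inconsistency warning and sets de novo
  status.
* Report JSON uses sorted keys and rounded floats, so identical inputs give
  byte-identical reports.

## Known limitations

No mosaicism handling, no copy-number integration, no full ACMG/AMP
evidence-code model, no HGVS parsing/validation beyond string carriage, no
subpopulation-stratified frequencies, and no in-silico predictor execution
(scores arrive via the sidecar). Gene symbols are exact-match strings with
no alias resolution — a curated-panel decision that trades convenience for
safety against silent misassignment.
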