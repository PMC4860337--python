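# fetalis

Phenotype-driven variant prioritization and tiered reporting for targeted
prenatal exome sequencing.

When a routine ultrasound reveals a fetal structural abnormality in a
chromosomally balanced (euploid) fetus, the underlying cause is often a
single-gene disorder drawn from a large, heterogeneous set of candidates.
Whole-exome analysis in this setting is burdened by interpretation volume,
variants of uncertain significance, and — most sensitive in a prenatal
context — incidental findings unrelated to the indication. `fetalis`
implements the alternative strategy used by targeted prenatal panels: a
closed universe of 758 genes associated with fetal structural abnormalities,
phenotype-driven gene gating from up to three ultrasound findings, staged
population-frequency filtering, conservative variant classification, and
family-trio segregation logic, ending in a per-case diagnostic tier.
Because every reported variant must lie in a panel gene *and* in a gene
matching the reported findings, incidental findings are structurally
impossible rather than policy-suppressed.

## Method

1. **Panel restriction.** Variant calls (VCF) are joined with an annotation
   sidecar (gene, consequence, HGVS, in-silico predictor scores, splice
   predictions) and restricted to the panel's gene universe.
2. **Phenotype prioritization.** Phenotype terms form a DAG (is_a edges);
   each term's information content is IC(t) = −ln(n_t/N), where n_t counts
   panel genes annotated to t or a descendant. Gene relevance to the
   findings F against gene annotations G is Resnik similarity aggregated
   one-sidedly:

   score(g) = (1/|F|) Σ_{f∈F} max_{t∈G} IC(MICA(f, t))

   where MICA is the most informative common ancestor. Genes with
   score > 0 form the prioritized subset; all downstream evaluation is
   confined to it.
3. **Frequency gates.** Local database first, then international sources;
   thresholds are inheritance-aware (defaults 5×10⁻⁴ dominant, 5×10⁻³
   recessive; documented known-pathogenic alleles are exempt).
4. **Classification.** Strict precedence: known pathogenic (database hit) →
   obligatory pathogenic (nonsense, frameshift, canonical ±2 splice-site) →
   probable pathogenic (composite EMA predictor score ≥ 70/100, or predicted
   splice disruption at an exon-boundary base) → VOUS → likely benign.
5. **Case tiering.** Inheritance-model evaluation per gene (dominant,
   recessive with compound-heterozygote trans-phase detection from parental
   genotypes, X-linked, dual-mode) yields `definitive`, `highly_likely`,
   `vous`, or `negative`.

## Worked example

Materialize the bundled offline cohort fixtures and run one case — a fetus
with brain MRI abnormalities, analyzed as a family trio:

```
fetalis fixtures --out demo
fetalis run \
  --vcf demo/case_05.vcf --sidecar demo/case_05.sidecar.tsv \
  --panel demo/panel_758_synthetic.tsv --obo demo/mini_ontology.obo \
  --known-db demo/known_pathogenic.tsv \
  --freq local=demo/freq_local.tsv --freq intl_exac=demo/freq_intl_exac.tsv \
  --finding HP:0000313 --finding HP:0000315 \
  --case-id case_05 --mother MOTHER --father FATHER --sex female \
  --out demo_out
```

prints

```
case_05 definitive
```

and `demo_out/case_05.report.json` contains one recessive diagnosis:

```
ASS1  Citrullinemia  AR  confirmed_trans  definitive
  c.971G>T  p.G324V  known_pathogenic      (EMA 91)
  c.725C>T  p.T242I  probable_pathogenic   (EMA 75)
```

Both alleles passed the phenotype and frequency gates; the paternal allele
is a documented pathogenic mutation, the maternal allele a novel missense
scored probable-pathogenic (composite score 75/100), and the parental
genotypes confirm the pair in trans — a definitive compound-heterozygous
recessive diagnosis. The whole 14-case cohort runs with:

```
fetalis cohort --manifest demo/table1_manifest.tsv --out demo_cohort
```

which reports 5 definitive cases, 1 highly-likely, 1 VOUS and 7 negatives,
writing per-case JSON reports, ranked TSV review lists and a cohort summary.

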