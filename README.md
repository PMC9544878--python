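# msea

Pathway-based **metabolite set enrichment analysis (MSEA)** for untargeted
metabolomics screening of inherited metabolic disorders (IMDs).

Untargeted LC-MS metabolomics ("next-generation metabolic screening")
measures tens of thousands of features per plasma sample; a patient run
typically yields hundreds of features that differ significantly from the
batch controls, far too many to interpret one by one. Many of the truly
disease-relevant metabolites sit in the same biochemical pathway as the
defective enzyme, while diet and medication scatter aberrations across
unrelated pathways. This package prioritises candidate biomarkers by
asking which *pathways* are statistically over-represented among the
aberrant features, rather than which individual features are largest.

## Method

For one patient run against its ~10 batch controls:

1. **Aberrant feature detection** — per feature, the patient's log
   intensity is studentized against the control mean and standard
   deviation, `T = (x_p − x̄_c) / (s_c √(1 + 1/n))`, giving a two-sided
   t(n−1) p-value; Benjamini–Hochberg correction across the run flags
   features with adjusted p < 0.05 as aberrant.
2. **Annotation** — each feature m/z is corrected for the [M+H]⁺,
   [M+Na]⁺, [M−H]⁻ and [M+Cl]⁻ adducts of its ion mode and matched to
   reference metabolites (HMDB-style and KEGG-style tables) within 5 ppm
   of the database monoisotopic mass; features map to a pathway when any
   annotated metabolite is a member.
3. **Enrichment** — per pathway, a 2×2 table of aberrant vs non-aberrant
   × pathway-associated vs not (background = all detected features) is
   tested with a one-sided Fisher exact test, P(X ≥ a) under the
   hypergeometric null. Pathways with ≤1 aberrant associated feature are
   not tested; Bonferroni–Holm correction across tested pathways retains
   those with adjusted p < 0.05.
4. **Clustering** — enriched pathways of one source database driven by
   100%-overlapping aberrant metabolite sets are merged (connected
   components), and each cluster is summarised by a representative chosen
   by most aberrant features → lowest p → preferred "Metabolic"/
   "Metabolism" category.
5. **Ranking and cohort analyses** — known biomarkers are ranked in the
   intensity-sorted and pathway-p-sorted aberrant feature–metabolite pair
   lists (1-based row indices, permutation significance against uniform
   placement); enriched biomarker pathways yield putative *novel*
   biomarker candidates (aberrant members minus known biomarkers), and
   pathways enriched across many disorders flag diet/medication
   confounders.

Because real screening cohorts are not publicly shareable, the package
ships a fully seeded synthetic-cohort generator (`msea.synthetic_data`)
that emulates the input structure with planted ground truth, and a
hand-built worked example (`msea.examples.structured_demo`) whose
enrichment/clustering/rank structure is known exactly.

## Worked example

Simulate a run in which 15 of the 20 members of pathway `SMP00001` are
perturbed 20-fold in the patient, on top of 1500 decoy features:

```yaml
# spec.yaml
n_metabolites: 300
n_pathways: 6
pathway_size_range: [20, 20]
n_features_decoy: 1500
spiked_pathways:
  - pathway_id: SMP00001
    n_members_perturbed: 15
    fold_change: 20.0
seed: 1
```

```bash
msea simulate --spec spec.yaml --out demo
msea enrich --features demo/features.tsv --metabolites demo/metabolites.tsv \
            --pathways demo/pathways.tsv --out-dir demo_out
# -> 1 significant pathways, 1 clusters -> demo_out/
```

`demo_out/enrichment.tsv` then contains (abridged):

```
pathway_id  source  a   b  c  d     raw_p       holm_p      significant
SMP00001    SMPDB   15  5  0  1780  3.186e-33   3.186e-33   True
```

i.e. all 15 perturbed members were detected as aberrant (`a = 15`), the 5
unperturbed members were not (`b = 5`), no aberrant feature fell outside
the pathway (`c = 0`), and the spiked pathway is the only enrichment.
Ranking the panel's two biomarkers:

```bash
msea rank --features demo/features.tsv --metabolites demo/metabolites.tsv \
          --pathways demo/pathways.tsv --panel demo/biomarkers.tsv --out demo_out/ranks.tsv
```

```
disorder      metabolite_id   feature_rank  pathway_feature_rank  cluster_feature_rank
SIM_DISORDER  HMDB0000003     14            14                    14
SIM_DISORDER  HMDB0000011     4             4                     4
SIM_DISORDER  <pathway_rank>  1                                   1
```

The best biomarker-containing pathway (and cluster) ranks first; the
biomarker features themselves sit at intensity positions 4 and 14 of the
aberrant pair list.

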