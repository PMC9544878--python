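# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the design decisions taken where more than one reasonable
choice existed.

## Aberrant feature detection

Each feature is a single intensity for the patient plus ~10 control
intensities from the same analytical batch. Electrospray LC-MS intensity
noise is predominantly multiplicative, so intensities are moved to the
log scale (`log1p`, which tolerates the zeros we deliberately keep as
observed values) and the patient deviation is studentized against the
controls:

    T = (log1p(x_pat) − mean(log1p(x_ctrl))) / (s_ctrl · √(1 + 1/n))

Under a log-normal null, T is exactly Student t with n−1 degrees of
freedom — the √(1+1/n) prediction-interval factor accounts for the
patient draw itself. This calibration matters: with only ~10 controls,
a robust median/MAD z-score referred to the normal distribution has
tail probabilities inflated by four orders of magnitude (the MAD of ten
points is extremely noisy), which would destroy false-discovery control
at the run level. We therefore accept the lower outlier resistance of
the mean/SD form in exchange for exact small-sample calibration; batches
with corrupted control measurements should be excluded upstream, as is
standard QC practice for this data type.

Two-sided p-values are Benjamini–Hochberg adjusted across all features
of the run, pooling both ion modes (the downstream enrichment universe
is also pooled); features with adjusted p < α (default 0.05) are
aberrant. Degenerate control sets (zero spread) give p = 1 when the
patient equals the shared value and a smallest-representable-p surrogate
with a `degenerate` flag otherwise.

## Annotation

Neutral mass candidates are `mz − shift` for each mode-compatible
adduct, with shifts (+1.007276, +22.989218, −1.007276, +34.969402 Da for
[M+H]⁺, [M+Na]⁺, [M−H]⁻, [M+Cl]⁻) using ion-mass conventions that
include the electron mass. Matching tolerates 5 ppm, with the database
(theoretical) monoisotopic mass as the ppm denominator — the tolerance
is a property of the reference. Multiple annotations per feature are
expected and kept. In-source fragments, isotopologues and multimers are
not modelled.

When a reference metabolite has a known retention time on the local LC
system, annotations further than 0.1 min from it are flagged
`inconsistent` but retained; RT checks are a post-hoc falsification tool
rather than a pipeline filter, and a switch (`drop_rt_inconsistent`)
excludes them from pathway mapping for users who prefer a hard filter.

Pathway association is binary per (feature, pathway): one supporting
annotation suffices and multiplicity adds nothing, which is what the
2×2 counts require. HMDB ids map to SMPDB pathways and KEGG compound ids
to KEGG pathways; no cross-database id mapping is attempted because the
two id spaces are poorly connected.

## Enrichment

The background universe is every detected feature of the run, associated
or not, both ion modes — the contrast is aberrant/non-aberrant ×
pathway-associated/unassociated over the whole feature table. The
one-sided Fisher p is the upper hypergeometric tail P(X ≥ a) with the
table's margins. Pathways need a ≥ 2 aberrant associated features to be
tested at all; untested pathways are excluded from the output *and* from
the Holm family, so decoy pathways never dilute the correction.
Bonferroni–Holm runs across the tested pathways of both sources jointly
by default (`per_source_family` switches to separate families);
significance means Holm-adjusted p < 0.05. Results are ordered by raw p
with pathway-id tie-breaks so output is deterministic.

## Clustering

Within one source database, enriched pathways are linked when their
aberrant metabolite sets overlap 100%: identical sets in `exact` mode
(default — this matches grouping pathways "enriched by the same root
metabolite set"), or containment in either direction in `subset` mode.
Clusters are connected components; exact mode always refines subset
mode. The representative is chosen by the three-rule cascade (most
aberrant features, lowest raw p, preferred category "Metabolic"/
"Metabolism"), with the lexicographically smallest pathway id as the
final deterministic tie-break; the cluster p is the representative's raw
Fisher p, since no combined cluster-level statistic is defined. Clusters
of different sources with identical aberrant *feature* sets are
cross-referenced (feature ids, unlike metabolite ids, are shared across
sources). A `link_key="features"` escape hatch clusters on aberrant
feature sets instead of metabolite sets.

## Ranking

The ranking universe is the run's aberrant feature–metabolite pairs,
deduplicated over adduct routes. Feature rank sorts pairs by patient
intensity (descending; intensity is used as a standalone ranking score);
pathway/cluster feature rank expands items in ascending-p order into
their intensity-sorted pairs, first occurrence winning; pathway-level
rank is the position of the first biomarker-containing pathway or
cluster, where "containing" means pathway membership of a panel id. A
biomarker's rank is the minimum over its pairs; ranks are 1-based row
indices. All ties break on ids, so every ranking is deterministic.

Permutation significance places each run's biomarker pairs uniformly
without replacement in its universe, takes the per-run minimum and the
across-run median, with p = (1 + #{null ≤ observed}) / (n_perm + 1). The
median (not mean) matches median-rank reporting. ROC AUCs of intensity,
|log₂ fold change| (patient / control median, with zero medians mapped
to the extreme of the ordering) and feature p-value as classifiers of
biomarker status are provided to compare candidate ranking scores.

## Cohort analyses

Pathway sharing counts, per pathway, the distinct *disorders* (and,
secondarily, runs) in which it was significant — disorders are the
binning unit for confounder detection, since medication and diet effects
recur across unrelated diagnoses. The specificity comparison of sharing
counts between biomarker and non-biomarker pathways uses a two-sided
Wilcoxon rank-sum test (exact enumeration for small untied samples,
tie-corrected normal approximation otherwise, via
`scipy.stats.mannwhitneyu(method="auto")`). Novel-biomarker candidates
are the aberrant member metabolites of each significant
biomarker-containing pathway minus the known panel, with a flag for
metabolites supported only by RT-implausible annotations.

## Synthetic cohorts

The generator emulates the *structure* of screening data: reference
masses uniform on 50–1000 Da with pairwise spacing > 12 ppm (beyond
twice the 5 ppm tolerance, so annotation is unambiguous by default),
half HMDB-like and half KEGG-like; disjoint pathways per source
(overlap, duplicates and collisions are opt-in knobs); one feature per
metabolite through an adduct sampled at 0.4/0.4/0.1/0.1 for
[M+H]/[M−H]/[M+Na]/[M+Cl], with Gaussian relative mass error (default
1 ppm); log-normal control intensities with log-mean uniform on [9, 13]
and log-sd uniform on [0.1, 0.4] — roughly 10–40% multiplicative noise,
a plausible single-batch spread; the patient is an independent draw
times the fold change (default 1) of its metabolite; 10 controls per
batch. Unannotatable decoys pad the universe (their m/z is rejected if
*any* adduct interpretation lands near a reference mass), and optional
"confounder" features are annotated, strongly elevated (fold 50 at the
top of the intensity range) but attached to metabolites outside every
pathway — the diet/medication signal that dominates intensity sorting
without enriching anything.

The canonical spike-in design used throughout testing and in
`scripts/acceptance.py` is six disjoint 20-member pathways with 15
members of one perturbed 20-fold over 1500 decoys; the biomarker panel
is the first two perturbed members. Everything derives from one integer
seed and identical seeds give byte-identical files.

What the generator does **not** emulate: chromatographic peak shape,
retention-time drift and alignment errors, batch and instrument effects,
correlated intensities between features of one compound, in-source
fragmentation, heavy-tailed or zero-inflated intensity noise, and the
incompleteness/bias of real pathway databases. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated noise model, not performance on real cohorts.

## Problem sizes and numerical choices

Simulation-based checks use 100–200 seeded runs of ~1700–1800 features
each and a 200-run null ensemble — large enough for binomial standard
errors of a few percent on the reported rates. The acceptance script's
ranking cohort uses 50 seeds with 30 confounders. On this confounded
design the biomarkers sit *below* the confounders in the intensity
ranking by construction, so the feature-rank permutation p is ~1 and the
intensity AUC is well below 0.5 — the quantification of exactly the
confounding that pathway sorting corrects (median pathway-sorted rank ≈
4–6 vs median intensity rank ≈ 35); within the enriched pathway the
panel biomarkers are exchangeable with the other perturbed members, so
their within-universe placement carries no extra signal. Fisher tails
come from `scipy.stats.hypergeom.sf` (checked against an exact-rational
tail sum on all tables with N ≤ 60), BH/Holm from
`statsmodels.stats.multitest` (checked elementwise against independently
coded textbook formulas), AUCs from `sklearn.metrics.roc_auc_score`
(checked against the Mann–Whitney U identity). P-value validation
rejects values outside [0, 1]; adjusted values are clipped at 1.

## Known limitations

* The per-feature test assumes approximately log-normal within-batch
  noise and loses power (and calibration) under heavy contamination of
  the control set.
* Fisher enrichment treats features as exchangeable and independent;
  adduct/isotope multiplicity of a single compound can inflate counts in
  real data (an adduct-grouping preprocessor would mitigate this).
* Exact-overlap clustering is deliberately conservative; pathways with
  high but imperfect overlap remain separate clusters.
* The background-universe choice (all detected features) and the joint
  two-source Holm family are defensible but not unique; both are
  switchable, and conclusions at the extremes of significance do not
  depend on them.
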