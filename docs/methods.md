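# Methods

This document records the statistical model behind each module, the
default parameters, the scope of the synthetic generator, numerical
choices, and known limitations.

## 1. Panel gene prioritization (`crcpanel.panel`)

Candidate genes come from a drug-sensitivity screen of cell-line models
and a human tumor mutation catalog.

* **Ranking.** For each drug, cell lines with a measured IC50 are sorted
  ascending by IC50, with AUC and then the cell-line identifier breaking
  ties deterministically. The k most sensitive and k most resistant lines
  form two tails. Each tail must contain exactly `crc_quota`
  colorectal-origin lines; the quota is filled from the CRC-restricted
  ranking first and the remainder from the global ranking, so a tail can
  never silently under-represent the tumor type of interest.
* **Phase 1 (recurrence rule).** Gene g is a candidate for a tail when,
  in at least ⌈m/2⌉ of the tail's m lines with non-zero mutation totals,
  g's mutation count strictly exceeds 5 % of that line's total count.
  Measuring the share per line (not over the pooled tail) excludes genes
  whose mutations pile up in a single hypermutated line. Zero-mutation
  lines are dropped from the denominator and logged.
* **Phase 2.** Gene symbols are normalized through an alias map
  (HGNC-style synonym → canonical symbol) before the sensitive and
  resistant candidate sets are unioned, so the same gene reported under
  two names cannot enter twice.
* **Phase 3.** A candidate survives the catalog cross-check when its
  tumor mutation frequency is strictly greater than 5 % and it is absent
  from the catalog's never-mutated list.
* **Assembly.** The core is unioned with oncodriver / actionable / extra
  enrichment lists; per-gene provenance is recorded.

## 2. Somatic variant profile (`crcpanel.somatic`)

* **Filter.** A call is kept iff `filter_status == "PASS"` **and**
  VAF ≥ 0.05 **and** alt-supporting reads ≥ 3. Both floors are
  *inclusive*. Rows missing any filter field are rejected with reason
  `missing_field`; rejection counts are reported by reason.
* **Impact classes.** nonsense, frameshift insertion/deletion, splice
  site and TSS variants are HIGH; missense and in-frame indels MODERATE;
  synonymous LOW; anything else MODIFIER. A patient *carries* a gene when
  they have at least one HIGH or MODERATE variant in it.
* **Summaries.** Per-gene carrier frequencies, per-sample variant counts
  (total and by impact), TMB = filtered variants / panel Mb, oncoplot
  frequency table (descending frequency, lexical tiebreak).
* **KRAS alleles.** `protein_change` is parsed as a one- or three-letter
  HGVS substitution (`p.G12D`, `p.Gly12Asp`); flags cover any-KRAS,
  codon 12/13, and 12D specifically. Unparseable strings set only the
  any-KRAS flag. Co-mutation indicators combine these with TP53 carriage
  and APC-truncating (HIGH) status.

## 3. Genome instability (`crcpanel.instability`)

* **Homopolymers.** Maximal single-base runs of length ≥ 5 over ACGT;
  `N` (or any non-ACGT character) never extends a run. Coordinates are
  0-based half-open.
* **MMR deficiency surrogate.** Indel positions (1-based anchor
  coordinates) are counted inside homopolymer regions and divided by the
  target megabase size; MMR-deficient iff density **strictly >** 1.5
  indels/Mb.
* **MSI.** MSI-high iff the unstable-site fraction is **strictly >**
  0.20, else MSS.
* **CNV thresholds (clonal-fraction model).** With tumor purity ρ and
  aberrant-clone fraction c, the effective fraction is f = ρc. A
  mono-allelic deletion present in fraction f of cells has expected
  log2 ratio log2((2 − f)/2); a single-copy gain log2((2 + f)/2). The
  calling windows for the B-allele frequency are 0.5 ± f/2 (deletion)
  and 0.5 ± f/6 (duplication). At ρ = 0.70, c = 0.50 (f = 0.35) these
  evaluate to −0.278, 0.233, 0.325–0.675 and 0.442–0.558.
* **Segment calling.** A segment is *excluded* when it has fewer than 3
  bins or its bin log2 values do not differ from reference bins by a
  pooled-variance two-sided Student t-test at α = 0.05. Otherwise it is
  a deletion iff mean log2 **<** the deletion threshold and BAF lies in
  the deletion window (inclusive); duplication symmetric; else neutral.
  The log2 comparisons are strict, matching the "< −0.278 / > 0.233"
  calling rule; the thresholds are detection floors: events must be
  *more* aberrant than an f = 0.35 event to be called reliably.

## 4. Association statistics (`crcpanel.stats`)

* **Fisher 2×2.** Two-sided p by the probability-mass rule: the sum of
  hypergeometric probabilities of all tables with the observed margins
  whose probability does not exceed that of the observed table (with a
  relative tolerance of 1e−7 to absorb floating-point ties). Degenerate
  margins give p = 1.
* **Freeman–Halton r×c.** The same rule over all tables with the
  observed margins, enumerated recursively with log-factorial table
  probabilities. An enumeration budget guards runtime; larger tables use
  a seeded Monte-Carlo version (margin-preserving sampling via
  `scipy.stats.random_table`, Patefield's algorithm) with an add-one
  estimator.
* **Rank statistics.** Kruskal–Wallis and Spearman wrap
  `scipy.stats`; identical-value corner cases are defined as the null.
* **Multiplicity.** Benjamini–Hochberg step-up via
  `statsmodels.stats.multitest.multipletests`. The family is *all tests
  executed in a screen*, and each result records the family size it was
  adjusted in.
* **Contingency construction.** Clinical levels are collapsed through an
  explicit map (e.g. stage I/II vs III/IV); mapping a level to `None`
  excludes those patients (e.g. grade Gx), and the exclusion count is
  recorded. An incomplete map raises instead of silently dropping.

## 5. Survival analysis (`crcpanel.survival`)

* **Endpoints.** Overall survival: surgery to death from any cause.
  Recurrence-free survival: surgery to recurrence; deaths in remission
  and last controls in remission are censored, so RFS ≤ OS always.
  Stage IV patients are excluded from all survival analyses.
* **Kaplan–Meier.** Product-limit estimates via lifelines; medians with
  confidence intervals where defined.
* **Gehan–Breslow test.** The k-group weighted log-rank statistic with
  weight w(t) = number at risk at each event time (the "Breslow" test of
  SPSS; reduces to the generalized Wilcoxon for two groups). The
  covariance is the multivariate hypergeometric form; one group is
  dropped to invert the singular covariance, and the statistic is
  referred to χ² with k − 1 df. Cross-checked in the test suite against
  `lifelines.statistics.multivariate_logrank_test(weightings="wilcoxon")`.
* **Prognostic screen.** Stage 1: every gene mutated in ≥ 10 % of
  patients is tested carrier vs non-carrier within each stratum (all /
  untreated / adjuvant-treated). Stage 2: per stratum, genes with crude
  p < 0.05 form a set; patients are classified by the number of set
  genes mutated (0 / 1 / >1) and each set is tested in every stratum.
  B-H adjustment runs over the full family (all stage-1 plus all
  stage-2 tests). An optional union mode screens a single cross-stratum
  union set instead.

## 6. Germline association (`crcpanel.germline`)

* **Phenotype.** RFS dichotomized at 3 years: recurrence at or before 36
  months → case; followed beyond 36 months → control; censored before 36
  months without recurrence → missing.
* **Allelic test.** Per variant, the 2×2 allele-count table (cases /
  controls × alt / ref over 2n alleles, missing genotypes dropped
  pairwise) is tested with the Pearson chi-square, 1 df, no continuity
  correction — the PLINK `--assoc` allelic test. Monomorphic variants
  are defined as null.
* **max(T) permutation.** Phenotype labels are permuted B times; for
  each permutation the maximum chi-square across variants is recorded.
  The family-wise adjusted p for variant i is
  (1 + #{b : max_b ≥ T_i}) / (B + 1); pointwise permutation p values use
  the same add-one form. The implementation is fully vectorized (allele
  counts as genotype-matrix × permutation-matrix products), so B = 10⁴
  over dozens of variants runs in seconds, and a fixed seed gives
  identical output regardless of variant row order.
* **Prioritization.** Genes are shortlisted when HIGH-impact variants
  give a carrier frequency ≥ 5 %; ClinVar-style flagged variants within
  shortlisted genes are enumerated.

## 7. Synthetic cohort generator (`crcpanel.synthetic`)

Scope: the generator produces *inputs* for every pipeline stage with
planted, machine-readable truth. It is a validation instrument, not a
biological simulator.

* **Clinical.** Stage and grade are drawn from configurable
  distributions (defaults 12/40/47/1 % for stages I–IV; 22/67/11 % for
  G1–G3 plus 1 % Gx). Survival times are exponential with proportional
  multipliers: per-stage baselines, planted prognostic-set hazard ratios
  on OS (default: a 5-gene set at HR 3), and planted germline effects
  per endpoint. Censoring is uniform over the follow-up window for a
  configurable dropout fraction; OS caps RFS. Adjuvant treatment is
  assigned only to stage II–IV patients at a rate that hits the
  configured overall treated fraction.
* **Planted stage associations.** Carrier status for planted genes uses
  a higher probability in stage III/IV with odds ratio OR; the stage-I/II
  base rate is solved numerically (Brent root-finding) so the *marginal*
  frequency still equals the configured gene frequency.
* **Somatic realization.** Each carrier's first variant in a gene is
  always HIGH or MODERATE (so the planted carrier matrix survives impact
  filtering); KRAS carriers receive hotspot protein changes at realistic
  allele shares. A configurable fraction of sub-threshold variants
  (VAF < 5 %, < 3 reads, or non-PASS) is injected and indexed in truth to
  exercise the filter.
* **Seeding.** One global seed fans out through fixed per-generator
  child seeds (`np.random.default_rng((seed, offset))`), so the carrier
  draw shared by the clinical and somatic generators is identical in
  both, and regenerating one input never perturbs another.
* **Reference/indels.** Background sequence is built with no run of ≥ 5
  identical bases; planted runs are made maximal by flanking; indel
  truth records whether each 1-based anchor falls inside a run.
* **CNV.** Segment bins are drawn normal around the clonal-fraction
  expectations. Deletion BAF centers on the mono-allelic-loss value
  1/(2 − f) (mirrored at random); duplications are emulated as
  allele-balanced gains (BAF 0.5), because the expected BAF of a
  mono-allelic gain at moderate f falls outside the duplication calling
  window by construction — the window targets near-balanced states.
* **Germline.** Null variants in Hardy–Weinberg proportions at uniform
  random MAFs; planted variants reuse the genotype draw that shaped the
  survival times, so their stated hazard ratios are actually realized.
* **Drug screen.** Planted resistance genes are injected at 10 % of each
  resistant-tail line's mutation total (surviving phase 1 by
  construction); their catalog frequency / never-mutated entries then
  decide their phase-3 fate, which is recorded in truth.

## 8. Numerical choices

* Exact-test probability comparisons use a relative tolerance (1e−7) when
  deciding "as or less probable", preventing float noise from dropping
  tied tables.
* The weighted log-rank solves the (k−1)-dimensional system with
  `numpy.linalg.solve`, falling back to the pseudo-inverse for singular
  covariance; the statistic is clipped at 0.
* Permutation p values use add-one estimators, bounded below by
  1/(B + 1) and never exactly zero.
* All threshold comparisons (MMR-D, MSI, CNV log2, catalog frequency) are
  strict; the somatic filter floors are inclusive. Boundary unit tests
  pin each of these.
* Random draws go through `numpy.random.default_rng` exclusively; no
  global RNG state is touched.

## 9. Limitations

* Survival times are exponential (constant hazard); no frailty, no
  time-varying effects, no competing risks. The planted hazard ratios
  are marginal multipliers, not estimates from a fitted model.
* The MSI/MMR-D calls are surrogates computed from homopolymer indel
  density and unstable-site fractions, not from paired-normal
  microsatellite genotyping.
* The CNV model covers single-copy mono-allelic losses and near-balanced
  gains only; no allele-specific copy-number inference, no subclonal
  mixtures beyond one aberrant fraction, and events at exactly the
  threshold fraction f are undetectable by design (the thresholds are
  floors, strict comparisons).
* The Freeman–Halton enumeration is exponential in table size; large
  tables must use the seeded Monte-Carlo fallback, whose p values carry
  sampling error of order 1/√n_sim.
* The germline arm assumes a binary phenotype and biallelic variants
  coded 0/1/2; no covariate adjustment, relatedness correction or
  population stratification control is implemented.
* The synthetic generator plants effects independently per gene given
  stage; real mutational co-occurrence structure (mutual exclusivity,
  signatures) is not modeled.
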