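# Methods

`crfdrivers` implements a driver-gene analysis for somatic mutation cohorts
with a focus on chromatin regulatory factors (CRFs): histone modifiers, DNA
methyltransferases/demethylases and ATP-dependent remodelers.  This note
documents the statistical models, their assumptions, the tunable parameters,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Mutation model and vocabulary

A somatic mutation is reduced to (sample, gene, consequence, protein
position, functional impact scores).  Consequences use a seven-value
vocabulary (`missense`, `stop_gained`, `frameshift_indel`, `inframe_indel`,
`synonymous`, `splice`, `other`); a default alias table normalizes common
MAF spellings, and unknown labels fall to `other` with a warning — never
silently into the protein-affecting class.  Protein-affecting mutations
(PAMs) are exactly {missense, stop_gained, frameshift_indel}.  Positions are
1-based residue indices; functional impact scores (FIS) live on [0, 1] with
higher = more damaging, and input columns declared on another range are
rescaled linearly at read time.  Samples with zero mutations are first-class
roster members, because per-site mutated fractions need true denominators.

## FM bias (functional-impact accumulation)

*Model.*  Under neutrality, the FIS of a gene's PAMs are exchangeable with
the FIS of all PAMs in the cohort.  A gene under positive selection
accumulates functional mutations, so its mean FIS exceeds that background.

*Test.*  For each predictor, the statistic is the mean FIS over the gene's
`n` PAMs.  The null is built by drawing `N` sets of `n` values with
replacement from the pooled cohort PAM background, and the empirical P value
uses the add-one convention `(1 + #{null mean >= observed}) / (N + 1)`, so P
is valid and bounded below by `1/(N+1)`.  Per-predictor P values are
combined with Fisher's method (Stouffer optional).  Benjamini–Hochberg runs
over the tested genes of one dataset.  Gene groups (complexes, the whole CRF
catalog) are tested identically after pooling member PAMs into a meta-gene.

*Scoring conventions.*  Truncating mutations (stop gains, frameshift
indels) carry no predictor output and are assigned the maximal score 1.0 —
the tumor-suppressor-friendly convention.  Missense rows missing a score are
imputed at the predictor's cohort median (configurable to drop).  The mean
comparison uses a 1e-9 tolerance so that all-tied catalogs give P = 1
despite floating-point summation error.

*Parameters.*  `min_pams` (default 3) — genes below it are *untested*
(absent P, not P = 1) and excluded from the BH denominator; `n_samplings`
(default 10,000); background pool = all PAMs of the cohort.

*Known limitation.*  When several predictors are supplied, their P values
are dependent (they share each mutation, and truncating mutations carry the
same 1.0 on every predictor), so Fisher combination is anti-conservative:
on passenger-only simulations the fraction of genes at p < 0.05 was ~0.09
with two correlated predictors versus ~0.05 with one.  Calibration claims in
this package are therefore stated for the single-predictor configuration;
multi-predictor combination is provided as the conventional interface, and a
dependence-robust combination would be a straightforward extension.

## CLUST bias (positional clustering)

*Model.*  Gain-of-function drivers concentrate PAMs on few residues.
Synonymous mutations of the same dataset carry the positional biases of the
mutational process without selection, so they calibrate the null.

*Cluster detection* (seed–merge–extend): a residue seeds a cluster when its
mutation count exceeds the uniform expectation `n / L` (`n` positioned PAMs,
`L` protein length) **and** is at least 2 — one mutation is never evidence
of clustering.  Seeds within `gap` residues (default 5) merge; clusters then
absorb any mutated position within `gap` of their boundary until stable, and
clusters that come within `gap` of each other after extension are re-merged.
The gene score is `sum over clusters of (count / n) * w` with positional
weight `w = 1 - (span - 1)/L`: 1 when all positioned PAMs share one residue,
0 without clusters.  These rules and constants are this package's own
reconstruction of "grouping in protein regions"; they are deliberately the
smallest rule set with that behavior, and every constant is exposed.

*Null.*  Each gene with >= `min_pams` positioned synonymous mutations
contributes one background score; a normal law is moment-fitted to those
scores and each gene's PAM score gets a one-sided upper-tail P, floored at
the smallest positive float.  Fewer than 10 background genes is a
calibration error, not a silent default.  At realistic synonymous densities
most background scores are exactly 0, so the fitted SD is floored at 0.01 to
keep P values defined; the practical consequence is that any *genuine*
residue coincidence (two or more PAMs on one residue) is strong evidence
against this null.  On passenger-only cohorts the resulting false-positive
fraction at q < 0.05 is ~2%, within the nominal level.  Genes lacking an
annotated protein length use 1.1x the maximum observed position.

## Cross-dataset combination and FDR

Gene-wise P values from datasets of one anatomical site are combined with
Fisher's method (`-2 * sum(ln p) ~ chi^2_{2k}`); Stouffer's weighted z is
available for cohorts of very different sizes.  A gene tested in one dataset
keeps its P unchanged.  Zeros are clipped to the smallest positive float
with a warning.  BH is applied per analysis unit — within a dataset for
dataset-level results, within a site across combined results — and the
driver flag is `min(q_fm, q_clust) < q_threshold` (default 0.05).
`bh_adjust` and the combination rules are backed by
`statsmodels`/`scipy`; independent step-up and closed-form oracles verify
them in the test suite.

## Cohort metrics

The **CF ratio** of a sample is (distinct driver CRFs with >= 1 PAM) /
(distinct driver genes with >= 1 PAM).  Counting distinct genes — not raw
mutations — is what bounds the ratio in [0, 1].  Samples with no mutated
driver have an undefined ratio and are excluded from ratio distributions but
included in mutated-fraction denominators.  **Driver overrepresentation**
uses the upper-tail hypergeometric computed in log space; with the curated
CRF catalog (34 driver CRFs of 183) against 382 likely drivers among 22,696
genes it gives P = 1.26e-25.  (The source literature also quotes a total of
348 drivers in the same sentence; that count gives 5.6e-27.  The printed P
corresponds to 382, so that is the worked example this package reproduces;
both are one call away.)  **Mutual exclusivity** of two genes is the
lower-tail hypergeometric probability of their co-mutated sample count given
the margins; the oncoprint "memo sort" orders genes by mutation count and
samples by descending binary weight (most-mutated gene = most significant
bit), ties lexicographic, and is idempotent.

## SLEA (sample-level enrichment analysis)

Expression is standardized per gene: median-centered across samples and
divided by the pre-centering standard deviation (zero-variance genes are
dropped, or kept as zeros on request).  For each module and sample, the mean
(or median) standardized expression of the module's measured genes is
compared with the same statistic over `n_random` = 10,000 random gene sets
of identical size drawn from measured genes without replacement;
`z = (observed - null mean) / null SD`.  Null draws are made **once per
module size and shared across samples**: this matches the per-sample z
definition, keeps runtime proportional to the number of distinct sizes, and
makes z columns comparable across samples (independent per-sample redrawing
is available via ``share_null_across_samples=False``).  Modules with fewer than
`min_module_size` (default 5) measured genes are skipped; a zero null SD
yields NaN with a warning.  Mutant-vs-wild-type comparison of a module's z
row uses the Wilcoxon–Mann–Whitney test, exact when the pooled size is <= 20
with no ties and tie-corrected asymptotic otherwise, reporting both one-sided
tails with BH adjustment per tail across modules.  Sample strata that differ
globally in expression (e.g. blood-derived vs solid-derived lines) should be
analyzed as separate matrices; the API takes whatever sample subset it is
given, so stratification is a matter of calling it per stratum.

## Synthetic data generator

The generator is a pure function of configuration + seed and emulates
exactly the structure the analyses assume: Poisson(`mutations_per_sample`)
counts per sample (default 10); uniform gene assignment (optional per-gene
weights emulate gene length); a consequence mix of 50% missense / 25%
synonymous / 5% stop / 5% frameshift / 4% in-frame / 6% splice / 5% other;
uniform positions within log-normal protein lengths (median ~450 residues,
log-SD 0.6, clipped to [50, 5000]); and i.i.d. Beta(2, 5) FIS for missense
(right-skewed, passenger-dominated).  Driver effects are injected on top:

- `fis_shift` redraws the gene's missense FIS from the background law
  shifted up by `driver_fis_shift` (default 0.6, clipped at 1 — mean
  effective FIS ~0.85, the near-saturating regime of strongly damaging
  driver mutations; shift 0 reproduces the background law exactly);
- `hotspot` moves a fraction (default 1.0) of the gene's positioned PAMs
  onto one random residue;
- both optionally add `driver_n_add` (default 10) extra missense PAMs in
  random samples, because detectable drivers are recurrently mutated — at
  the default cohort size an un-recurrent gene averages ~2.6 PAMs and would
  mostly sit below `min_pams`;
- `module_link` ties an expression-module shift (default +2 noise SD on a
  20-gene module) to the samples mutated in a chosen gene.

What the generator does **not** emulate: trinucleotide mutational
signatures, gene-length-correlated mutation rates (unless weights are
supplied), copy-number events, subclonality, inter-sample mutation-rate
heterogeneity beyond Poisson, and correlated predictors trained on the same
features.  Passing calibration and recovery tests on this generator shows
the statistics are implemented correctly and calibrated under their own
assumptions; it does not show robustness to covariate structure in real
cohorts (the motivation for covariate-adjusted background models, which are
out of scope here).

## Problem sizes used in the shipped checks

Calibration and power studies run at 500 genes x 200 samples (the package's
reference cohort scale) with 10,000 resamplings; hotspot recovery uses 10
replicates of that cohort; SLEA calibration uses 1,000 genes x 200 samples
x 100 size-20 modules with 10,000 random modules, and recovery 50 replicates
of a 200 x 40 matrix with 2,000 random modules (null-moment precision at
2,000 draws is already far below the effect size).  The calibration cohort
uses 25 mutations/sample so that essentially every gene clears `min_pams`
and the uniformity checks run on ~470 tested genes.  The end-to-end demo is
150 genes x 100 samples and re-runs byte-identically from its manifest.

## Numerical choices and degenerate inputs

- Empirical-P comparisons use a 1e-9 tolerance on `>=`.
- P = 0 entering any combination is clipped to the smallest positive float
  with a warning; CLUST P values are floored there too.
- The CLUST null SD is floored at 0.01 (see above).
- Ties in every deterministic ordering break lexicographically (gene symbol,
  sample id); result tables sort by P with untested entries last.
- Untested is represented as absent (`None`), never as P = 1 — this keeps BH
  denominators honest.
- Catalog invariants (roster membership, position <= protein length, FIS in
  [0, 1]) are enforced at construction, so downstream code never re-checks.

## Known limitations

- The FM and CLUST formulations are reconstructions of their verbal
  definitions (statistic, null, constants chosen and documented here), not
  re-implementations of any released tool; numerical agreement with other
  software is not a goal.
- Fisher combination across dependent predictors is anti-conservative (see
  FM bias above).
- The normal CLUST null is a convenience fit; with very few background genes
  its tail behavior is driven by the SD floor.
- Pairwise exclusivity ignores interdependence among more than two genes;
  set-level exclusivity models are out of scope.
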