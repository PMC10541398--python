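# Methods

This note records the models, estimators, numerical choices and known
limits of `clonalpop`, in the order the pipeline applies them.

## Genotype model and filters

Genotypes are biallelic SNP dosages {0, 1, 2} with a distinct missing
sentinel; multiallelic and non-SNP VCF records are skipped on input with
a logged count.  Three site filters mirror the genotype-level options of
de novo RAD genotyping pipelines:

- `min_presence_fraction` (default 0.5): minimum fraction of samples
  with a call at the site;
- `single_snp_per_locus` (default on): keep the lowest-position SNP per
  locus, suppressing intra-locus linkage;
- `min_maf` (default 0.05): minor-allele frequency floor computed over
  non-missing diploid calls; a site exactly at the floor is retained.

The application order — presence, then single-SNP, then MAF — follows
the locus-level-then-site-level logic of such pipelines; it matters (MAF
changes as samples drop) so it is fixed, and the attrition of each step
is reported.  Filtering only selects sites; it never edits calls.

## Clonality statistic

For a pair, on sites called in both samples: *variable* means not both
homozygous for the same allele; *conserved het* means het in both;
the statistic is `100 * conserved / variable`.  Defining "variable" this
way matches what a two-sample run of a genotyping pipeline reports as
polymorphic.  Pairs with no variable sites (or fewer than
`min_variable_sites`, default 50) are *inconclusive*, never 0%.

Under independent allele dropout at rate `d` on each copy of a clone
pair, a founder-het site is het/het with probability (1−d)², and leaves
the denominator only when both copies drop to the *same* homozygote
(probability d²/2), giving the expectation `100(1−d)²/(1−d²/2)`.  This
closed form assumes the dropout direction is an equal-probability coin —
the same convention the simulator uses — and is the calibration oracle
for the noise model: d = 0.35 gives 45.0%, inside the 40–50% band
technical replicates show in practice.

The decision threshold defaults to 40% and is calibrated as
`max(40, min(replicate conservations) − margin)` with a 4-point margin:
replicates bound what genotyping noise alone does, and true clones may
sit a few points lower through somatic loss of heterozygosity.  Clonal
groups are connected components (size ≥ 2) of pairs at or above
threshold — transitive closure, since a lineage is grouped by cluster
membership rather than all-pairs passing.  Pairs within the margin below
threshold are annotated *borderline* for the user instead of being
silently decided.  Tabular output rounds percentages to one decimal,
half-up by default (a truncation mode exists because some legacy tables
truncate); raw ratios are kept internally.

## Diversity and differentiation

Site-level, from non-missing calls within a population: He = 1 − p² − q²;
π = 2·n_ref·n_alt/(n(n−1)) over the n sampled alleles (unbiased mean
pairwise difference); Fis = 1 − Ho/He on sites polymorphic within the
population.  Population summaries include sites genotyped in ≥ 70% of the
population's members; He and π average over all included sites
(within-population-monomorphic sites contribute 0) while Fis averages
where it is defined.  Pairwise Fst is Weir–Cockerham θ: the a/b/c
variance components per site, combined as ratio of sums across sites,
negative per-site components retained.  A clonal group violates the
random-mating sampling assumption behind θ — its members are one founder
genotype — so Fst involving clonal groups is reported as computed but
should be read as lineage divergence, not drift.

## Ordination and clustering

Genotype PCA centers each site by mean dosage, scales by √(2p̂(1−p̂)),
and mean-imputes missing entries before centering; contribution ratios
are eigenvalue shares of the full-rank total (they sum to 100%).
Identity-by-state distance is one minus the mean shared-allele fraction
(2 − |gᵢ − gⱼ|)/2 over sites called in both.  MDS is classical Torgerson
scaling (double-centered squared distances, top-k eigenvectors scaled by
√λ); negative eigenvalues are dropped with a note.  UPGMA uses average
linkage with leaves pre-sorted lexicographically so tied merges resolve
identically under any input order; Newick branch lengths place each node
at half its merge height (ultrametric convention).  Trait tables are
z-scored per trait before PCA; zero-variance traits are dropped,
missing trait values are a hard error.

## Admixture model

Dosages are Binomial(2, π_ij) with π_ij = Σ_k q_ik f_kj.  Fitting is the
classic EM with the per-allele-copy population of origin as latent
variable: both the Q and F updates use responsibilities from the current
parameters, so each iteration increases the log-likelihood (asserted at
run time).  EM was chosen over quasi-Newton block relaxation for
monotonicity and simplicity at desk scale; its boundary convergence is
geometric, hence the deep default budget (`max_iter` 2000, absolute
log-likelihood tolerance 1e−5, 8 starts for `em_fit`).  Q rows start
Dirichlet(1,…,1), F entries Uniform(0.05, 0.95); frequencies are clamped
to [1e−6, 1−1e−6].  All randomness flows from one seed through named
substreams, so fits are reproducible.

K is selected by entry-masking cross-validation: each fold masks 10% of
non-missing calls (redrawn, bounded retries, if a sample or site would
lose all data), refits, and scores mean squared error between held-out
dosage and 2π̂; the grid argmin wins, ties to the smaller K.  Masking
fraction and fold count (default 5; the pipeline uses 3) are reported;
only the argmin is consumed downstream.  Fitted solutions are defined up
to label permutation; evaluation aligns labels by Hungarian assignment
on column mean absolute difference.

## Group and subgroup classification

At K = 3 the two clusters whose member samples are near-pure (dominant
ancestry ≥ 0.95) and coincide with called clonal groups anchor labels A
and B — the smaller cluster is A, a fixed arbitrary-but-deterministic
rule echoed in the output.  With fewer than two pure clonal clusters the
labels fall back to purity alone, with a warning.  C-anchored samples
split by detected gene flow at threshold τ (default 0.05): ancestry from
A and/or B at or above τ gives C2/C3/C4, neither gives C1.  The four
predicates are mutually exclusive and exhaustive, and raising τ moves
samples only toward C1 (property-tested).  τ is a reporting convention,
not an estimate — there is no natural zero for fitted ancestry — so it
is exposed and echoed everywhere.  The regional report cross-tabulates
groups against region labels with a permutation chi-square test (999
shuffles) labelled descriptive.

## Simulator

Population allele frequencies follow a Balding–Nichols construction:
ancestral frequency uniform on (0.1, 0.9) by default, population
frequency Beta-distributed with mean p and variance F_k·p(1−p), F_k the
per-population drift; F = 0 and F = 1 degenerate to the ancestral value
and a fixed 0/1 draw.  Individuals draw two independent allele copies
with success probability Σ q_k f_kj.  Clonal groups copy one founder
with per-het-site somatic loss of heterozygosity (`somatic_mu`);
genotyping noise applies het→random-homozygote dropout (`dropout_d`) and
hom→het miscall (`error_e`) per sample; missingness is per-call MCAR
(`missing_m`).  Technical replicates re-apply noise and missingness to a
source sample's true genotype.

The `wild-garlic` preset emulates a survey of a bulb-propagated wild
onion: K = 3, drift (0.25, 0.25, 0.10), clonal groups A (6) and B (9),
outbred C1 (10), admixed C2 (4, ancestry 0.30 from A), C3 (9, 0.35 from
B), C4 (11, 0.20 from A and 0.30 from B), three replicate pairs,
d = 0.35, e = 0.005, m = 0.10, somatic_mu = 0.01, 10000 raw sites
(~9400 post-filter, the scale of a de novo ddRAD panel).  d comes from
the closed form above (45% expected clone conservation, mid-band); the
admixture fractions are set high enough to be unambiguous at τ = 0.05
given the ~0.02–0.04 spurious-ancestry floor that dropout-distorted
genotypes induce in the fitted Q, which mirrors how visibly such surveys'
admixture bars show gene flow.

What the simulator does *not* emulate: linkage between loci (sites are
independent, so single-SNP-per-locus filtering is cosmetic here),
locus-dropout correlated with divergence (missingness is MCAR, not
restriction-site loss), read-depth-dependent error, null alleles, and
selection.  Passing recovery tests therefore shows the estimators are
correct under the stated generative model, not that real RAD data meets
that model; the MCAR assumption in particular is optimistic for de novo
assemblies.

## Problem sizes and determinism

Recovery checks run at desk scale, chosen to keep Monte-Carlo error
comfortably inside the asserted tolerances: 20–30 samples per population
and 2000–5000 sites for Fst and admixture recovery, 25000 het sites for
the dropout calibration, ten seeds for partition/selection stability.
Every stochastic stage takes an explicit seed; the pipeline reruns
byte-identically under a fixed configuration (wall times are kept out of
checksummed outputs).

## Known limitations

- The admixture EM ignores genotyping error; heavy dropout biases
  fitted ancestry of admixed samples toward their majority component
  (regression dilution through noisy anchor frequencies).  Detected
  gene-flow fractions are therefore conservative.
- Weir–Cockerham θ on clonal groups measures lineage divergence, not
  population drift (above).
- The heterozygosity-ratio screen flags low-het individuals without
  modelling why (inbreeding, dropout severity and true homozygosity are
  confounded at a single threshold).
- Classification assumes exactly three ancestry clusters; other K values
  fall through with a warning rather than a generalized labelling.
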