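# Methods

## Probability model

A biallelic SNP site *i* covered by *n_i* read bases (k_i reference,
n_i − k_i alternative) is modelled as n_i independent draws: the sequenced
chromosome is picked uniformly from the individual's two copies, and the
base is miscalled with probability ε. For dosage g ∈ {0,1,2} this gives

    L(g, n, k) = (1/2^n) [(2−g)ε + g(1−ε)]^(n−k) [gε + (2−g)(1−ε)]^k,

so homozygotes contribute ≈ (1−ε) per concordant base and ε per discordant
base, and heterozygotes contribute exactly 1/2 per base regardless of ε.
ε is a single global constant, default 1e-6 — deliberately far below real
base-quality error rates. The model treats a discordant base at a
homozygous site as near-definitive evidence against the candidate
(log ε ≈ −13.8), which is what gives the score its discriminating power at
a handful of bases; it also means unmodelled errors (mapping artefacts,
contamination) are penalized heavily, a known and intended sharpness.
All products are accumulated in natural-log space; with ε = 1e-6 the
per-candidate likelihood underflows double precision after a few dozen
sites otherwise.

Third-allele bases (matching neither the panel's ref nor alt) are excluded
from n_i rather than folded into either allele: the likelihood is
explicitly biallelic, and counting foreign bases as reference would bias k.

## Null moments, standardization and P values

Under the null the candidate is a random member of the population:
dosages are independent across (LD-pruned) sites with Hardy–Weinberg
frequencies P(g|p) = ((1−p)², 2p(1−p), p²) at alt-allele frequency p.
Expectation and variance of the score follow in closed form by summing the
per-site moments of log L over the genotype distribution. The observed
score standardizes to z = (LS − E)/√V, tested one-sided (a matching
candidate inflates the score). Per-site score contributions are skewed
(a point mass near log ε), but a few hundred sites are enough for the CLT
to make z practically standard normal — the test suite verifies this on
2,000 simulated unrelated pairs with ~500 bases each (KS test, and type-1
error at α = 0.05 inside its 99% binomial interval).

E and V are recomputed per candidate over exactly the sites where that
candidate has a non-missing dosage, so z stays comparable across
candidates with different missingness.

When V = 0 (e.g. all covered sites fixed in the population) z and the
P values are reported as NA, never 0 or 1, so a degenerate panel cannot
produce a spurious match. An empirical P value
(1 + #{LS_sim > LS_j})/(n_draws + 1) over genotype vectors simulated
site-independently from the frequencies (default 99,999 draws; strict
inequality, ties favour the null) is available as a cross-check of the
normal approximation.

## LD pruning

Scores assume independent sites, so the covered sites are pruned by
windowed pairwise r² (window 100 sites, step 30, threshold r² > 0.1,
matching the conventional `--indep-pairwise 100 30 0.1`), repeated until
stable. Of an offending pair the later site in genomic order is removed —
a deliberate, deterministic divergence from PLINK's MAF-based preference;
downstream results require only approximate independence, not PLINK's
exact retained set. Monomorphic reference columns have undefined r²,
treated as 0 (kept). Missing dosages are pairwise-deleted.

r² is estimated from a reference dosage matrix, and the estimate's null
expectation is ≈ 1/n_individuals. With fewer than ~40 individuals that
noise exceeds the 0.1 threshold often enough to prune away most genuinely
independent sites, so the LD reference should be a cohort of ≥ ~150
individuals — the role the population frequency panel plays. `run_match`
accepts a dedicated `ld_reference`; the candidate database is only a
fallback, adequate when it is itself large.

Pruning is applied per query to its covered-site list: coverage patterns
differ across queries, and pruning the union once would discard sites some
queries need.

## Decision rules and evaluation

Both published decision rules are always computed: (1) the candidate with
the highest score, and (2) candidates with p below α/n_tests (Bonferroni;
n_tests defaults to n_queries × n_candidates, overridable to model a larger
screening campaign). `evaluate_decisions` reports sensitivity (true pairs
called), specificity (non-pairs not called) and top-score accuracy against
a truth map; queries whose donor is absent from the database count only
toward specificity.

## Ancestry

Each population A is scored by the expectation of the likelihood score
when the genotype is drawn from A's Hardy–Weinberg distribution,
E(LS_A) = Σ_i Σ_g P(g|p_iA) log L(g, n_i, k_i); the argmax is the
prediction. No variance standardization is applied — the compared scores
share the identical observation set, which is also why sites lacking a
frequency in any candidate population are dropped for all populations.
Ties (relative difference < 1e-9) are flagged and broken lexicographically.

## Sex inference

Per-chromosome read counts are normalized by total library reads, then by
chromosome length; for X and Y, counting is restricted to
non-pseudo-autosomal regions (PARs recombine and carry two copies in both
sexes), and the masked lengths are used. A GRCh37 non-PAR BED ships with
the package (complement of PAR1/PAR2); other references are a
configuration, not separate code. The Y/X normalized-depth ratio is ≈ 1 in
males and ≈ 0 in females up to mismapping noise. A one-feature logistic
regression (scikit-learn, lightly ridge-penalized so separable cohorts
still yield a finite boundary between the class extremes) provides
P(male) and the boundary r*; a reference boundary of 0.43 is shipped for
use without training data. A ratio exactly at r*, or an undefined ratio
(zero X depth), yields a no-call.

## Synthetic data

The generator provides every input the pipeline consumes, with the
statistical structure the model assumes:

* **Panels** — ancestral MAFs uniform on [0.01, 0.5] by default (a
  1/p-weighted spectrum is available); per-population frequencies follow
  the Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F), clipped to the
  open unit interval.
* **Genotypes** — site-independent Binomial(2, p) (HWE). Offspring receive
  one uniformly transmitted allele per parent; missing parental dosages
  propagate.
* **Observations** — depth per site is Poisson(λ); each base's true allele
  comes from the genotype and flips with probability ε_sim (default 1e-3,
  a realistic post-quality-filter base error rate, intentionally larger
  than the scoring model's ε). Contamination draws each base from a second
  genotype with probability f. λ is numerically the genome coverage:
  at coverage ≪ 1, site-level Poisson thinning is statistically equivalent
  to read-level downsampling, without carrying a reference genome.
* **Whole-genome scale** — `simulate_sparse_cohort` draws depths across an
  implicit catalogue of 1,000,000 potential SNP sites and instantiates
  only the covered ones (sites are independent, so nothing is lost). The
  coverage grid 1e-5…1e-3× then yields ~10…1,000 informative bases per
  query, spanning the regime from no power to full power.
* **Depth profiles** — reads multinomially allocated ∝ copy number ×
  chromosome length; female Y receives 1% of the autosomal per-base weight
  as a mismapping noise floor.

What the generator does **not** emulate: linkage disequilibrium (sites are
independent by construction; clumping tests use explicitly planted
correlated columns), read-level artefacts (duplicates, mapping bias,
indels), base-quality variation, and real population frequency spectra.
Passing simulation tests therefore demonstrate the statistical machinery —
calibration, power scaling, relatedness and contamination behaviour —
not performance on any real cohort.

Every stochastic function takes a seed or NumPy `Generator`; identical
seed and inputs reproduce outputs bit-exactly on a given platform.

## Numerical and interface choices

* Coordinates: VCF/pileup/site-count tables 1-based; BED 0-based
  half-open. Leading `chr` is stripped on load.
* Allele matching across files: exact (ref, alt) or exact swap (dosage
  complemented, 2−g); anything else — including A/T and C/G strand
  ambiguities — is dropped rather than guessed.
* Pileup decoding handles the full samtools grammar (`^`+MAPQ, `$`,
  `+n…`/`-n…` indel runs, `*`, `>`/`<`); bases below the Phred threshold
  (default 20) are discarded. Mapping-quality filtering cannot be done on
  pileup text and is assumed applied upstream (e.g. `-q 40` when
  generating the pileup).
* The mitochondrial non-major-allele fraction takes the per-position
  plurality base as major (ties toward the reference) and reports the
  aggregate fraction of disagreeing bases — ~0 for a single donor,
  ~min(f, 1−f) for a two-haplotype mixture at fraction f.

## Problem sizes in the test suite

Test and acceptance-script experiments use panels of 400–2,000 sites
(1,100 for ancestry), 2,000 null scores for calibration, 25 replicates ×
100 candidates per coverage tier, 200 trios, 200 ancestry queries and 300
sex profiles. These sizes put every binomial confidence interval well
inside the asserted bounds while keeping a full run in tens of seconds.

## Known limitations

* ε is global; per-base quality-aware likelihoods are not implemented.
* No kinship estimation: relatives appear only as a simulation scenario,
  and first-degree relatives of a database member can produce significant
  scores (the intermediate-z behaviour is tested, not corrected for).
* The sex model is strictly binary; karyotype anomalies are out of scope.
* No imputation, genotype calling or LD-aware scoring.
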