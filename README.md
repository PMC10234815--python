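# metareid

Gut shotgun-metagenome libraries contain a small number of human reads from
the host. `metareid` quantifies how much personal information those sparse
reads carry. It implements a likelihood-score framework over biallelic SNP
sites for three inferences, together with a synthetic-data generator that
reproduces the framework's power and calibration experiments entirely
in silico:

* **Re-identification** — match an anonymous read set against a database of
  candidate genotype records.
* **Ancestry prediction** — assign the sample to the superpopulation whose
  allele frequencies best explain the reads.
* **Genetic-sex prediction** — classify the sample from the Y/X
  normalized read-depth ratio over non-pseudo-autosomal regions.

The intended audience is researchers studying genomic privacy of microbiome
data, and data stewards who need to estimate re-identification risk before
sharing metagenomes without host-read removal.

## The model

At SNP site *i*, covered by *n<sub>i</sub>* read bases of which
*k<sub>i</sub>* show the reference allele, the probability that a diploid
individual *j* carrying *g<sub>i,j</sub>* ∈ {0,1,2} alternative alleles
produced the bases — with independent per-base error ε (default 10⁻⁶) — is

```
L(g, n, k) = (1/2^n) · [(2−g)ε + g(1−ε)]^(n−k) · [gε + (2−g)(1−ε)]^k
```

The likelihood score of candidate *j* over *N* LD-pruned covered sites is
`LS_j = Σ_i log L(g_ij, n_i, k_i)`. Under the null hypothesis that the reads
came from a random member of the population, genotypes follow Hardy–Weinberg
frequencies P(g|p) = ((1−p)², 2p(1−p), p²), giving closed-form moments
E(LS_pop) and V(LS_pop) that standardize LS into
`z = (LS − E)/√V` and a one-sided normal P value (an empirical P value from
simulated genotype vectors is available as a cross-check). Two decision
rules run side by side: highest score, and P below a Bonferroni-corrected
threshold α/(n_queries × n_candidates).

Ancestry uses the expected score
`E(LS_A) = Σ_i Σ_g P(g|p_iA) log L(g, n_i, k_i)` per population A and takes
the argmax. Sex uses read counts per chromosome normalized by library size
and chromosome length; a logistic regression on the Y/X depth ratio ships
with a reference decision boundary of 0.43.

## Worked example

Simulate a 150-person cohort genotyped at 400 SNPs, with per-site read
evidence for each person at mean depth 1 (~400 bases), then match person
`JPT_0000`'s reads against the whole cohort:

```sh
cat > sim.yaml <<EOF
n_sites: 400
populations: [JPT]
n_individuals: 150
depth: 1.0
eps_sim: 0.001
seed: 99
EOF
metareid simulate --config sim.yaml --out-dir demo
metareid match --obs demo/obs_JPT_0000.tsv \
    --candidates demo/genotypes_JPT.vcf \
    --panel demo/panel.vcf --pop JPT -o matches.tsv
```

The top of `matches.tsv` (sorted by z):

```
query        candidate n_sites n_bases      LS        E         V       z     p_normal  top_score significant
obs_JPT_0000 JPT_0000     273     433  -119.91  -1170.92  13863.01  8.926  2.20e-19    True      True
obs_JPT_0000 JPT_0003     273     433  -852.14  -1170.92  13863.01  2.707  3.39e-03    False     False
obs_JPT_0000 JPT_0079     273     433  -889.42  -1170.92  13863.01  2.391  8.41e-03    False     False
```

Of the ~400 covered sites, 273 survive LD pruning, contributing 433 read
bases. The true donor's score sits 8.9 standard deviations above the
population expectation (P ≈ 2×10⁻¹⁹, far below the corrected threshold
0.05/150), while every other candidate stays within the null range — so
roughly four hundred bases of stool-derived human sequence suffice to
re-identify the donor against this database.

`metareid ancestry`, `metareid sex` and `metareid power-sweep` follow the
same pattern; `metareid <cmd> --help` lists the options, and every output
TSV begins with a manifest (version, parameters, input checksums, seed).

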