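# Methods

## The dissimilarity and the APD statistic

Genotypes are alternate-allele dosages at biallelic SNPs: 0, 1, 2 or
missing. The pairwise statistic is the simple matching coefficient on
genotype states: over the loci called in *both* samples, *S* = matches /
compared, *d* = 1 − *S*. The heterozygote is a state of its own — a 0/1 vs
1/1 comparison is a full mismatch, not a half match. An allele-sharing
variant (per-locus |gᵢ−gⱼ|/2) is available behind `method="allele"` for
comparison but is not used by the pipeline.

Missing data contract: comparisons are pairwise-complete and nothing is
imputed. A pair with zero co-called loci is *undefined*; it is excluded from
that sample's APD and counted in the diagnostics (`n_pairs_used`,
`min_pair_loci`) rather than silently scored 0 or 1, which would bias APD.

APDᵢ is the mean of the sample's defined pairwise *d*; `apd_sd` is the
sample standard deviation (ddof = 1) over those n−1 values. The
collection-level distribution uses the mean *M* and sample SD (ddof = 1) of
the APD values. When all pairs are defined, *M* equals the grand mean of
all C(n,2) pairwise dissimilarities (each *d*ᵢⱼ enters exactly two
per-sample averages); this identity is exercised in the tests.

### Blocked computation

The all-pairs matrix is accumulated over locus blocks (default 10,000
columns) as three state-indicator matrix products plus a co-called-count
product. Per-block counts are integers represented exactly in float32
(valid to 2²⁴ loci per block), then accumulated in int64, so the result is
bit-identical for every block size; a naive per-pair double loop is kept in
the test suite as the independent oracle. Peak memory scales with the block
size and the n×n output.

## Categorization

Six groups cut the APD distribution at M+3SD, M+2SD, M+SD, M, M−SD. The
bottom bin's closure is a design choice: group 6 is the catch-all for
everything below M−SD (samples below M−2SD also fall there, and the M−2SD
edge is still reported as a threshold). Each interior group spans one SD.
Boundary ties resolve upward, toward the more distinct group, so the
partition is total and deterministic; SD = 0 degenerates to "all group 4"
with a warning. Outliers are one-sided — APD > M + k·SD with k = 5 by
default — because distinctness, not redundancy, is what an extreme tail
flags. Distinct/redundant sets take the top/bottom k (default 100) APD
ranks with ties broken on sample id.

The analysis ranks extreme SNP variation only; it cannot verify biological
identity or status, and the distinct set is not a core collection in the
formal sense.

## AMOVA

One-level AMOVA on the same simple-matching distance matrix used for APD
(any precomputed symmetric matrix is accepted). With squared distances:
SSD_total = (1/n)Σ_{i<j}d²ᵢⱼ, SSD_within = Σ_g (1/n_g)Σ_{i<j∈g}d²ᵢⱼ,
SSD_among by difference; σ²_within = MS_within, σ²_among = (MS_among −
MS_within)/n₀ with n₀ = (n − Σn_g²/n)/(g−1). The among-group percentage is
100·σ²_among/(σ²_among+σ²_within); a negative σ²_among (expected under no
structure) is reported as computed and flagged, with a clamp-to-zero option.
No permutation p-value is computed by default; `amova_permutation_test`
provides a seeded label-permutation test when wanted.

## Weir–Goudet group-specific Fst

The allele-matching (β) form. For group *i*, M<sup>w</sup>ᵢ averages over
loci the probability that one allele drawn from each of two *distinct*
individuals of the group matches (computed from individual allele
frequencies xᵢ/2; excluding within-individual pairs removes the
selfing/inbreeding effect). M<sup>b</sup> averages between-group matching
p̄ᵢp̄ⱼ + (1−p̄ᵢ)(1−p̄ⱼ) over loci and group pairs. Then βᵢ =
(M<sup>w</sup>ᵢ − M<sup>b</sup>)/(1 − M<sup>b</sup>), and the overall value
is the unweighted group mean. Loci without the needed calls are skipped per
term; groups with fewer than two samples are dropped with a warning.
Negative βᵢ is meaningful: the group carries more rare alleles than the
average pair of groups. Under a Balding–Nichols simulation the estimator
recovers the simulated θ (tested at θ = 0.01/0.05/0.1 to ±0.02, and ≈0
under the null).

## Sensitivity study

Four axes: random sample subsets, random SNP subsets, removal of loci with
MAF < t (t up to 0.05), removal of loci with missing rate ≥ t (t up to
~0.07). Each scenario's APD vector is correlated (Pearson primary, Spearman
reported alongside since ranking is the concern) against the full-data APD
of the same samples; for sample subsets the reference is the full-data APD
restricted to the retained samples. Replicates default to 5; each scenario
draws its own seed from SeedSequence(master, axis, parameter, replicate),
so a plan is reproducible bit-for-bit and robust to plan reordering.
On the default synthetic panels this reproduces the expected qualitative
pattern: r > 0.98 from ~5000 SNPs up, r ≥ 0.999 for half-collection
subsamples at full SNP count, and markedly more degradation from removing
loci below MAF 0.05 than below 0.001.

## Synthetic germplasm collections

The generator emulates the statistical profile of genebank SNP panels of
selfing crops; it makes no attempt at coalescent realism, linkage, or
ascertainment bias.

* **Frequencies.** Ancestral allele frequency p ~ Beta(0.3, 0.3) (L-shaped
  MAF spectrum); subpopulation frequencies are Balding–Nichols draws
  Beta(p(1−θ)/θ, (1−p)(1−θ)/θ), so θ is also the target Fst for the
  diversity tests. Defaults: 3 subpopulations, θ = 0.05.
* **Selfing.** With probability `selfing_f` (default 0.95) a sample is
  fully homozygous (dosage 2·Bernoulli(p)), else Hardy–Weinberg
  Binomial(2, p) — a per-sample switch, sufficient to mimic inbred
  accessions with a small heterogeneous (landrace-like) fraction.
* **Near-duplicates.** Each of `n_duplicate_pairs` (default 5) pairs is a
  homozygous donor plus a copy whose loci flip to one of the two other
  states with probability `duplicate_mutation_rate` (default 0.001), i.e.
  ~99.9% similarity — redeposited seed lots of the same inbred line. Donors
  are restricted to selfed samples so the planted redundancy signal is not
  confounded with heterozygosity.
* **Outliers.** A Balding–Nichols perturbation of the *same* ancestral
  frequencies is mean-preserving and therefore cannot raise an outlier's
  expected distance to the collection, however large its θ. The outlier
  source population instead mixes an independent ancestral frequency
  vector into the collection's with weight `outlier_theta` (default 0.5):
  0 gives just another subpopulation, 1 an unrelated species. This models
  misclassified or introgressed accessions and produces APD outliers far
  beyond M+5SD.
* **Missingness.** Locus-driven: per-locus rate min(Beta(0.3, 5), 0.95),
  Bernoulli per cell — an L-shaped missing-rate spectrum reaching 0.95.
* Sample order is shuffled so planted samples carry no positional signal;
  everything is reproducible from the config seed.

### What planted-truth tests do and do not show

Planted outliers are recovered exactly (10/10 seeds at the defaults): their
APD shift is a mean-level effect, ~0.15 above the bulk against a 5·SD
threshold. Planted duplicate *pairs* are a different matter. A single
near-identical partner lowers a member's APD by only d̄/(n−1) ≈ 0.0006 at
the default sizes, while the across-sample APD spread from each sample's
own genotype-sampling noise is ≥ ~0.002 (≈ sqrt(E[p(1−p)(1−2p)²]/L)
analytically, confirmed empirically). Bottom-k APD rank therefore cannot
reliably single out isolated duplicate pairs in an otherwise exchangeable
collection, at any realistic frequency spectrum — the pair's near-zero
*pairwise distance* is the reliable signal, and real collections flag
redundant sets successfully because duplicates there come in families of
related, centrally-placed lines rather than as isolated planted pairs. The
suite asserts the true, testable properties (pair distance ≈ flip rate;
adding an exact duplicate strictly lowers APD) and the acceptance check of
bottom-20 recovery documents this resolution limit.

## Numerical and interface choices

* Dosage is int8 with −1 as the missing sentinel; VCF ingestion keeps only
  biallelic SNP records, ignores phase, promotes haploid calls (0→0, 1→2),
  and synthesizes `CHROM:POS` locus ids (`:k` ordinal on collision).
* Filters attribute each removed locus to the first failing rule in the
  order monomorphic → MAF → missing rate; filtering is idempotent.
* All CSVs are written with `%.10g` floats so reruns are byte-identical.
* CLI exit codes: 0 ok, 2 validation, 3 I/O, 4 computation.
* Default problem sizes in the test and acceptance runs (300×5000 for the
  categorization studies, 2000×20,000 for the sensitivity study, 500×5000
  for Fst recovery) are chosen so every property of interest is measurable
  with comfortable statistical margins on a single CPU.

## Known limitations

No imputation, LD pruning, ascertainment-bias correction, or multi-level
AMOVA; GDS/HapMap/DArT native formats are out of scope (convert upstream);
APD comparisons assume one individual represents an accession, which is
biased for heterogeneous landraces; and simple-matching distances on
dosage data carry no allele identity, so `write_vcf` emits synthetic
REF/ALT alleles.
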