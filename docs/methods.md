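# Methods

This note documents the models and procedures implemented in `campop`, the
assumptions behind them, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Data model

Genotypes are diploid biallelic SNP dosages: the count of the ALT allele in
{0, 1, 2}, with −1 reserved for missing calls. All frequency-based
statistics are complete-case per locus: a missing genotype contributes no
alleles anywhere. Half-calls (e.g. `./1`) are treated as fully missing on
input — the information in a half-call is not worth a special code path, and
the convention is stated rather than silent.

## Synthetic panels

The generator produces the statistical structure a GBS diversity panel is
assumed to have after filtering; it is the ground truth against which every
inference stage is tested.

- **Divergence.** Population allele frequencies follow the Balding–Nichols
  model: for ancestral frequency p and divergence F, each population draws
  from Beta(p(1−F)/F, (1−p)(1−F)/F), so E = p and Var = F·p(1−p). F is the
  generating Fst; F = 0 collapses to p exactly. This is the simplest model
  that realizes "two subpopulations at a target Fst" without committing to a
  demographic history.
- **Admixture.** An individual from population j draws
  q ~ Dirichlet(c), c_j = 1 and c_k = α elsewhere. The default α = 0.2
  gives a mean home-cluster membership of ~0.83 for K = 2 — visible
  admixture with most individuals still assignable, which is what diversity
  panels of partially outcrossing crops tend to look like. α = None gives
  one-hot q (unadmixed).
- **Genotypes.** Each of the two allele copies independently picks an origin
  cluster from q, then is ALT with that cluster's frequency. Missingness is
  MCAR at a configurable per-genotype rate.
- **Variant contexts.** Sites are spread over 20 chromosomes proportionally
  to length at unique uniform positions; each site is a transition
  (A↔G/C↔T) with probability t/(1+t) for target Ts/Tv ratio t, else a
  uniform transversion pair.
- **Defaults** are the reference study conditions: K = 2 with 105 + 108
  individuals, 6,192 loci, F = 0.04, Ts/Tv = 2.80, 10% missing calls (the
  filter regime admits up to 20%; 10% is a realistic post-filter GBS level),
  ancestral minor-allele frequencies uniform on (0.05, 0.5), chromosome
  lengths from the bundled reference table.

What the generator does **not** emulate: linkage disequilibrium (loci are
independent), allele-frequency spectra skewed toward rare variants
(ancestral MAF is uniform on its range, so simulated mean gene diversity
≈ 0.37 rather than the ≈ 0.29 typical of real GBS panels), allopolyploid
subgenome structure, genotyping error, and informative missingness. Passing
parameter-recovery tests therefore shows the estimators are correct under
the model, not that real panels satisfy the model.

## Filtering

Three inclusive stages, in order: strictly biallelic SNPs (single-nucleotide
REF and ALT), call rate ≥ `min_call_rate`, MAF ≥ `min_maf`. The defaults are
0.8 and 0.05. The vcftools flag `--max-missing 0.2`, which GBS studies often
cite for "at most 20% missing", actually keeps sites with call rate ≥ 0.2;
both readings are reachable here by setting `min_call_rate` to 0.8 or 0.2,
and the default follows the stated intent (≤ 20% missing). The MAF used for
filtering is the same estimator exported by `divstats`, so the two can never
disagree.

## Landscape summaries

Per-chromosome marker density is (max position − min position) / SNP count,
in kb; this observed-span convention reproduces the bundled reference
table's density column to two decimals, which a rounded-length convention
does not. "Average marker density" is the unweighted mean of the 20
per-chromosome densities (101.77 kb on the reference table); a pooled
genome-wide span/count would weight long chromosomes and give a different
number. A chromosome with one SNP has no span and its density is reported
missing. A panel with zero transversions has an undefined (not infinite)
Ts/Tv ratio.

## Diversity statistics

H = 1 − Σpᵢ² and PIC = 1 − Σpᵢ² − ΣΣ_{i<j} 2pᵢ²pⱼ² from called-allele
frequencies. For biallelic loci PIC ≤ H ≤ 0.5 with max PIC = 0.375 at
p = 0.5; the often-quoted "0.5 ceiling" for biallelic markers is the H cap,
not the PIC cap — the implementation follows the formula. PIC
informativeness bands: ≥ 0.5 highly, [0.25, 0.5) moderately, < 0.25
slightly informative.

Per-population indices use per-locus called sample sizes: uHe applies
2N/(2N−1) with N the individuals typed at that locus (so the reported mean
N column is the mean number typed per locus, below the census size under
missingness), F = 1 − Ho/He is computed only where He > 0 and averaged over
those loci, loci with no calls in a population are excluded from that
population's means, and a private allele is one present in exactly one
population. Shannon's I uses natural logarithms.

## Distances and PCoA

Individual distances are codominant squared dosage differences (0, 1, 4 per
locus) summed over loci called in both individuals and rescaled by
L / L_shared, keeping pairs with different completeness on a common scale; a
pair with no shared loci is an error, not a silent zero. Nei's distance is
D = −ln(Jxy/√(Jx·Jy)) over per-locus homozygosity/identity means and is
undefined (flagged NaN) when the populations share no alleles.

PCoA double-centers −½D², takes the symmetric eigendecomposition, and scales
eigenvectors by √λ. Negative eigenvalues (non-Euclidean input) are reported
but excluded from the explained-variance denominator and never produce
coordinates. Axis signs are arbitrary; tests compare up to sign. Distances
are used raw by default; a `standardize` flag rescales by the maximum entry.

## AMOVA

Each diploid is expanded to two allele rows of ALT indicators; within a
heterozygote the copies are written (1, 0) in fixed arbitrary order, and
every statistic downstream is invariant to that order, so no randomness
enters. Sums of squares are ratios of pairwise squared distances: SS_total =
Σ_pairs d²/(2N), within-group SS analogously inside each grouping, and
SS is partitioned as total = among-pops + among-individuals-within-pops +
within-individuals with df (K−1, N−K, N). Variance components come from the
expected mean squares σ²_WI = MS_WI, σ²_AI = (MS_AI − MS_WI)/2 and σ²_AP =
(MS_AP − MS_AI)/(2n₀) with the unequal-size coefficient
n₀ = (N − Σnₚ²/N)/(K−1). Fst is the among-population share of the summed
components; Nm = [(1/Fst) − 1]/4 (undefined for Fst ≤ 0); Fst > 0.15 is
labelled "significant" differentiation by convention.

Negative component estimates are retained in the table but floored at zero
when computing percentages, with a flag. Missing genotypes propagate through
the same shared-locus rescaling as individual distances. The permutation
test shuffles whole individuals (both allele rows together) among
populations and reports the plain fraction of permutations with Fst ≥ the
observed value, so p = 0 is possible at finite permutation counts. Note that
Nm computed from a rounded Fst differs in the second decimal from Nm
computed from the full-precision value; the implementation always uses full
precision.

## Admixture model

The Gibbs sampler targets the classic admixture model with uncorrelated
cluster frequencies: z (origin of each allele copy) ~ Categorical(q_i),
allele ~ Bernoulli(p_{z,l}), priors p ~ Beta(1,1) and q ~ Dirichlet(1,…,1).
Each sweep samples all z, then p from its Beta posterior, then q from its
Dirichlet posterior. Missing genotypes contribute no likelihood terms and
are skipped in all updates. LnP(D) is estimated as mean(log L) − ½·var(log
L) over retained sweeps (sample variance). Defaults are 500 burn-in + 1,500
retained sweeps; these are desk-scale settings chosen so a full K-grid with
replicates runs in minutes on one CPU, and parameter-recovery tests show
they suffice at the panel sizes used (60–100 individuals, a few hundred
loci). Correlated frequencies, the linkage model and prior population
information are out of scope.

Label switching across replicates is resolved by anchoring on the first run
and permuting each subsequent run's columns by the optimal assignment
(Hungarian algorithm) against the running mean of already-aligned runs.
Evanno's ΔK(K) is the replicate mean of |L(K+1) − 2L(K) + L(K−1)| divided by
the replicate standard deviation of L(K); it exists only for interior K,
K values with zero replicate spread are excluded with a warning, and ties
break toward smaller K (the more parsimonious model). Membership assignment
requires a proportion strictly above the threshold (default 0.5); otherwise
the individual is labelled admixed.

Per-cluster Fst is reported as the heterozygosity deficit
1 − He_cluster/He_pool, with the pool being the size-weighted mean of
cluster frequencies. This is an interpretation, not an estimate of the
generating Balding–Nichols F: pooling K clusters shrinks the apparent
divergence (for K = 2 the expectation is F/(2−F), e.g. ≈ 0.11 at F = 0.2),
and tests compare the fitted statistic against the same deficit computed
from the generating frequencies rather than against raw F.

## Neighbor joining

Classical NJ with the Q-criterion; ties break by the lexicographically
smallest pair of representative leaf labels, making the algorithm
deterministic under input reordering. Negative branch-length estimates are
floored at zero with the excess transferred to the sibling branch
(preserving their sum). On additive matrices the generating topology and
branch lengths are recovered exactly (tested against an independent
path-length construction and cross-checked against scikit-bio's NJ).
Bootstrap support resamples loci with replacement, recomputes distances and
the tree, and annotates each internal edge of the full-data tree with the
percentage of replicates containing the same bipartition; supports attach
to bipartitions, not nodes, avoiding rooting ambiguity. Individuals — not
loci — are the exchangeable units of the AMOVA permutation test, while loci
are the resampling units of the tree bootstrap, matching what each procedure
treats as replicable.

## Pipeline and determinism

The CLI executes the stages in a fixed order from one YAML config. A master
seed feeds a per-stage seed derivation (SeedSequence over (master, stage
index)), so any stage can rerun independently and two runs with the same
config are byte-identical, including the emitted VCF. Reports are
plain-delimited text plus Newick. AMOVA and the per-population indices take
their population labels from the metadata table (`true_pop`, falling back
to `origin_code`); in the synthetic pathway the origin label equals the
generating population.

## Known limitations

- The sampler's LnP(D) is an evidence proxy, adequate for ΔK comparison,
  not a marginal-likelihood estimate.
- Individual distances assume missingness is uninformative; the L/L_shared
  rescaling is unbiased only under MCAR.
- AMOVA p-values are plain permutation fractions; at small permutation
  counts they are granular.
- PCoA on strongly non-Euclidean distance matrices discards negative
  eigenvalues; explained-variance percentages then refer only to the
  positive part.
- All analyses treat loci as unlinked; dense panels with LD will overstate
  effective information (bootstrap supports, permutation significance).
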