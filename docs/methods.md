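# Methods

## The genotyping model

`snvem` treats diploid SNV calling as unsupervised multi-class label
aggregation. The latent variable at locus *i* is its genotype class
*kᵢ* ∈ {AA, CC, GG, TT, AC, AG, AT, CG, CT, GT} (this canonical order —
homozygotes first, heterozygotes lexicographic — is fixed package-wide).
The observations are per-base nucleotide reports, stratified into *L*
"learners". A learner is a base-quality bin (defaults 0–9, 10–19, 20–29,
30+): strata of different quality genuinely have different error
profiles, which is exactly what a per-learner confusion matrix models.
Learner *j*'s parameters are a 10×4 row-stochastic confusion matrix
θⱼ(b | k); the class prior π(k | r) is conditioned on the reference base
*r*, because a single global prior would be dominated by reference
composition and bias every locus toward AA — conditioning makes
"homozygous reference" the high-prior class at every locus.

Given counts nᵢⱼᵦ, the E-step posterior is

    qᵢ(k) ∝ π(k | rᵢ) · ∏ⱼ ∏ᵦ θⱼ(b | k)^nᵢⱼᵦ ,

computed in log space with a log-sum-exp normalization. A zero-depth
locus therefore reproduces its prior row. The M-step re-estimates

    θⱼ(b | k) = (α + Σᵢ qᵢ(k)·nᵢⱼᵦ) / (4α + Σᵢ qᵢ(k)·Σᵦ nᵢⱼᵦ)

with pseudocount α (and analogously for π), i.e. a Dirichlet-MAP update.
A learner with zero retained observations keeps its previous confusion
rows (logged); a reference base with no loci keeps its prior row.

**Monotonicity and convergence.** With pseudocount smoothing, EM's
ascent guarantee applies to the penalized objective — observed-data
log-likelihood plus the Dirichlet log-prior α·Σ log θ + α·Σ log π — not
to the raw log-likelihood, which can dip when the smoothing mass is
non-negligible relative to the data (observable on tiny instances).
`run_em` therefore monitors and converges on the penalized objective,
records both traces per iteration, and the monotonicity property tests
assert on the objective. Convergence: relative objective change below
`tol` (default 1e-6) or `max_iters` (default 50). A non-finite
log-likelihood aborts with a diagnostic.

**Initialization** is structured rather than random: homozygous class
(x,x) emits x with probability 1−ε and each other base ε/3; heterozygous
(x,y) emits x and y with (1−ε)/2 each and the others ε/2; ε defaults to
0.05. Priors put p₀ = 0.998 on homozygous reference, the remainder
uniform. Argmax ties break to the lowest class index for determinism.
Posterior entropy is Shannon entropy in bits (the base must be fixed for
the filter feature to be portable across models).

**Windows and exactness.** The EM is fitted independently per 1 Mb window
per contig. Within a window, loci with identical (reference base, count
matrix) patterns have identical posteriors, so they are collapsed with
multiplicities before fitting — an exact, not approximate, speedup
(property-tested). Windows are merged in coordinate order; a thread pool
may process them concurrently without changing any output byte.

## Pileup construction

pysam parses SAM/BAM; this package only filters and counts. Only
read-to-reference match columns contribute (insertions skipped, deletion
columns yield no observation). Default read filters: exclude unmapped,
secondary, supplementary, duplicate-flagged and QC-fail records and
mapping quality < 20; drop observations with base quality < 13 or non-ACGT
base; skip reference-N loci. All configurable. Overlapping mate pairs are
**not** deduplicated per fragment — both mates count; this keeps the
engine simple and matches the independent-read model of the simulator,
but on real paired data it can double-count fragment evidence at
overlap columns. With an alignment index, regions use random access;
without one, the coordinate-sorted file is streamed and filtered, with
early exit past the window end.

Internally all coordinates are 0-based half-open (BAM/BED convention);
VCF output and samtools-style region strings are 1-based.

## The candidate filter

A candidate (decided genotype ≠ homozygous reference) carries four
features: the genotype (encoded as the categorical class code plus an
is-het indicator, since the bare category has no natural order), depth,
alternate-read fraction, and posterior entropy. The keep/drop classifier
is a `DecisionTreeClassifier` with max depth 5, Gini criterion, balanced
class weights and a fixed `random_state` — depth 5 is a deliberate
capacity bound against overfitting, and the constant tree seed keeps
tie-breaking between the two correlated confidence features stable.
Training labels come from genotype-aware truth matching: a candidate is
"true" only if a truth variant exists at its position with the identical
genotype.

**Default model.** Rather than shipping a serialized tree, the packaged
default is trained on demand (seconds, cached per process, bit-stable
from its fixed seed 20240901) on a documented synthetic regime. A caller
whose generative model matches the simulator produces almost no false
candidates on well-behaved data, so the training regime is one where
untrue candidates actually arise: a 30× experiment with 6 % contaminant
reads from a genome diverged at 1.2 % of its bases. Contaminant alleles
are absent from the truth set, so contaminated divergence sites that
cross the calling threshold are exactly the low-allele-fraction,
higher-entropy false calls the tree should remove. Planted SNVs in that
regime are heterozygous only, because contamination converts
homozygous-alternate sites into het-looking genotype errors that no
keep/drop filter can repair. The training set additionally mixes in a
clean default-condition run so that true candidates span the whole
confidence range; without it the tree sacrifices uncertain-but-true
calls on clean data. Users with a real truth set should train their own
model (`snvem train-filter`); the default is a sensible fallback, not a
substitute for domain-matched training data.

## Evaluation

SNV-only, genotype-aware matching at identical (chrom, pos): true
positive iff the genotypes are identical; a call at a truth locus with
the wrong genotype counts as one false positive **and** one false
negative; optional BED confident regions restrict both sets. For isolated
SNVs this equals haplotype-comparison benchmarking; complex-variant
normalization is out of scope. Undefined precision (zero evaluated calls)
is reported as 1.0 together with an explicit `zero_calls` flag so it
cannot be misread as an earned score. Malformed, non-SNV, genotype-less
or duplicate-position records are skipped and counted.

## The simulator

The generator emulates a small WGS experiment with known truth: i.i.d.
uniform reference; SNVs planted at rate 10⁻³ per bp, heterozygous with
probability 2/3 (roughly the human het:hom balance), alternate allele
uniform over the three non-reference bases; reads of length 100 placed
uniformly, each drawn from one of the two haplotypes, corrupted at its
learner's substitution rate (uniform over wrong bases). Default learner
strata: base qualities 15, 25 and 35 (one per usable default quality bin
— a quality below the default base-quality floor would never enter the
pileup) with error rates 1 %, 0.4 % and 0.1 % and equal weights; defaults
model a 100 kb genome at 30×. Reads are emitted pre-aligned
(perfect mapping, all-match CIGAR, coordinate-sorted SAM) because
alignment is upstream of the caller; an optional FASTQ dump exists for
external aligners. The optional contaminant-read mechanism (rate γ,
divergence δ) draws a read from a diverged copy of the reference whose
variants are excluded from the truth VCF.

Everything is bit-reproducible from the seed. What the simulator does
*not* model — quality-by-cycle and GC biases, indels, mate-pair fragment
geometry, alignment artifacts, mappability structure — bounds what
passing tests show: they validate the inference machinery and its
contracts, not performance on real data.

## Numerical choices and edge cases

- Probabilities are floored at 10⁻¹² (guaranteed by smoothing; also
  applied under the log to tolerate deliberate boundary models in tests).
- Posterior rows sum to 1 within 10⁻⁹; entropy ∈ [0, log₂10].
- VCF QUAL is −10·log₁₀(1 − posterior of the decided class), capped at
  99; records are refused unless sorted.
- `AF`/`ENT` are VCF Floats (32-bit in htslib), so they round-trip at
  text-format precision (~5·10⁻⁷); coordinates, alleles, genotypes and
  `DP` round-trip exactly.
- Ten-class posteriors, diploid only, substitution variants only; indels
  and multi-sample joint calling are out of scope.

## Problem sizes in the packaged checks

The property suite and the acceptance script run at desk scale, chosen so
each statistical assertion is well-powered for its tolerance: exhaustive
posterior enumeration up to depth 4 and 2 learners; 100 random EM
instances for monotonicity; 50 000 vs 5 000 loci at 20× for parameter
recovery (±0.01 on the confusion diagonal); 100 kb at 30× for end-to-end
genotype recovery (f1 ≥ 0.99; exactly 1 in the noiseless limit); and a
120 kb spiked-contamination pair of runs for the filter benchmark.
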