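# Methods

## The problem and the estimator

Shotgun sequencing of a purified virus community (a virome) yields short
reads with no marker gene to anchor taxonomy.  The standard work-around is
to assemble reads into contigs and treat the **contig spectrum** — the
multiset of read counts per contig — as a surrogate for the community's
abundance structure, from which diversity indices are computed.  Assembly,
however, routinely leaves one viral genotype spread over several contigs, so
spectrum-based estimates overestimate diversity.

The **Homologous Virus Diversity Index (HVDI)** corrects for this: contigs
from one sample are compared all-against-all, pairs that align with high
similarity (E-value < 10⁻²⁰) over at least 50 % of the shorter contig are
assigned to the same viral genotype by single linkage, read counts are summed
within genotypes to give a **corrected contig spectrum**, and the diversity
index is computed on those corrected counts:

* Shannon form: H = −Σᵢ pᵢ ln pᵢ over corrected proportions pᵢ (nats;
  natural log throughout, forced by the evenness convention below).
* Chao1 form: S_obs + F₁²/(2 F₂), with F₁/F₂ the numbers of genotypes
  backed by exactly one/two reads; used for rarefaction because it penalizes
  rare contigs.  When F₂ = 0 the bias-corrected form
  S_obs + F₁(F₁−1)/(2(F₂+1)) avoids the division by zero.
* Evenness: Pielou's J = H / ln S, in [0, 1]; undefined (reported as
  `None`) when S = 1, since ln 1 = 0.

## Pipeline

`simulate → qc → assemble → cluster → diversity`, with community-comparison
tools (permutation test, membership matrices, Bray-Curtis + PCoA) on the
side.  Stage parameters, all exposed in `PipelineConfig`:

| stage | parameter | default | meaning |
|---|---|---|---|
| qc | min/max read length | 50 / 300 nt | reads outside are removed |
| qc | max homopolymer run | 7 | runs of ≥ 8 identical bases are low-complexity artifacts |
| qc | ambiguous characters | rejected | unless `allow_ambiguous` |
| assembly | min identity | 0.98 | over the overlap |
| assembly | min overlap | max(25 nt, 50 % of the shorter read) | merge criterion |
| assembly | min contig length | 200 nt | shorter consensi are demoted to singletons |
| clustering | E-value | 10⁻²⁰ within-sample; 10⁻¹⁰ across samples | similarity cut |
| clustering | coverage | 50 % of the shorter contig | alignment extent |
| rarefaction | depth grid | 500 … 20 000 reads | clipped to sample size |

## Synthetic viromes

The simulator provides ground truth the real data cannot: every read carries
its source genotype, start and strand, and the realized per-genotype read
counts (the *truth spectrum*) are the reference against which the HVDI is
judged.

**Genomes** are i.i.d. random sequences at a target GC content (default
0.455, typical of tailed-phage isolates), 10 kb by default.  Two deliberate
departures from raw i.i.d. noise:

* Genomes contain no homopolymer run longer than 7 bases.  The read filter
  removes reads with ≥ 8-base runs as sequencing artifacts; a random genome
  carries ~0.3 genuine 8-base runs per 10 kb, and removing the genuine reads
  that cover one punches a coverage hole that splits the assembly at that
  exact locus.  Keeping the genomes clean keeps the artifact filter
  orthogonal to what the validation measures.
* Genomes share no genes or repeats, unlike real phage databases.  This
  isolates assembler/clustering behavior; it also means the clustering step
  is only ever *tested* for not merging what it should not, plus merging
  genuine fragments — cross-species mosaicism is out of scope.

**Abundance profiles** are solved to a target Pielou evenness by root
bracketing on a one-parameter family (achieved evenness is strictly monotone
in the parameter; the solver reports the achieved value and raises if the
0.01 tolerance cannot be met).  Two families are provided:

* `geometric` (default for general use): pᵢ ∝ r^(i−1).  Spans any evenness,
  but its abundance ratio p₁/p_S explodes as evenness falls — at S = 100 and
  evenness 0.33 the rarest genotype sits ~9 orders of magnitude below the
  commonest, beyond any feasible sequencing effort.
* `dominant_block` (default for the validation grid): m = ⌈S^E⌉ genotypes
  carry 99 % of the community with within-block geometric weights solved for
  the evenness target; the remaining genotypes split a fixed 1 % background
  — the rare biosphere below assembly depth that every real virome carries.
  The block's dynamic range stays within roughly one order of magnitude for
  every evenness target, so a finite read budget can cover each dominant
  genotype to assemblable depth.

**Reads**: source genotype ~ multinomial on the profile; start uniform over
positions where the read fits (genomes are linear, no wrap-around); strand
uniform; length from a discretized normal, mean 200 nt, sd 25, truncated by
rejection to [150, 250] — the truncation is symmetric so the mean stays 200.
Errors default off; a substitution model and homopolymer/ambiguity artifact
injectors exist solely to exercise QC.

A single top-level seed is fanned out to per-stage seeds through a
counter-based `SeedSequence` scheme, so one integer reproduces every
artifact byte-for-byte.

## Assembly

Greedy overlap-layout-consensus.  Candidate overlaps come from exact 25-mer
seeding with an exhaustive-by-construction trick: any qualifying overlap
must contain, inside the earlier-placed read, the later read's first 25-mer
(same strand) or the reverse complement of its last 25-mer (opposite
strand), so indexing every 25-mer position once and querying two words per
read finds all overlaps of ≥ 25 nt.  Per-query seed hits are capped at 25
occurrences (deep-coverage cost control; with ≥ 25 candidate partners the
probability of losing a read's connection to its locus is < 10⁻⁹).
Candidates are verified by direct comparison — substitution-tolerant and
ungapped, which matches the substitution-only error model; indel-heavy data
would need a banded aligner behind the same interface.  Accepted overlaps
are processed best-score-first (ties: lexicographic read id) through a
union-find whose links carry (orientation, offset) frame transforms.
Consensus is per-column majority with the alphabetically first base winning
ties; contigs shorter than 200 nt are demoted to their member reads as
singletons, and unassembled reads are retained as weight-1 spectrum
categories.  Everything is deterministic for a fixed input.

Under this merge rule the Lander–Waterman island calculation says a 10-kb
genome needs roughly 12–15× coverage before the expected number of breaks
per genome falls below ~0.1; the validation grid therefore sizes read
counts for 20× expected coverage of the least abundant *dominant* genotype
(never below 2 000 reads per virome).  This matters: fragments created by
under-coverage are *alignment-disjoint*, so the similarity correction
cannot rejoin them, and a grid run at insufficient depth measures coverage
response rather than the clustering correction.

## Similarity search and E-values

A BLASTN-like seed-and-extend local aligner: exact 25-mer seeds, one
ungapped X-drop extension (match +1, mismatch −2, X = 20) per
(subject, strand, diagonal), both strands searched, self-hits excluded in
within-sample mode.  E = K·m·n·e^(−λS) with λ ≈ 1.33 solved from the
score-generating equation at uniform base composition, K = 0.621 (the
tabulated ungapped value for +1/−2), m the query length and n the total
subject length.  The engine is pluggable — any generator of hit records
with the same fields (including a real BLASTN wrapper) can stand in.

## Validation grid

For every (S, evenness) cell: fresh genome pool, fresh profile (the
rank-to-genotype assignment reshuffles per replicate), error-free reads,
full pipeline, then 100·|HVDI − H_true|/H_true against the Shannon index of
the realized truth counts.  Test-suite and acceptance runs use S ∈
{10, 50, 100}, evenness ∈ {0.10–0.90}, 3 replicates, 10-kb genomes and
read counts from the 20×-minimum-coverage rule (≈ 2 000–130 000 reads per
virome).  Observed behavior: cell means ≤ ~4 % for evenness ≥ 0.33, with
the 0.10 cells showing the grid's largest overestimates — at very low
evenness the true H is small and the scattered background reads (grouped by
genotype in the truth, but appearing as independent singleton contigs in
the spectrum) inflate the estimate proportionally most.

What passing does *not* show: performance on real viromes with shared
genes, strain mixtures, repeats, indel-type errors or amplification bias;
the grid isolates the assembly-fragmentation pathway only.

## Community comparison

The shared-contig statistic for an ordered virome pair (A, B) is the
fraction of `n_sampled` randomly drawn contigs of A with at least one hit
in B (E < 10⁻¹⁰, and by default also ≥ 50 % coverage of the shorter contig
for symmetry with the clustering rule; a flag disables the coverage
condition).  Pairwise hit profiles are computed once and only the sampling
is repeated across iterations.

Two permutation schemes:

* `paired` (default): each of B iterations draws one within-group pair and
  one between-group pair; p = fraction of iterations with between ≥ within.
  "≥", not ">": conservative.
* `pooled`: one within-group draw referred to B between-group draws with
  the mid-p convention for ties — the Monte-Carlo form whose p-values are
  approximately uniform under a label-exchangeable null (verified by KS
  over 200 seeded runs); the paired form is conservative rather than
  calibrated, especially when the discrete statistic produces ties.

Intra-subject pairs are excluded from the between-group pool when subject
labels are provided.

Bray-Curtis distances (Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)) default to corrected-genotype
read-count profiles; global-assembly membership columns are the alternative
feature space.  PCoA is classical metric scaling: double-center −D²/2,
eigendecompose, coordinates from the top-k non-negative eigenvalues.  All
eigenvalues, including negative ones from non-Euclidean distances, are
returned for scree inspection; axes with negative eigenvalues carry zero
coordinates rather than being silently dropped.

## Numerical and degenerate-input choices

* Zero counts are ignored by the Shannon index; an all-zero vector is a
  domain error.
* Evenness values are clamped to [0, 1] against floating spill of H above
  ln S.
* Extremely skewed geometric profiles are floored at the smallest positive
  float so proportions stay strictly positive.
* Consensus ties break alphabetically; greedy ties break on read ids;
  cluster ordering is (count desc, member ids) — all for determinism.
* Bray-Curtis between two all-zero profiles is NaN with a warning, not an
  exception.
* An assembly component whose layout leaves a zero-coverage column (only
  possible through a corrupt merge) is split at the gap rather than emitting
  an ambiguous consensus.

## Known limitations

* The aligner is ungapped end to end; data with indel errors will
  under-merge at both the assembly and clustering stages.
* Quality-score-based trimming is not modeled; QC is purely sequence-based.
* Reads mapping equally well to two contigs are assigned to exactly one
  (their assembly placement); no fractional assignment.
* The simulator's i.i.d. genomes make clustering look cleaner than real
  communities where temperate phages share large gene cassettes.
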