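"""Synthetic virome construction with ground truth.

This module emulates the validation strategy of building mock phage viromes:
a pool of double-stranded DNA phage genomes, a relative-abundance profile
solved to hit a target Pielou evenness, and shotgun-style reads of mean
length 200 nt (bounded 150-250 nt) drawn uniformly across each genome.
Every read carries its source genotype, start and strand, so downstream
estimates can be compared against the realized ("truth") genotype spectrum.

Genomes are i.i.d. random sequences at a target GC content.  Real phage
genomes share genes and repeats; random pools deliberately do not, which
isolates assembler and clustering behavior from database idiosyncrasies.
A FASTA loader (:func:`load_genome_pool`) accepts any user-supplied pool
instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ._seq import decode, encode, revcomp

__all__ = [
    "VirusGenome",
    "GenomePool",
    "AbundanceProfile",
    "SimulatedRead",
    "SimulatedVirome",
    "generate_genome_pool",
    "load_genome_pool",
    "geometric_proportions",
    "dominant_block_proportions",
    "construct_abundance_profile",
    "sample_reads",
    "stage_seed",
]


def stage_seed(master_seed: int, *key: int) -> int:
    """Derive a per-stage integer seed (< 2**31) from one master seed.

    A counter-based scheme built on :class:`numpy.random.SeedSequence`: the
    same (master, key) always yields the same child seed, and distinct keys
    yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class VirusGenome:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomePool:
    """Ordered collection of genomes with the seed that produced it."""

    genomes: tuple[VirusGenome, ...]
    seed: int | None = None

    def __post_init__(self):
        ids = [g.id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("genome ids must be unique")

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, i: int) -> VirusGenome:
        return self.genomes[i]

    @property
    def ids(self) -> list[str]:
        return [g.id for g in self.genomes]

    def gc_content(self) -> float:
        gc = tot = 0
        for g in self.genomes:
            gc += g.sequence.count("G") + g.sequence.count("C")
            tot += len(g.sequence)
        return gc / tot if tot else float("nan")

    def max_shared_kmer_fraction(self, k: int = 25) -> float:
        """Max over genome pairs of the shared-k-mer fraction (Jaccard-like,
        relative to the smaller genome's k-mer set).

        Near zero for i.i.d. random pools; a sanity report that distinct
        genomes are separated well enough not to co-assemble.
        """
        from ._seq import kmer_codes, rc_kmer_codes

        sets = []
        for g in self.genomes:
            c = encode(g.sequence)
            fw = kmer_codes(c, k)
            rc = rc_kmer_codes(c, k)
            sets.append(frozenset(np.minimum(fw, rc).tolist()))
        best = 0.0
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                denom = min(len(sets[i]), len(sets[j]))
                if denom:
                    best = max(best, len(sets[i] & sets[j]) / denom)
        return best


def generate_genome_pool(
    n_genomes: int,
    length_range: tuple[int, int],
    gc_content: float = 0.5,
    seed: int = 0,
    max_homopolymer: int | None = 7,
) -> GenomePool:
    """Generate ``n_genomes`` i.i.d. random dsDNA genomes at a GC target.

    Lengths are drawn uniformly (inclusive) from ``length_range``, which must
    lie within [1000, 500000] nt.

    By default genomes are free of homopolymer runs longer than
    ``max_homopolymer`` (7, matching the read-level low-complexity filter):
    otherwise reads genuinely covering a genomic run are removed by QC, which
    punches coverage holes unrelated to what the filter is meant to catch
    (sequencing artifacts).  Pass ``max_homopolymer=None`` for unconstrained
    i.i.d. sequences.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if not (1000 <= lo <= hi <= 500_000):
        raise ValueError("length_range must satisfy 1000 <= lo <= hi <= 500000")
    if not (0.0 < gc_content < 1.0):
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    width = max(4, len(str(n_genomes)))
    genomes = []
    for i in range(n_genomes):
        length = int(rng.integers(lo, hi + 1))
        codes = rng.choice(4, size=length, p=p).astype(np.uint8)
        if max_homopolymer is not None:
            codes = _break_homopolymer_runs(codes, max_homopolymer, p, rng)
        genomes.append(VirusGenome(id=f"genome_{i + 1:0{width}d}", sequence=decode(codes)))
    return GenomePool(genomes=tuple(genomes), seed=int(seed))


def _break_homopolymer_runs(codes: np.ndarray, max_run: int, p: np.ndarray, rng):
    """Redraw bases inside homopolymer runs longer than ``max_run`` until the
    sequence is clean; preserves length and (approximately) composition."""
    while True:
        same = np.concatenate(([False], codes[1:] == codes[:-1]))
        # position within the current run, via segmented counting
        idx = np.flatnonzero(~same)
        seg_start = np.zeros(codes.size, dtype=np.int64)
        seg_start[idx] = idx
        seg_start = np.maximum.accumulate(seg_start)
        run = np.arange(codes.size) - seg_start + 1
        bad = np.flatnonzero(run > max_run)
        if bad.size == 0:
            return codes
        codes = codes.copy()
        codes[bad] = rng.choice(4, size=bad.size, p=p).astype(np.uint8)


def load_genome_pool(path) -> GenomePool:
    """Load a genome pool from FASTA (e.g. a real phage database extract)."""
    from Bio import SeqIO

    genomes = tuple(
        VirusGenome(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    )
    return GenomePool(genomes=genomes, seed=None)


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative genotype abundances with achieved-evenness metadata."""

    genotype_ids: tuple[str, ...]
    proportions: np.ndarray
    target_evenness: float
    achieved_evenness: float

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if (p <= 0).any():
            raise ValueError("proportions must be strictly positive")
        object.__setattr__(self, "proportions", p)

    @property
    def S(self) -> int:
        return len(self.genotype_ids)

    def shannon(self) -> float:
        p = self.proportions
        return float(-(p * np.log(p)).sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "genotype_ids": list(self.genotype_ids),
                "proportions": self.proportions.tolist(),
                "target_evenness": self.target_evenness,
                "achieved_evenness": self.achieved_evenness,
            },
            indent=2,
        )


def geometric_proportions(S: int, r: float) -> np.ndarray:
    """Geometric abundance family p_i ∝ r**(i-1), normalized; r=1 is uniform."""
    if r >= 1.0:
        return np.full(S, 1.0 / S)
    w = np.power(float(r), np.arange(S, dtype=float))
    p = w / w.sum()
    # keep proportions strictly positive when the deep tail underflows
    return np.maximum(p, 5e-324)


def dominant_block_proportions(
    S: int, target_evenness: float, r: float, background_mass: float = 0.01
) -> np.ndarray:
    """Dominant-block abundance family with bounded dynamic range.

    m = ceil(S**target_evenness) genotypes share nearly all of the community
    (weights geometric with ratio ``r`` within the block); the remaining
    S - m genotypes split ``background_mass`` evenly — the rare biosphere
    below assembly depth that every real virome carries.  The dominant
    block's dynamic range stays within roughly one order of magnitude for
    every evenness target, so a finite read set can cover each dominant
    genotype to assemblable depth — unlike a global geometric profile,
    whose rarest genotypes are beyond any feasible sequencing effort.
    """
    m = min(S, int(np.ceil(S**target_evenness)))
    m = max(m, 1)
    block = geometric_proportions(m, r) * (1.0 - (background_mass if m < S else 0.0))
    if m == S:
        return block
    tail = np.full(S - m, background_mass / (S - m))
    return np.concatenate([block, tail])


def _evenness_of(p: np.ndarray, S: int) -> float:
    p = p[p > 0]  # underflowed tail contributes nothing to the entropy
    return float(-(p * np.log(p)).sum() / np.log(S))


def _geometric_evenness(S: int, r: float) -> float:
    return _evenness_of(geometric_proportions(S, r), S)


def construct_abundance_profile(
    S: int,
    target_evenness: float,
    tolerance: float = 0.01,
    seed: int | None = None,
    genotype_ids: Sequence[str] | None = None,
    family: str = "geometric",
) -> AbundanceProfile:
    """Solve a one-parameter abundance family for a target Pielou evenness.

    Evenness is H/ln(S) of the returned proportions, with H the Shannon index
    in nats.  The family parameter r in (0, 1] makes evenness continuous and
    strictly monotone, so the target is solved by root bracketing; the
    achieved value is reported alongside the target.

    ``family='geometric'`` spans p_i ∝ r**(i-1) over all S genotypes (any
    evenness, unbounded abundance ratio).  ``family='dominant_block'``
    (see :func:`dominant_block_proportions`) concentrates the community in
    ceil(S**target) genotypes with bounded dynamic range, the regime in which
    every effectively present genotype can be sequenced to assemblable depth.

    When ``seed`` is given, the rank-to-genotype assignment is shuffled so
    that replicate profiles differ in which genotypes dominate.
    """
    if S < 2:
        raise ValueError("evenness is undefined for S < 2 (ln(1) = 0)")
    if not (0.0 < target_evenness <= 1.0):
        raise ValueError("target_evenness must be in (0, 1]")
    if family not in ("geometric", "dominant_block"):
        raise ValueError("family must be 'geometric' or 'dominant_block'")
    if genotype_ids is None:
        width = max(4, len(str(S)))
        genotype_ids = tuple(f"genome_{i + 1:0{width}d}" for i in range(S))
    else:
        genotype_ids = tuple(genotype_ids)
        if len(genotype_ids) != S:
            raise ValueError("genotype_ids length must equal S")

    if family == "geometric":
        prop_of = lambda r: geometric_proportions(S, r)
    else:
        prop_of = lambda r: dominant_block_proportions(S, target_evenness, r)

    if target_evenness == 1.0:
        p = np.full(S, 1.0 / S)
        achieved = 1.0
    else:
        lo, hi = 1e-12, 1.0
        f = lambda r: _evenness_of(prop_of(r), S) - target_evenness
        if f(lo) > 0:  # target below what the family reaches at r→0
            r_star = lo
        elif f(hi) < 0:  # at most the background epsilon away from the target
            r_star = hi
        else:
            r_star = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
        p = prop_of(r_star)
        achieved = _evenness_of(p, S)
    if abs(achieved - target_evenness) > tolerance:
        raise RuntimeError(
            f"evenness solver did not converge: achieved {achieved:.6f} "
            f"for target {target_evenness:.6f}"
        )
    if seed is not None:
        rng = np.random.default_rng(seed)
        p = p[rng.permutation(S)]
    return AbundanceProfile(
        genotype_ids=genotype_ids,
        proportions=p,
        target_evenness=float(target_evenness),
        achieved_evenness=float(achieved),
    )


class SimulatedRead:
    """One simulated read with its ground-truth provenance."""

    __slots__ = ("id", "sequence", "source_genotype_id", "source_start", "strand")

    def __init__(self, id, sequence, source_genotype_id, source_start, strand):
        self.id = id
        self.sequence = sequence
        self.source_genotype_id = source_genotype_id
        self.source_start = source_start
        self.strand = strand

    def __repr__(self):
        return (
            f"SimulatedRead({self.id!r}, len={len(self.sequence)}, "
            f"src={self.source_genotype_id!r}@{self.source_start}{self.strand})"
        )


@dataclass
class SimulatedVirome:
    reads: list[SimulatedRead]
    truth_spectrum: dict[str, int]
    seed: int
    profile: AbundanceProfile | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.reads)

    def truth_counts(self) -> np.ndarray:
        """Realized read counts per genotype (descending), zeros dropped."""
        c = np.array(sorted(self.truth_spectrum.values(), reverse=True), dtype=int)
        return c[c > 0]


def _sample_lengths(rng, n, mean, sd, lo, hi):
    """Discretized normal truncated to [lo, hi] by rejection; symmetric, so
    the mean is preserved."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled))).astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_reads(
    pool: GenomePool,
    profile: AbundanceProfile,
    n_reads: int,
    len_mean: int = 200,
    len_sd: float = 25.0,
    len_min: int = 150,
    len_max: int = 250,
    error_rate: float = 0.0,
    homopolymer_artifact_rate: float = 0.0,
    ambiguous_artifact_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedVirome:
    """Draw shotgun reads from a genome pool according to an abundance profile.

    Source genotypes follow a multinomial on the profile proportions; start
    positions are uniform over positions where the read fits (genomes are
    linear, reads never wrap); strands are uniform.  Lengths follow a
    discretized normal (mean ``len_mean``, sd ``len_sd``) truncated to
    [len_min, len_max].

    ``error_rate`` adds uniform substitutions per base.  The two artifact
    rates corrupt a fraction of reads with an injected 8-base homopolymer run
    or an ambiguous 'N', solely to exercise downstream QC.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    pool_by_id = {g.id: g for g in pool.genomes}
    missing = [gid for gid in profile.genotype_ids if gid not in pool_by_id]
    if missing:
        raise ValueError(f"profile genotypes absent from pool: {missing[:3]}...")
    min_genome = min(pool_by_id[g].length for g in profile.genotype_ids)
    if len_max > min_genome:
        raise ValueError(
            f"len_max {len_max} exceeds shortest profiled genome ({min_genome} nt)"
        )
    if not (1 <= len_min <= len_mean <= len_max):
        raise ValueError("require 1 <= len_min <= len_mean <= len_max")

    rng = np.random.default_rng(seed)
    sources = rng.choice(profile.S, size=n_reads, p=profile.proportions)
    lengths = _sample_lengths(rng, n_reads, len_mean, len_sd, len_min, len_max)
    strands = rng.integers(0, 2, size=n_reads)
    u = rng.random(n_reads)

    reads: list[SimulatedRead] = []
    truth = {gid: 0 for gid in profile.genotype_ids}
    width = len(str(max(n_reads, 1)))
    for i in range(n_reads):
        gid = profile.genotype_ids[sources[i]]
        genome = pool_by_id[gid]
        L = int(lengths[i])
        start = int(u[i] * (genome.length - L + 1))
        seq = genome.sequence[start : start + L]
        if strands[i]:
            seq = revcomp(seq)
        reads.append(
            SimulatedRead(
                id=f"read_{i + 1:0{width}d}",
                sequence=seq,
                source_genotype_id=gid,
                source_start=start,
                strand="-" if strands[i] else "+",
            )
        )
        truth[gid] += 1

    if error_rate > 0:
        _apply_substitutions(reads, error_rate, rng)
    if homopolymer_artifact_rate > 0 or ambiguous_artifact_rate > 0:
        _apply_artifacts(reads, homopolymer_artifact_rate, ambiguous_artifact_rate, rng)

    return SimulatedVirome(reads=reads, truth_spectrum=truth, seed=int(seed), profile=profile)


def _apply_substitutions(reads, rate, rng):
    bases = "ACGT"
    for r in reads:
        n = len(r.sequence)
        k = rng.binomial(n, rate)
        if not k:
            continue
        pos = rng.choice(n, size=k, replace=False)
        seq = list(r.sequence)
        for p in pos:
            choices = [b for b in bases if b != seq[p]]
            seq[p] = choices[rng.integers(0, 3)]
        r.sequence = "".join(seq)


def _apply_artifacts(reads, homopolymer_rate, ambiguous_rate, rng):
    for r in reads:
        x = rng.random()
        if x < homopolymer_rate:
            p = int(rng.integers(0, max(1, len(r.sequence) - 8)))
            base = "ACGT"[rng.integers(0, 4)]
            r.sequence = r.sequence[:p] + base * 8 + r.sequence[p + 8 :]
        elif x < homopolymer_rate + ambiguous_rate:
            p = int(rng.integers(0, len(r.sequence)))
            r.sequence = r.sequence[:p] + "N" + r.sequence[p + 1 :]
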