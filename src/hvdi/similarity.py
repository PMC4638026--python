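"""Nucleotide similarity search and genotype clustering of contigs.

Highly similar contigs within one virome are the signature of a single viral
genotype that the assembler failed to join; merging their read counts yields
the corrected contig spectrum that the Homologous Virus Diversity Index is
computed on.  The same search, at a more permissive threshold, quantifies
shared sequence content between viromes.

The engine is a BLASTN-like seed-and-extend local aligner: exact word seeds,
ungapped X-drop extension with match +1 / mismatch -2 scoring, and
Karlin-Altschul E-values over a search space of query length times total
subject length.  It is deliberately simple (no gapped extension; adequate for
the substitution-dominated synthetic data this package targets) and pluggable:
any function producing :class:`SimilarityHit` records can stand in, e.g. a
real BLASTN wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._seq import encode, kmer_codes

__all__ = [
    "SimilarityHit",
    "CorrectedSpectrum",
    "find_similarity_hits",
    "correct_contig_spectrum",
    "cluster_assembly",
    "contig_hit_profile",
    "cross_sample_shared_fraction",
]

MATCH = 1
MISMATCH = -2

# Karlin-Altschul lambda for +1/-2 scoring on uniform base composition:
# solve sum_ij p_i p_j exp(lambda * s_ij) = 1
_LAMBDA = brentq(lambda lam: 0.25 * math.exp(lam) + 0.75 * math.exp(-2 * lam) - 1.0, 1e-6, 5.0)
_K = 0.621  # tabulated ungapped K for +1/-2, uniform composition


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    strand: str  # '+' or '-'
    query_start: int  # 0-based half-open on the forward query
    query_end: int
    subject_start: int
    subject_end: int
    alignment_length: int
    identity: float
    score: int
    bit_score: float
    e_value: float


def _bit_score(score: int) -> float:
    return (_LAMBDA * score - math.log(_K)) / math.log(2.0)


def _e_value(score: int, m: int, n: int) -> float:
    return _K * m * n * math.exp(-_LAMBDA * score)


def _extend_xdrop(qa: np.ndarray, sa: np.ndarray, qp: int, sp: int, k: int,
                  x_drop: int = 20):
    """Ungapped X-drop extension of an exact seed along one diagonal.

    Returns (q_start, q_end, matches, score) in oriented-query coordinates.
    """
    d = qp - sp
    lo = max(0, d)
    hi = min(qa.size, d + sa.size)
    eq = qa[lo:hi] == sa[lo - d : hi - d]
    step = np.where(eq, MATCH, MISMATCH).astype(np.int64)
    seed_lo = qp - lo
    seed_hi = seed_lo + k

    # right of the seed
    right_gain = 0
    right_end = seed_hi
    if seed_hi < step.size:
        c = np.cumsum(step[seed_hi:])
        run_max = np.maximum.accumulate(c)
        drop = np.flatnonzero(run_max - c > x_drop)
        stop = drop[0] if drop.size else c.size
        if stop > 0:
            best = int(np.argmax(c[:stop]))
            if c[best] > 0:
                right_gain = int(c[best])
                right_end = seed_hi + best + 1

    # left of the seed
    left_gain = 0
    left_start = seed_lo
    if seed_lo > 0:
        c = np.cumsum(step[:seed_lo][::-1])
        run_max = np.maximum.accumulate(c)
        drop = np.flatnonzero(run_max - c > x_drop)
        stop = drop[0] if drop.size else c.size
        if stop > 0:
            best = int(np.argmax(c[:stop]))
            if c[best] > 0:
                left_gain = int(c[best])
                left_start = seed_lo - best - 1

    seg = eq[left_start:right_end]
    matches = int(np.count_nonzero(seg))
    length = right_end - left_start
    score = MATCH * matches + MISMATCH * (length - matches)
    return lo + left_start, lo + right_end, matches, score


def find_similarity_hits(
    queries,
    subjects,
    e_value_max: float = 1e-20,
    min_frac_shorter: float = 0.50,
    word_size: int = 25,
    x_drop: int = 20,
    best_hit_only: bool = False,
    exclude_self: bool | None = None,
) -> list[SimilarityHit]:
    """All-vs-all local similarity search between two contig sets.

    ``queries`` and ``subjects`` are ``(id, sequence)`` pairs.  A hit is
    reported when its E-value is below ``e_value_max`` and its alignment
    covers at least ``min_frac_shorter`` of the shorter of the two sequences.
    Both strands are searched.  Self-hits (same id) are excluded automatically
    when the two sets share ids, or as directed by ``exclude_self``.

    With ``best_hit_only`` a single best-scoring hit per (query, subject,
    strand) is reported even if it fails the E-value/coverage thresholds
    (used for read mapping, where the caller applies its own criteria).
    """
    queries = [(str(i), s) for i, s in queries]
    subjects = [(str(i), s) for i, s in subjects]
    if not queries or not subjects:
        return []
    if e_value_max <= 0:
        raise ValueError("e_value_max must be > 0")
    if exclude_self is None:
        q_ids = {i for i, _ in queries}
        s_ids = {i for i, _ in subjects}
        exclude_self = bool(q_ids & s_ids)

    k = word_size
    s_b2 = [encode(s) for _i, s in subjects]
    s_lens = np.array([b.size for b in s_b2], dtype=np.int64)
    if (s_lens < k).all():
        return []
    s_starts = np.concatenate(([0], np.cumsum(s_lens)))[:-1]
    s_concat = np.concatenate(s_b2)
    total_subject = int(s_lens.sum())

    s_codes = kmer_codes(s_concat, k)
    gpos = np.arange(s_codes.size, dtype=np.int64)
    owner = np.searchsorted(s_starts, gpos, side="right") - 1
    valid = gpos - s_starts[owner] + k <= s_lens[owner]
    s_codes = s_codes[valid]
    s_gpos = gpos[valid]
    order = np.argsort(s_codes, kind="stable")
    s_codes = s_codes[order]
    s_gpos = s_gpos[order]

    hits: list[SimilarityHit] = []
    for q_id, q_seq in queries:
        if len(q_seq) < k:
            continue
        q_fw = encode(q_seq)
        for strand in ("+", "-"):
            qa = q_fw if strand == "+" else (3 - q_fw)[::-1]
            codes = kmer_codes(qa, k)
            left = np.searchsorted(s_codes, codes, side="left")
            right = np.searchsorted(s_codes, codes, side="right")
            m = right - left
            hit_mask = m > 0
            if not hit_mask.any():
                continue
            q_pos = np.repeat(np.flatnonzero(hit_mask), m[hit_mask])
            offs = np.concatenate(
                [np.arange(a, b) for a, b in zip(left[hit_mask], right[hit_mask])]
            )
            sg = s_gpos[offs]
            si = np.searchsorted(s_starts, sg, side="right") - 1
            sp = sg - s_starts[si]
            # one extension per (subject, diagonal), from its first seed
            diag = q_pos - sp
            key = si * np.int64(2 * 10**9) + (diag + 10**9)
            uniq_key, first = np.unique(key, return_index=True)
            for idx in first.tolist():
                s_idx = int(si[idx])
                s_id, _ = subjects[s_idx]
                if exclude_self and s_id == q_id:
                    continue
                qs, qe, matches, score = _extend_xdrop(
                    qa, s_b2[s_idx], int(q_pos[idx]), int(sp[idx]), k, x_drop
                )
                alen = qe - qs
                ident = matches / alen
                ev = _e_value(score, len(q_seq), total_subject)
                shorter = min(len(q_seq), int(s_lens[s_idx]))
                if not best_hit_only:
                    if ev >= e_value_max or alen < min_frac_shorter * shorter:
                        continue
                d = int(diag[idx])
                ss = qs - d
                se = qe - d
                if strand == "+":
                    q0, q1 = qs, qe
                else:
                    q0, q1 = len(q_seq) - qe, len(q_seq) - qs
                hits.append(
                    SimilarityHit(
                        query_id=q_id,
                        subject_id=s_id,
                        strand=strand,
                        query_start=q0,
                        query_end=q1,
                        subject_start=ss,
                        subject_end=se,
                        alignment_length=alen,
                        identity=ident,
                        score=score,
                        bit_score=_bit_score(score),
                        e_value=ev,
                    )
                )
    if best_hit_only:
        best: dict[tuple[str, str], SimilarityHit] = {}
        for h in hits:
            cur = best.get((h.query_id, h.subject_id))
            if cur is None or h.score > cur.score:
                best[(h.query_id, h.subject_id)] = h
        hits = list(best.values())
    return hits


@dataclass
class CorrectedSpectrum:
    """Read counts per viral genotype after single-linkage contig merging."""

    cluster_members: list[tuple[str, ...]]  # contig ids per cluster
    counts: np.ndarray  # summed read counts, aligned with cluster_members

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n_genotypes(self) -> int:
        return len(self.cluster_members)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def category_to_cluster(self) -> dict[str, int]:
        out = {}
        for ci, members in enumerate(self.cluster_members):
            for m in members:
                out[m] = ci
        return out


def correct_contig_spectrum(spectrum, hits) -> CorrectedSpectrum:
    """Merge contig counts over connected components of the similarity graph.

    Single linkage: any chain of qualifying pairwise hits places contigs in
    the same genotype, so counts are conserved and the genotype count never
    exceeds the contig count.
    """
    import networkx as nx

    ids = list(spectrum.category_ids)
    id_set = set(ids)
    count_of = dict(zip(ids, spectrum.counts.tolist()))
    g = nx.Graph()
    g.add_nodes_from(ids)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in id_set or h.subject_id not in id_set:
            raise ValueError(
                f"hit references unknown contig: {h.query_id!r} vs {h.subject_id!r}"
            )
        g.add_edge(h.query_id, h.subject_id)
    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        clusters.append((members, sum(count_of[m] for m in members)))
    clusters.sort(key=lambda c: (-c[1], c[0]))
    return CorrectedSpectrum(
        cluster_members=[c[0] for c in clusters],
        counts=np.array([c[1] for c in clusters], dtype=np.int64),
    )


def cluster_assembly(
    result,
    e_value_max: float = 1e-20,
    min_frac_shorter: float = 0.50,
    include_singletons: bool = True,
):
    """Within-sample genotype clustering of an :class:`AssemblyResult`.

    Runs the all-vs-all similarity search over the assembly's spectrum
    categories and returns ``(corrected_spectrum, read_to_cluster)`` where the
    mapping sends each read id to its genotype-cluster index.
    """
    from .assembly import contig_spectrum

    spectrum = contig_spectrum(result, include_singletons=include_singletons)
    cats = result.categories(include_singletons)
    seq_pairs = [(cid, seq) for cid, seq, _m in cats]
    hits = find_similarity_hits(
        seq_pairs, seq_pairs, e_value_max=e_value_max, min_frac_shorter=min_frac_shorter
    )
    corrected = correct_contig_spectrum(spectrum, hits)
    cat_to_cluster = corrected.category_to_cluster()
    read_to_cluster = {}
    for cid, _seq, members in cats:
        ci = cat_to_cluster[cid]
        for rid in members:
            read_to_cluster[rid] = ci
    return corrected, read_to_cluster


def contig_hit_profile(
    contigs_a,
    contigs_b,
    e_value_max: float = 1e-10,
    min_frac_shorter: float = 0.50,
    require_coverage: bool = True,
) -> np.ndarray:
    """Boolean per contig of A: does it hit anything in B below the E-value cut.

    ``require_coverage`` additionally demands the alignment cover half the
    shorter contig, mirroring the within-sample clustering criterion.
    """
    contigs_a = list(contigs_a)
    contigs_b = list(contigs_b)
    if not contigs_a or not contigs_b:
        raise ValueError("both contig sets must be non-empty")
    frac = min_frac_shorter if require_coverage else 0.0
    hits = find_similarity_hits(
        contigs_a, contigs_b, e_value_max=e_value_max, min_frac_shorter=frac,
        exclude_self=False,
    )
    hit_ids = {h.query_id for h in hits}
    return np.array([cid in hit_ids for cid, _s in contigs_a], dtype=bool)


def cross_sample_shared_fraction(
    contigs_a,
    contigs_b,
    e_value_max: float = 1e-10,
    min_frac_shorter: float = 0.50,
    require_coverage: bool = True,
    n_sampled: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of sampled contigs of virome A with >= 1 similar contig in B.

    ``n_sampled`` contigs are drawn without replacement when possible (with
    replacement when ``n_sampled`` exceeds the set size).
    """
    if n_sampled < 1:
        raise ValueError("n_sampled must be >= 1")
    profile = contig_hit_profile(
        contigs_a, contigs_b, e_value_max, min_frac_shorter, require_coverage
    )
    rng = np.random.default_rng(seed)
    replace = n_sampled > profile.size
    idx = rng.choice(profile.size, size=n_sampled, replace=replace)
    return float(profile[idx].mean())
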