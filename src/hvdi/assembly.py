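"""Greedy overlap-layout-consensus assembly of virome reads.

Overlaps are accepted when the aligned region covers at least
``max(min_overlap_abs, min_overlap_frac * shorter_sequence_length)`` at
``min_identity`` or better; both strands are considered.  Candidate overlaps
are found by exact 25-mer seeding, verified by direct (substitution-tolerant,
ungapped) comparison, and merged greedily from the highest-scoring overlap
down, with ties broken by lexicographic read id.  The layout is maintained as
an offset/orientation union-find, and each contig's consensus is called
per-column by majority rule (alphabetical base on ties).

The result is deterministic for a fixed input, and with error-free reads from
well-separated genomes it reconstructs each sufficiently covered genome as a
single contig — the oracle property the diversity-index validation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import decode, encode, kmer_codes, revcomp

__all__ = [
    "Contig",
    "AssemblyResult",
    "ContigSpectrum",
    "assemble",
    "contig_spectrum",
    "map_reads_to_reference",
]

SEED_K = 25  # exact seed word size; overlaps shorter than this are not searched


@dataclass
class Contig:
    id: str
    sequence: str
    member_read_ids: list[str]
    mean_coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def read_count(self) -> int:
        return len(self.member_read_ids)


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    unassembled_singletons: list[tuple[str, str]]  # (read_id, sequence)
    parameters: dict = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(c.read_count for c in self.contigs) + len(self.unassembled_singletons)

    def categories(self, include_singletons: bool = True):
        """Spectrum categories as ``(category_id, sequence, member_read_ids)``.

        Contigs contribute their consensus; unassembled reads contribute
        themselves as weight-1 categories (id = read id).
        """
        cats = [(c.id, c.sequence, list(c.member_read_ids)) for c in self.contigs]
        if include_singletons:
            cats.extend((rid, seq, [rid]) for rid, seq in self.unassembled_singletons)
        return cats

    def read_to_category(self, include_singletons: bool = True) -> dict[str, str]:
        out = {}
        for cid, _seq, members in self.categories(include_singletons):
            for rid in members:
                out[rid] = cid
        return out


@dataclass
class ContigSpectrum:
    """Per-category read counts sorted descending; the raw population surrogate."""

    category_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.size and c.min() < 1:
            raise ValueError("spectrum counts must be >= 1")
        self.counts = c

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


def _normalize_reads(reads) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    for r in reads:
        if hasattr(r, "sequence"):
            ids.append(r.id)
            seqs.append(r.sequence)
        elif hasattr(r, "seq"):
            ids.append(r.id)
            seqs.append(str(r.seq))
        else:
            ids.append(r[0])
            seqs.append(r[1])
    if len(set(ids)) != len(ids):
        raise ValueError("read ids must be unique")
    return ids, seqs


def _expand_ranges(left, right, cap):
    """Indices covering each [left, right) range, truncated at ``cap``."""
    reps = np.minimum(right - left, cap)
    hit = reps > 0
    reps = reps[hit]
    if reps.size == 0:
        return np.empty(0, dtype=np.int64), hit
    base = np.repeat(left[hit], reps)
    cs = np.cumsum(reps)
    within = np.arange(cs[-1], dtype=np.int64) - np.repeat(cs - reps, reps)
    return base + within, hit


def _candidate_overlaps(b2s, starts, lengths, min_overlap_abs, min_overlap_frac,
                        max_seed_occ=25):
    """Vectorized exact 25-mer seed candidate generation.

    Any overlap of >= SEED_K nt between two reads must contain, in the
    earlier-placed read's frame, the later read's first k-mer (same strand)
    or the reverse complement of its last k-mer (flipped).  So it suffices to
    index every k-mer position once and query just those two words per read.

    Returns unique candidates (i, j, flip, param) with i < j, where for
    flip=0 read j's position 0 sits at offset ``param`` in read i's frame and
    for flip=1 read j is reverse-complemented with its base u at coordinate
    ``param - u`` (the flip parameter is symmetric between the two frames).
    """
    k = SEED_K
    n_reads = len(lengths)
    starts_arr = np.asarray(starts, dtype=np.int64)
    lens_arr = np.asarray(lengths, dtype=np.int64)
    concat = np.concatenate(b2s) if b2s else np.empty(0, dtype=np.uint8)
    if concat.size < k:
        return np.empty((0, 4), dtype=np.int64)

    fw = kmer_codes(concat, k)
    npos = fw.size
    owner_full = np.repeat(np.arange(n_reads, dtype=np.int64), lens_arr)
    owner = owner_full[:npos]
    local = np.arange(npos, dtype=np.int64) - starts_arr[owner]
    valid = local + k <= lens_arr[owner]

    idx_gpos = np.flatnonzero(valid)
    idx_codes = fw[idx_gpos]
    order = np.argsort(idx_codes, kind="stable")
    idx_codes = idx_codes[order]
    idx_gpos = idx_gpos[order]

    q_reads = np.flatnonzero(lens_arr >= k)
    if q_reads.size == 0:
        return np.empty((0, 4), dtype=np.int64)
    pref_codes = fw[starts_arr[q_reads]]
    # rc of each read's last k-mer, computed from a (n, k) gather
    cols = (starts_arr[q_reads] + lens_arr[q_reads] - k)[:, None] + np.arange(k)
    suff = concat[cols].astype(np.uint64)
    suff_rc = np.zeros(q_reads.size, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k - 1, -1, -1):
        suff_rc <<= np.uint64(2)
        suff_rc |= three - suff[:, j]

    pairs = []
    for flip, codes in ((0, pref_codes), (1, suff_rc)):
        left = np.searchsorted(idx_codes, codes, side="left")
        right = np.searchsorted(idx_codes, codes, side="right")
        pos_idx, hit = _expand_ranges(left, right, max_seed_occ)
        if pos_idx.size == 0:
            continue
        reps = np.minimum(right - left, max_seed_occ)[hit]
        qj = np.repeat(q_reads[hit], reps)
        g = idx_gpos[pos_idx]
        si = owner_full[g]
        p = g - starts_arr[si]
        # geometry prefilter: implied overlap must reach the merge threshold
        li = lens_arr[si]
        lj = lens_arr[qj]
        v = np.minimum(li, p + lj) - p  # query placed at p in si's frame
        thr = np.maximum(min_overlap_abs, min_overlap_frac * np.minimum(li, lj))
        keep = (si != qj) & (v >= thr)
        pairs.append((qj[keep], si[keep], p[keep], flip))

    if not pairs:
        return np.empty((0, 4), dtype=np.int64)

    max_l = int(lens_arr.max())
    prange = 3 * max_l + k
    if 2 * n_reads * n_reads * prange >= 2**62:
        raise ValueError("input too large for candidate packing")

    keys = []
    for qj, si, p, flip in pairs:
        i = np.minimum(qj, si)
        j = np.maximum(qj, si)
        if flip == 0:
            # query read qj's position 0 sits at si-local p
            param = np.where(si < qj, p, -p)
        else:
            # flipped placement x_si = param - x_qj; symmetric in both frames
            param = p + lens_arr[qj] - 1
        keys.append(((i * n_reads + j) * 2 + flip) * prange + (param + max_l))
    keys = np.unique(np.concatenate(keys))

    param = (keys % prange) - max_l
    rest = keys // prange
    flip = rest % 2
    rest //= 2
    j = rest % n_reads
    i = rest // n_reads
    return np.stack([i, j, flip, param], axis=1)


def _verify_overlaps(cands, seqs, rc_seqs, b2s, rc_b2s, lengths, min_identity,
                     min_overlap_abs, min_overlap_frac):
    """Check candidates by direct comparison.

    Returns accepted overlaps as parallel arrays (i, j, flip, off, score);
    ``off`` is the start of read j's placement in read i's frame (already
    converted for flipped placements).
    """
    if cands.size == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z, z
    exact = min_identity >= 1.0 - 1e-12
    lens_arr = np.asarray(lengths, dtype=np.int64)
    ci, cj, cflip, cparam = cands.T
    li = lens_arr[ci]
    lj = lens_arr[cj]
    off_all = np.where(cflip == 0, cparam, cparam - lj + 1)
    ov_s = np.maximum(0, off_all)
    ov_e = np.minimum(li, off_all + lj)
    v_all = ov_e - ov_s
    thr = np.maximum(min_overlap_abs, min_overlap_frac * np.minimum(li, lj))
    idx = np.flatnonzero(v_all >= thr)

    out_i, out_j, out_flip, out_off, out_score = [], [], [], [], []
    for t in idx.tolist():
        i, j, flip, off = int(ci[t]), int(cj[t]), int(cflip[t]), int(off_all[t])
        s, e = int(ov_s[t]), int(ov_e[t])
        v = e - s
        sj = seqs[j] if flip == 0 else rc_seqs[j]
        if seqs[i][s:e] == sj[s - off : e - off]:
            score = v
        elif exact:
            continue
        else:
            bj = b2s[j] if flip == 0 else rc_b2s[j]
            mm = int(np.count_nonzero(b2s[i][s:e] != bj[s - off : e - off]))
            if 1.0 - mm / v < min_identity - 1e-12:
                continue
            score = v - mm
        out_i.append(i)
        out_j.append(j)
        out_flip.append(flip)
        out_off.append(off)
        out_score.append(score)
    return (
        np.asarray(out_i, dtype=np.int64),
        np.asarray(out_j, dtype=np.int64),
        np.asarray(out_flip, dtype=np.int64),
        np.asarray(out_off, dtype=np.int64),
        np.asarray(out_score, dtype=np.int64),
    )


class _LayoutUnionFind:
    """Union-find whose links carry (flip, offset) frame transforms.

    A node transform (f, t) maps the node's local coordinate x to its parent
    frame: t + x when f=0, t - x when f=1.
    """

    def __init__(self, n):
        self.parent = list(range(n))
        self.f = [0] * n
        self.t = [0] * n
        self.size = [1] * n

    def find(self, x):
        path = []
        while self.parent[x] != x:
            path.append(x)
            x = self.parent[x]
        root = x
        # path compression with transform folding
        for node in reversed(path):
            p = self.parent[node]
            if p != root:
                fp, tp = self.f[p], self.t[p]
                fn, tn = self.f[node], self.t[node]
                self.f[node] = fp ^ fn
                self.t[node] = tp + tn if fp == 0 else tp - tn
                self.parent[node] = root
        return root

    def root_and_transform(self, x):
        root = self.find(x)
        if x == root:
            return root, 0, 0
        return root, self.f[x], self.t[x]

    def union(self, i, j, g_f, g_t):
        """Merge given transform g mapping j-frame -> i-frame."""
        ri, fi, ti = self.root_and_transform(i)
        rj, fj, tj = self.root_and_transform(j)
        if ri == rj:
            return False
        # h : rj-frame -> ri-frame  =  (fi,ti) o g o inv(fj,tj)
        # inv(f,t): f=0 -> (0,-t); f=1 -> (1,t)
        inv_f, inv_t = (0, -tj) if fj == 0 else (1, tj)
        f1 = g_f ^ inv_f
        t1 = g_t + inv_t if g_f == 0 else g_t - inv_t
        hf = fi ^ f1
        ht = ti + t1 if fi == 0 else ti - t1
        if self.size[ri] >= self.size[rj]:
            self.parent[rj] = ri
            self.f[rj], self.t[rj] = hf, ht
            self.size[ri] += self.size[rj]
        else:
            inv_hf, inv_ht = (0, -ht) if hf == 0 else (1, ht)
            self.parent[ri] = rj
            self.f[ri], self.t[ri] = inv_hf, inv_ht
            self.size[rj] += self.size[ri]
        return True


def assemble(
    reads,
    min_identity: float = 0.98,
    min_overlap_frac: float = 0.50,
    min_overlap_abs: int = 25,
    min_contig_len: int = 200,
) -> AssemblyResult:
    """Assemble reads into contigs by greedy overlap merging.

    ``reads`` may be ``(id, sequence)`` pairs, :class:`SimulatedRead` objects
    or Biopython ``SeqRecord``s.  Contigs whose consensus is shorter than
    ``min_contig_len`` are demoted: their member reads are returned as
    unassembled singletons.  Every input read appears in exactly one contig
    or as exactly one singleton.
    """
    if not (0.0 < min_identity <= 1.0) or not (0.0 < min_overlap_frac <= 1.0):
        raise ValueError("min_identity and min_overlap_frac must be in (0, 1]")
    if min_overlap_abs < 1 or min_contig_len < 1:
        raise ValueError("length thresholds must be positive")
    ids, seqs = _normalize_reads(reads)
    params = dict(
        min_identity=min_identity,
        min_overlap_frac=min_overlap_frac,
        min_overlap_abs=min_overlap_abs,
        min_contig_len=min_contig_len,
    )
    n = len(ids)
    if n == 0:
        return AssemblyResult(contigs=[], unassembled_singletons=[], parameters=params)

    b2s = [encode(s) for s in seqs]
    lengths = [len(s) for s in seqs]
    starts = np.concatenate(([0], np.cumsum(lengths)))[:-1]

    cands = _candidate_overlaps(b2s, starts, lengths, min_overlap_abs, min_overlap_frac)
    rc_seqs = [None] * n
    rc_b2s = [None] * n
    if cands.size and (cands[:, 2] == 1).any():
        rc_seqs = [revcomp(s) for s in seqs]
        if min_identity < 1.0 - 1e-12:
            rc_b2s = [(3 - b)[::-1] for b in b2s]
    ov_i, ov_j, ov_flip, ov_off, ov_score = _verify_overlaps(
        cands, seqs, rc_seqs, b2s, rc_b2s, lengths,
        min_identity, min_overlap_abs, min_overlap_frac,
    )

    # greedy: best score first, lexicographic read-id tie-break
    rank = np.empty(n, dtype=np.int64)
    rank[np.argsort(np.asarray(ids, dtype=object), kind="stable")] = np.arange(n)
    order = np.lexsort((rank[ov_j], rank[ov_i], -ov_score))

    uf = _LayoutUnionFind(n)
    lens_list = lengths
    for t in order.tolist():
        i, j, flip, off = int(ov_i[t]), int(ov_j[t]), int(ov_flip[t]), int(ov_off[t])
        if flip == 0:
            uf.union(i, j, 0, off)
        else:
            uf.union(i, j, 1, off + lens_list[j] - 1)

    members: dict[int, list[int]] = {}
    for x in range(n):
        members.setdefault(uf.find(x), []).append(x)

    contigs: list[Contig] = []
    singles: list[tuple[str, str]] = []
    raw_groups = []
    for root, mem in members.items():
        if len(mem) == 1:
            singles.append((ids[mem[0]], seqs[mem[0]]))
        else:
            raw_groups.append(mem)

    for mem in raw_groups:
        placed = []
        for x in mem:
            _root, f, t = uf.root_and_transform(x)
            start = t if f == 0 else t - lengths[x] + 1
            placed.append((x, f, start))
        base = min(p[2] for p in placed)
        span = max(p[2] + lengths[p[0]] for p in placed) - base
        counts = np.zeros((4, span), dtype=np.int32)
        cols = np.arange(span)
        for x, f, start in placed:
            codes = b2s[x] if f == 0 else (3 - b2s[x])[::-1]
            s0 = start - base
            counts[codes, cols[s0 : s0 + lengths[x]]] += 1
        cov = counts.sum(axis=0)
        # a malformed merge could leave uncovered columns: split there
        pieces = _coverage_runs(cov)
        for lo, hi in pieces:
            piece_members = [
                (x, f, start)
                for x, f, start in placed
                if start - base >= lo and start - base + lengths[x] <= hi
            ]
            if not piece_members:
                continue
            consensus = decode(np.argmax(counts[:, lo:hi], axis=0).astype(np.uint8))
            contigs.append(
                Contig(
                    id="",
                    sequence=consensus,
                    member_read_ids=sorted(ids[x] for x, _f, _s in piece_members),
                    mean_coverage=float(cov[lo:hi].mean()),
                )
            )

    # demote short or single-read contigs to singletons
    kept = []
    id_to_seq = dict(zip(ids, seqs))
    for c in contigs:
        if c.length < min_contig_len or c.read_count < 2:
            singles.extend((rid, id_to_seq[rid]) for rid in c.member_read_ids)
        else:
            kept.append(c)
    kept.sort(key=lambda c: (-c.read_count, -c.length, c.member_read_ids[0]))
    width = max(5, len(str(len(kept))))
    for idx, c in enumerate(kept):
        c.id = f"contig_{idx + 1:0{width}d}"
    singles.sort(key=lambda p: p[0])
    return AssemblyResult(contigs=kept, unassembled_singletons=singles, parameters=params)


def _coverage_runs(cov):
    """Maximal runs of positive coverage as [lo, hi) intervals."""
    pos = cov > 0
    if pos.all():
        return [(0, cov.size)]
    edges = np.flatnonzero(np.diff(np.concatenate(([0], pos.view(np.int8), [0]))))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def contig_spectrum(result: AssemblyResult, include_singletons: bool = True) -> ContigSpectrum:
    """Per-contig read counts, descending; the raw contig spectrum."""
    cats = result.categories(include_singletons)
    cats.sort(key=lambda c: (-len(c[2]), c[0]))
    return ContigSpectrum(
        category_ids=[c[0] for c in cats],
        counts=np.array([len(c[2]) for c in cats], dtype=np.int64),
    )


def map_reads_to_reference(
    reads,
    reference,
    min_identity: float = 0.98,
    min_frac: float = 0.50,
):
    """Map reads to a reference genome; returns ``(coverage, mapped_fraction)``.

    A read maps when its best local alignment (either strand) covers at least
    ``min_frac`` of the read length at ``min_identity`` or better.  The
    coverage vector counts mapped-read bases per reference position.
    """
    from .similarity import find_similarity_hits

    ref_id = getattr(reference, "id", "reference")
    ref_seq = getattr(reference, "sequence", None) or str(reference)
    if not ref_seq:
        raise ValueError("reference must be non-empty")
    ids, seqs = _normalize_reads(reads)
    coverage = np.zeros(len(ref_seq), dtype=np.int64)
    mapped = 0
    if not ids:
        return coverage, 0.0
    hits = find_similarity_hits(
        list(zip(ids, seqs)),
        [(ref_id, ref_seq)],
        e_value_max=np.inf,
        min_frac_shorter=0.0,
        best_hit_only=True,
    )
    best = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.score > cur.score:
            best[h.query_id] = h
    for rid, seq in zip(ids, seqs):
        h = best.get(rid)
        if h is None:
            continue
        if h.identity >= min_identity - 1e-12 and h.alignment_length >= min_frac * len(seq):
            mapped += 1
            coverage[h.subject_start : h.subject_end] += 1
    return coverage, mapped / len(ids)
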