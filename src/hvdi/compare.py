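"""Between-community comparisons: permutation tests on shared contigs,
membership of samples in global assemblies, Bray-Curtis beta diversity and
principal coordinates.

The permutation test asks whether viromes share more sequence content within
a group (e.g. chemostat cultures of one donor) than between groups.  Each
iteration draws one within-group virome pair and one between-group pair,
estimates each pair's shared-contig fraction on a random contig sample, and
the empirical p-value is the fraction of iterations in which the
between-group (null) statistic is at least the within-group statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import contig_hit_profile

__all__ = [
    "PermutationResult",
    "MembershipMatrix",
    "permutation_shared_test",
    "assembly_membership_matrix",
    "membership_profiles",
    "bray_curtis_matrix",
    "pcoa",
]


@dataclass
class PermutationResult:
    observed_stat: float  # mean within-group shared fraction
    null_stats: np.ndarray  # per-iteration between-group statistics
    within_stats: np.ndarray = field(repr=False, default=None)
    p_value: float = float("nan")
    B: int = 0
    n_sampled: int = 0
    seed: int = 0
    scheme: str = "paired"

    def summary(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "p_value": self.p_value,
            "B": self.B,
            "n_sampled": self.n_sampled,
            "scheme": self.scheme,
            "within_mean": float(np.mean(self.within_stats)),
            "within_sd": float(np.std(self.within_stats, ddof=1)),
            "between_mean": float(np.mean(self.null_stats)),
            "between_sd": float(np.std(self.null_stats, ddof=1)),
            "null_quantiles": {
                q: float(np.quantile(self.null_stats, q))
                for q in (0.025, 0.25, 0.5, 0.75, 0.975)
            },
        }


def permutation_shared_test(
    group_a,
    group_b,
    B: int = 10_000,
    n_sampled: int = 1000,
    e_value_max: float = 1e-10,
    min_frac_shorter: float = 0.50,
    require_coverage: bool = True,
    subject_labels_a=None,
    subject_labels_b=None,
    seed: int = 0,
    scheme: str = "paired",
) -> PermutationResult:
    """Resampling test of within- vs between-group contig sharing.

    ``group_a`` and ``group_b`` are lists of viromes, each a list of
    ``(contig_id, sequence)`` pairs.  Pairwise hit profiles (which contigs of
    one virome have a similar contig in another, at ``e_value_max``) are
    computed once; each of the ``B`` iterations then samples ``n_sampled``
    contigs per drawn pair.  When subject labels are provided, between-group
    pairs of the same subject are excluded.

    ``scheme='paired'``: p = fraction of iterations where the between-group
    fraction >= the within-group fraction (drawn in the same iteration).
    ``scheme='pooled'``: a single within-group draw is referred to the B
    between-group draws with the mid-p convention for ties,
    p = (1 + #{null > observed} + (1 + #{null == observed}) / 2) / (B + 1),
    the Monte-Carlo form whose p-values are approximately uniform under a
    label-exchangeable null even though the shared-fraction statistic is
    discrete.  The paired ">=" form is conservative.
    """
    if scheme not in ("paired", "pooled"):
        raise ValueError("scheme must be 'paired' or 'pooled'")
    group_a = [list(v) for v in group_a]
    group_b = [list(v) for v in group_b]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two viromes per group")
    if subject_labels_a and len(subject_labels_a) != len(group_a):
        raise ValueError("subject_labels_a length mismatch")
    if subject_labels_b and len(subject_labels_b) != len(group_b):
        raise ValueError("subject_labels_b length mismatch")

    kw = dict(
        e_value_max=e_value_max,
        min_frac_shorter=min_frac_shorter,
        require_coverage=require_coverage,
    )
    groups = (group_a, group_b)
    profiles: dict[tuple, np.ndarray] = {}

    def profile(ga, ia, gb, ib):
        key = (ga, ia, gb, ib)
        if key not in profiles:
            profiles[key] = contig_hit_profile(groups[ga][ia], groups[gb][ib], **kw)
        return profiles[key]

    within_pairs = [(g, i, j) for g in (0, 1) for i in range(len(groups[g]))
                    for j in range(len(groups[g])) if i != j]
    between_pairs = []
    for i in range(len(group_a)):
        for j in range(len(group_b)):
            if (
                subject_labels_a
                and subject_labels_b
                and subject_labels_a[i] == subject_labels_b[j]
            ):
                continue
            between_pairs.append((0, i, 1, j))
            between_pairs.append((1, j, 0, i))
    if not between_pairs:
        raise ValueError("no between-group pairs remain after exclusions")

    rng = np.random.default_rng(seed)

    def draw(prof):
        replace = n_sampled > prof.size
        idx = rng.choice(prof.size, size=n_sampled, replace=replace)
        return float(prof[idx].mean())

    within_stats = np.empty(B)
    null_stats = np.empty(B)
    for b in range(B):
        g, i, j = within_pairs[rng.integers(len(within_pairs))]
        within_stats[b] = draw(profile(g, i, g, j))
        ga, ia, gb, ib = between_pairs[rng.integers(len(between_pairs))]
        null_stats[b] = draw(profile(ga, ia, gb, ib))

    if scheme == "paired":
        observed = float(within_stats.mean())
        p = float((null_stats >= within_stats).mean())
    else:
        observed = float(within_stats[0])
        greater = float((null_stats > observed).sum())
        ties = float((null_stats == observed).sum())
        p = (greater + 0.5 * (ties + 1.0) + 0.5) / (B + 1.0)
    return PermutationResult(
        observed_stat=observed,
        null_stats=null_stats,
        within_stats=within_stats,
        p_value=p,
        B=B,
        n_sampled=n_sampled,
        seed=seed,
        scheme=scheme,
    )


@dataclass
class MembershipMatrix:
    presence: pd.DataFrame  # assemblies x samples, boolean
    percentages: pd.Series  # per sample: % of assemblies containing it

    def __post_init__(self):
        if not self.presence.any(axis=1).all():
            raise ValueError("every assembly must contain at least one sample")


def assembly_membership_matrix(
    global_result,
    contig_sample_labels: dict[str, str],
    include_singletons: bool = True,
) -> MembershipMatrix:
    """Which samples contributed to each global assembly.

    ``global_result`` is an :class:`~hvdi.assembly.AssemblyResult` built over
    contigs pooled from labeled samples (time points, feces, ...), and
    ``contig_sample_labels`` maps every pooled contig id to its sample label.
    The per-sample summary is the percentage of global assemblies containing
    at least one contig from that sample.
    """
    cats = global_result.categories(include_singletons)
    samples = sorted(set(contig_sample_labels.values()))
    rows = {}
    for cid, _seq, members in cats:
        unlabeled = [m for m in members if m not in contig_sample_labels]
        if unlabeled:
            raise ValueError(f"unlabeled pooled contigs: {unlabeled[:3]}")
        present = {s: False for s in samples}
        for m in members:
            present[contig_sample_labels[m]] = True
        rows[cid] = present
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    percentages = 100.0 * presence.mean(axis=0)
    percentages.name = "percent_of_assemblies"
    return MembershipMatrix(presence=presence, percentages=percentages)


def membership_profiles(matrix: MembershipMatrix) -> pd.DataFrame:
    """Per-sample feature vectors over global assemblies (samples x
    assemblies, 0/1), the alternative Bray-Curtis/PCoA input built from
    which samples contributed contigs to which global assemblies."""
    return matrix.presence.T.astype(int)


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between rows of an abundance table.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1] for non-negative
    input.  A pair of all-zero profiles has no defined distance; the cell is
    set to NaN and a warning issued.
    """
    profiles = pd.DataFrame(profiles)
    x = profiles.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundance profiles must be non-negative")
    from scipy.spatial.distance import squareform, pdist

    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(x, metric="braycurtis"))
    if zero_rows.size:
        warnings.warn("all-zero profiles produce undefined Bray-Curtis cells (NaN)")
        for i in zero_rows:
            for j in zero_rows:
                if i != j:
                    d[i, j] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def pcoa(distance_matrix, k: int = 2):
    """Classical metric scaling (principal coordinates analysis).

    Double-centers -D**2/2, eigendecomposes, and builds coordinates from the
    top ``k`` non-negative eigenvalues.  Returns ``(coordinates, eigenvalues)``
    with *all* eigenvalues reported (negative ones included, for scree
    inspection of non-Euclidean distortion), sorted descending.
    """
    dm = pd.DataFrame(distance_matrix)
    d = dm.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    k = min(k, n)
    coords = np.zeros((n, k))
    for axis in range(k):
        if eigval[axis] > 0:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])
    coords = pd.DataFrame(
        coords, index=dm.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return coords, eigval
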