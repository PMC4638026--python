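"""Read-level quality control applied before assembly.

Deterministic filters on length, low-complexity homopolymer runs and
ambiguous characters.  Platform-specific quality trimming (the error model of
semiconductor sequencing) is not modeled; these rules are the sequence-level
subset that can be applied to any FASTA/FASTQ input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from ._seq import has_ambiguous, max_homopolymer_run

__all__ = ["QCReport", "filter_reads"]


@dataclass
class QCReport:
    input_count: int
    removed_short: int
    removed_long: int
    removed_homopolymer: int
    removed_ambiguous: int
    retained_count: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _read_seq(read) -> str:
    if isinstance(read, str):
        return read
    if hasattr(read, "sequence"):
        return read.sequence
    if hasattr(read, "seq"):  # Bio.SeqRecord
        return str(read.seq)
    return read[1]  # (id, seq) pair


def filter_reads(
    reads,
    min_len: int = 50,
    max_len: int = 300,
    max_homopolymer: int = 7,
    allow_ambiguous: bool = False,
):
    """Filter reads; returns ``(retained, QCReport)``.

    A read is removed if it is shorter than ``min_len``, longer than
    ``max_len``, contains a homopolymer run longer than ``max_homopolymer``
    (i.e. a run of >= ``max_homopolymer + 1`` identical bases; the default 7
    rejects runs of 8 or more), or contains an ambiguous character unless
    ``allow_ambiguous``.  Removals are categorized by the first failing rule
    in the order length -> homopolymer -> ambiguity, so the category counts
    sum to exactly ``input_count - retained_count``.
    """
    if min_len <= 0 or max_len <= 0 or max_homopolymer <= 0:
        raise ValueError("thresholds must be positive")
    retained = []
    n_short = n_long = n_homo = n_ambig = 0
    for read in reads:
        seq = _read_seq(read)
        L = len(seq)
        if L < min_len:
            n_short += 1
            continue
        if L > max_len:
            n_long += 1
            continue
        if max_homopolymer_run(seq) > max_homopolymer:
            n_homo += 1
            continue
        if not allow_ambiguous and has_ambiguous(seq):
            n_ambig += 1
            continue
        retained.append(read)
    report = QCReport(
        input_count=len(retained) + n_short + n_long + n_homo + n_ambig,
        removed_short=n_short,
        removed_long=n_long,
        removed_homopolymer=n_homo,
        removed_ambiguous=n_ambig,
        retained_count=len(retained),
    )
    return retained, report
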