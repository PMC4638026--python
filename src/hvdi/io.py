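"""FASTA/FASTQ/TSV/JSON input and output for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input FASTA not found: {path}")
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input FASTQ not found: {path}")
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_sequences(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ based on extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return read_fastq(path)
    return read_fasta(path)


def _records(pairs):
    for rid, seq in pairs:
        yield SeqRecord(Seq(seq), id=str(rid), description="")


def write_fasta(pairs, path) -> None:
    SeqIO.write(_records(pairs), str(path), "fasta")


def write_fastq(pairs, path, quality: int = 30) -> None:
    """FASTQ with constant per-base quality (synthetic reads carry no real
    quality information)."""

    def recs():
        for rec in _records(pairs):
            rec.letter_annotations["phred_quality"] = [quality] * len(rec.seq)
            yield rec

    SeqIO.write(recs(), str(path), "fastq")


def write_truth_table(virome, path) -> None:
    df = pd.DataFrame(
        {
            "read_id": [r.id for r in virome.reads],
            "genotype_id": [r.source_genotype_id for r in virome.reads],
            "start": [r.source_start for r in virome.reads],
            "strand": [r.strand for r in virome.reads],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "genotype_id": str})


def write_spectrum(spectrum, path) -> None:
    ids = getattr(spectrum, "category_ids", None)
    if ids is None:
        ids = ["|".join(m) for m in spectrum.cluster_members]
    pd.DataFrame({"category_id": ids, "read_count": spectrum.counts}).to_csv(
        path, sep="\t", index=False
    )


def write_hits(hits, path) -> None:
    """Tabular pairwise-search output (the standard 12 columns)."""
    rows = [
        (
            h.query_id,
            h.subject_id,
            round(100.0 * h.identity, 2),
            h.alignment_length,
            h.alignment_length - round(h.identity * h.alignment_length),
            0,
            h.query_start + 1,
            h.query_end,
            h.subject_start + 1 if h.strand == "+" else h.subject_end,
            h.subject_end if h.strand == "+" else h.subject_start + 1,
            f"{h.e_value:.2e}",
            round(h.bit_score, 1),
        )
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    ).to_csv(path, sep="\t", index=False, header=False)


def write_clusters(corrected, path) -> None:
    rows = []
    for ci, (members, count) in enumerate(
        zip(corrected.cluster_members, corrected.counts)
    ):
        for m in members:
            rows.append((f"genotype_{ci + 1:05d}", m, int(count)))
    pd.DataFrame(rows, columns=["cluster_id", "contig_id", "cluster_read_count"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
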