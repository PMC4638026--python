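"""End-to-end pipeline wiring: configuration, stage execution, fixtures.

A :class:`PipelineConfig` captures every stage parameter plus one top-level
seed; per-stage seeds are fanned out deterministically from it, so a single
(config, seed) pair reproduces every artifact byte-for-byte.  Stages run in
order simulate/ingest -> QC -> assemble -> cluster -> diversity, and each
written artifact directory is stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .assembly import AssemblyResult, assemble, contig_spectrum
from .diversity import DiversityResult, hvdi, rarefaction_curve
from .qc import filter_reads
from .similarity import CorrectedSpectrum, cluster_assembly, correct_contig_spectrum
from .simulate import (
    construct_abundance_profile,
    generate_genome_pool,
    sample_reads,
    stage_seed,
)

log = logging.getLogger("hvdi")

__all__ = [
    "PipelineConfig",
    "ViromeAnalysis",
    "analyze_virome",
    "run_pipeline",
    "generate_fixture_set",
]


@dataclass
class PipelineConfig:
    """Serializable parameters for every pipeline stage."""

    seed: int = 0
    # simulation (used when no input FASTA/FASTQ is given)
    n_genomes: int = 10
    genome_length_range: tuple[int, int] = (10_000, 10_000)
    gc_content: float = 0.455
    target_evenness: float = 0.67
    evenness_tolerance: float = 0.01
    abundance_family: str = "dominant_block"
    n_reads: int = 8000
    len_mean: int = 200
    len_sd: float = 25.0
    len_min: int = 150
    len_max: int = 250
    error_rate: float = 0.0
    homopolymer_artifact_rate: float = 0.0
    ambiguous_artifact_rate: float = 0.0
    # ingest (overrides simulation when set)
    input_reads: str | None = None
    # QC
    qc_min_len: int = 50
    qc_max_len: int = 300
    qc_max_homopolymer: int = 7
    qc_allow_ambiguous: bool = False
    # assembly
    min_identity: float = 0.98
    min_overlap_frac: float = 0.50
    min_overlap_abs: int = 25
    min_contig_len: int = 200
    # genotype clustering
    cluster_e_value_max: float = 1e-20
    cluster_min_frac_shorter: float = 0.50
    include_singletons: bool = True
    # diversity
    rarefaction_depths: tuple[int, ...] | None = None
    rarefaction_reps: int = 10
    # output
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome_length_range"] = list(d["genome_length_range"])
        if d["rarefaction_depths"] is not None:
            d["rarefaction_depths"] = list(d["rarefaction_depths"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "genome_length_range" in d:
            d["genome_length_range"] = tuple(d["genome_length_range"])
        if d.get("rarefaction_depths") is not None:
            d["rarefaction_depths"] = tuple(d["rarefaction_depths"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ViromeAnalysis:
    """Artifact bundle for one virome run through the pipeline."""

    qc_report: object
    assembly: AssemblyResult
    raw_spectrum: object
    corrected: CorrectedSpectrum
    diversity: DiversityResult
    read_to_cluster: dict[str, int] = field(repr=False, default_factory=dict)


def _truth_clustering(result: AssemblyResult, reads, include_singletons: bool):
    """Clustering oracle: assign every contig to its true source genotype
    using the simulator truth table (majority vote over member reads)."""
    src = {r.id: r.source_genotype_id for r in reads}
    spectrum = contig_spectrum(result, include_singletons=include_singletons)
    counts_by_geno: dict[str, int] = {}
    members_by_geno: dict[str, list[str]] = {}
    cat_members = {cid: members for cid, _s, members in result.categories(include_singletons)}
    for cid, count in zip(spectrum.category_ids, spectrum.counts):
        genos = [src[rid] for rid in cat_members[cid]]
        top = max(set(genos), key=genos.count)
        counts_by_geno[top] = counts_by_geno.get(top, 0) + int(count)
        members_by_geno.setdefault(top, []).append(cid)
    order = sorted(counts_by_geno, key=lambda g: (-counts_by_geno[g], g))
    corrected = CorrectedSpectrum(
        cluster_members=[tuple(sorted(members_by_geno[g])) for g in order],
        counts=np.array([counts_by_geno[g] for g in order], dtype=np.int64),
    )
    cat_to_cluster = corrected.category_to_cluster()
    read_to_cluster = {
        rid: cat_to_cluster[cid]
        for cid, members in cat_members.items()
        for rid in members
    }
    return corrected, read_to_cluster


def analyze_virome(
    virome_or_reads,
    config: PipelineConfig | None = None,
    qc: bool = True,
    clustering: str = "similarity",
) -> ViromeAnalysis:
    """QC -> assemble -> cluster -> diversity for one read set.

    ``virome_or_reads`` is a :class:`~hvdi.simulate.SimulatedVirome` or any
    list of reads accepted by :func:`~hvdi.qc.filter_reads`.
    ``clustering='truth'`` uses the simulator truth table as a perfect
    clustering oracle (only available for simulated input).
    """
    cfg = config or PipelineConfig()
    reads = getattr(virome_or_reads, "reads", virome_or_reads)

    if qc:
        retained, report = filter_reads(
            reads,
            min_len=cfg.qc_min_len,
            max_len=cfg.qc_max_len,
            max_homopolymer=cfg.qc_max_homopolymer,
            allow_ambiguous=cfg.qc_allow_ambiguous,
        )
    else:
        retained, report = list(reads), None
    log.info("qc: %d reads in, %d retained", len(reads), len(retained))

    result = assemble(
        retained,
        min_identity=cfg.min_identity,
        min_overlap_frac=cfg.min_overlap_frac,
        min_overlap_abs=cfg.min_overlap_abs,
        min_contig_len=cfg.min_contig_len,
    )
    raw = contig_spectrum(result, include_singletons=cfg.include_singletons)
    log.info(
        "assembly: %d contigs, %d singletons", len(result.contigs),
        len(result.unassembled_singletons),
    )

    if clustering == "truth":
        corrected, read_to_cluster = _truth_clustering(
            result, reads, cfg.include_singletons
        )
    else:
        corrected, read_to_cluster = cluster_assembly(
            result,
            e_value_max=cfg.cluster_e_value_max,
            min_frac_shorter=cfg.cluster_min_frac_shorter,
            include_singletons=cfg.include_singletons,
        )
    log.info("clustering: %d genotypes from %d categories",
             corrected.n_genotypes, len(raw.category_ids))

    div = hvdi(corrected, index="shannon")
    return ViromeAnalysis(
        qc_report=report,
        assembly=result,
        raw_spectrum=raw,
        corrected=corrected,
        diversity=div,
        read_to_cluster=read_to_cluster,
    )


def run_pipeline(config: PipelineConfig) -> ViromeAnalysis:
    """Execute the full pipeline from a config; write artifacts if out_dir set.

    Simulates a virome (or ingests ``input_reads``), then runs
    :func:`analyze_virome` plus rarefaction.  Every output is stamped with the
    config hash and seed in ``run_info.json``.
    """
    stage = "simulate/ingest"
    try:
        if config.input_reads is not None:
            reads = hio.read_sequences(config.input_reads)
            virome = None
        else:
            pool = generate_genome_pool(
                config.n_genomes,
                config.genome_length_range,
                gc_content=config.gc_content,
                seed=stage_seed(config.seed, 0),
            )
            profile = construct_abundance_profile(
                config.n_genomes,
                config.target_evenness,
                tolerance=config.evenness_tolerance,
                seed=stage_seed(config.seed, 1),
                genotype_ids=pool.ids,
                family=config.abundance_family,
            )
            virome = sample_reads(
                pool,
                profile,
                config.n_reads,
                len_mean=config.len_mean,
                len_sd=config.len_sd,
                len_min=config.len_min,
                len_max=config.len_max,
                error_rate=config.error_rate,
                homopolymer_artifact_rate=config.homopolymer_artifact_rate,
                ambiguous_artifact_rate=config.ambiguous_artifact_rate,
                seed=stage_seed(config.seed, 2),
            )
            reads = virome.reads
        stage = "analysis"
        out = analyze_virome(virome if virome is not None else reads, config)
        stage = "rarefaction"
        rare = None
        if out.read_to_cluster:
            n = len(out.read_to_cluster)
            depths = config.rarefaction_depths
            if depths is not None:
                depths = [d for d in depths if d <= n]
            rare = rarefaction_curve(
                out.read_to_cluster,
                depths=depths or None,
                reps_per_depth=config.rarefaction_reps,
                seed=stage_seed(config.seed, 3),
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if config.out_dir:
        stage = "write"
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if virome is not None:
            hio.write_fasta([(g.id, g.sequence) for g in pool.genomes],
                            out_dir / "genomes.fasta")
            hio.write_fasta([(r.id, r.sequence) for r in virome.reads],
                            out_dir / "reads.fasta")
            hio.write_truth_table(virome, out_dir / "truth.tsv")
            (out_dir / "profile.json").write_text(profile.to_json())
        if out.qc_report is not None:
            (out_dir / "qc_report.json").write_text(out.qc_report.to_json())
        hio.write_fasta([(c.id, c.sequence) for c in out.assembly.contigs],
                        out_dir / "contigs.fasta")
        hio.write_spectrum(out.raw_spectrum, out_dir / "spectrum.tsv")
        hio.write_clusters(out.corrected, out_dir / "clusters.tsv")
        hio.write_spectrum(out.corrected, out_dir / "corrected_spectrum.tsv")
        div = out.diversity
        hio.write_json(
            {
                "H": div.H, "S_obs": div.S_obs, "evenness": div.evenness,
                "chao1": div.chao1, "F1": div.F1, "F2": div.F2,
            },
            out_dir / "diversity.json",
        )
        if rare is not None:
            rare.to_csv(out_dir / "rarefaction.tsv", sep="\t", index=False)
        hio.write_json(
            {"config_hash": config.config_hash(), "seed": config.seed,
             "config": config.to_dict()},
            out_dir / "run_info.json",
        )
    return out


def generate_fixture_set(out_dir, seed: int = 0) -> dict:
    """Write the deterministic fixtures used by the test suite.

    Emits a 5-genome pool, error-free reads tiled across one genome, a contig
    set containing a known duplicate pair, three virome pairs sharing 0 %,
    50 % and 100 % of their source genomes, and a 5-time-point series with a
    persistent genome subset.  Returns the in-memory objects as well.
    """
    from .simulate import GenomePool

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx: dict = {}

    pool = generate_genome_pool(5, (8000, 12000), seed=stage_seed(seed, 10))
    hio.write_fasta([(g.id, g.sequence) for g in pool.genomes],
                    out_dir / "pool5.fasta")
    fx["pool"] = pool

    # error-free reads tiled every 50 nt across genome 1, alternating strands
    from ._seq import revcomp

    g0 = pool[0]
    tiled = []
    starts = list(range(0, g0.length - 200 + 1, 50))
    if starts[-1] != g0.length - 200:
        starts.append(g0.length - 200)  # cover the genome tail exactly
    for idx, start in enumerate(starts):
        seq = g0.sequence[start : start + 200]
        strand = "-" if idx % 2 else "+"
        tiled.append((f"tile_{idx + 1:05d}", revcomp(seq) if strand == "-" else seq))
    hio.write_fasta(tiled, out_dir / "tiled_reads.fasta")
    fx["tiled_reads"] = tiled
    fx["tiled_source"] = g0

    # contig set with a known duplicate pair: two overlapping halves of g1
    g1 = pool[1]
    dup_contigs = [
        ("ctg_a", g1.sequence[:3000]),
        ("ctg_a_dup", g1.sequence[500:3000]),  # contained in ctg_a
        ("ctg_b", g1.sequence[5000:8000]),
        ("ctg_c", pool[2].sequence[:3000]),
    ]
    hio.write_fasta(dup_contigs, out_dir / "dup_contigs.fasta")
    fx["dup_contigs"] = dup_contigs

    # virome pairs with 0 / 50 / 100 % shared source genomes
    big = generate_genome_pool(8, (10000, 10000), seed=stage_seed(seed, 11))
    fx["share_pairs"] = {}
    for frac, gen_a, gen_b in (
        (0, big.genomes[:4], big.genomes[4:]),
        (50, big.genomes[:4], big.genomes[2:6]),
        (100, big.genomes[:4], big.genomes[:4]),
    ):
        pair = []
        for tag, genomes in (("a", gen_a), ("b", gen_b)):
            sub = GenomePool(genomes=tuple(genomes))
            prof = construct_abundance_profile(
                len(genomes), 1.0, genotype_ids=sub.ids
            )
            vir = sample_reads(
                sub, prof, 4000, seed=stage_seed(seed, 12, frac, 0 if tag == "a" else 1)
            )
            hio.write_fasta(
                [(r.id, r.sequence) for r in vir.reads],
                out_dir / f"share{frac}_{tag}_reads.fasta",
            )
            hio.write_truth_table(vir, out_dir / f"share{frac}_{tag}_truth.tsv")
            pair.append(vir)
        fx["share_pairs"][frac] = tuple(pair)

    # 5-time-point persistence series: genomes 1-2 persistent, rest transient
    series_pool = generate_genome_pool(7, (10000, 10000), seed=stage_seed(seed, 13))
    persistent = series_pool.genomes[:2]
    fx["series"] = []
    for t in range(5):
        genomes = tuple(persistent) + (series_pool.genomes[2 + t],)
        sub = GenomePool(genomes=genomes)
        prof = construct_abundance_profile(len(genomes), 1.0, genotype_ids=sub.ids)
        vir = sample_reads(sub, prof, 2500, seed=stage_seed(seed, 14, t))
        hio.write_fasta(
            [(r.id, r.sequence) for r in vir.reads],
            out_dir / f"series_t{t}_reads.fasta",
        )
        fx["series"].append(vir)
    fx["series_persistent_ids"] = [g.id for g in persistent]

    hio.write_json({"seed": seed}, out_dir / "fixture_info.json")
    return fx
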