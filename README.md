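# hvdi — phage community diversity from virome contig spectra

Estimating how diverse a bacteriophage community is from shotgun virome
sequencing is harder than it looks: without a marker gene, diversity must be
read off the assembly itself, and assemblers routinely scatter one viral
genotype over several contigs, inflating every index computed on per-contig
read counts.  `hvdi` implements the **Homologous Virus Diversity Index**,
which repairs the contig spectrum before estimating diversity: contigs from
the same sample that align with high similarity (E < 10⁻²⁰ over ≥ 50 % of
the shorter contig) are merged into single viral genotypes by single
linkage, their read counts are summed into a *corrected contig spectrum*,
and diversity is computed on the corrected counts,

    H      = −Σᵢ pᵢ ln pᵢ                (Shannon, nats)
    J      = H / ln S                     (Pielou evenness)
    Chao1  = S_obs + F₁² / (2 F₂)         (richness; F₁ singletons, F₂ doubletons)

The package is aimed at microbiome/virome researchers who want to benchmark
or apply spectrum-based diversity estimation with full ground truth.  It
contains:

* a **synthetic virome simulator** — genome pools, abundance profiles solved
  to a target Pielou evenness, shotgun reads (mean 200 nt, 150–250 nt)
  with per-read source/strand/position truth tables;
* read **QC** (length, homopolymer, ambiguity filters);
* a deterministic greedy **overlap-consensus assembler** (98 % identity,
  overlap ≥ max(25 nt, 50 % of the shorter read), majority-rule consensus);
* BLASTN-like **similarity search** (seed-and-extend, Karlin–Altschul
  E-values) and single-linkage **genotype clustering**;
* **diversity** estimation (Shannon/Chao1 HVDI, evenness, rarefaction) and
  the richness × evenness **validation grid**;
* **community comparison**: shared-contig permutation tests, global-assembly
  membership matrices, Bray-Curtis distances and PCoA.

## Worked example

Simulate a 10-genotype community at evenness 0.67, run the full pipeline,
and compare the HVDI with the Shannon index of the realized per-genotype
read counts (the simulator's ground truth):

```python
from hvdi import (generate_genome_pool, construct_abundance_profile,
                  sample_reads, analyze_virome, shannon_index)

pool    = generate_genome_pool(10, (10_000, 10_000), gc_content=0.455, seed=7)
profile = construct_abundance_profile(10, 0.67, seed=7, genotype_ids=pool.ids,
                                      family="dominant_block")
virome  = sample_reads(pool, profile, 12_000, seed=7)
out     = analyze_virome(virome)

h_true = shannon_index(virome.truth_counts())
d = out.diversity
print(f"achieved evenness   : {profile.achieved_evenness:.4f}")
print(f"contigs assembled   : {len(out.assembly.contigs)}")
print(f"genotypes clustered : {out.corrected.n_genotypes}")
print(f"true Shannon H      : {h_true:.4f}")
print(f"HVDI (Shannon form) : {d.H:.4f}")
print(f"relative difference : {100*abs(d.H - h_true)/h_true:.2f} %")
```

prints

```
achieved evenness   : 0.6700
contigs assembled   : 16
genotypes clustered : 83
true Shannon H      : 1.5355
HVDI (Shannon form) : 1.5569
relative difference : 1.40 %
```

The ten dominant genotypes assemble into 16 contigs that clustering reduces
back toward ten; the remaining genotype categories are singleton reads from
the simulated rare background (1 % of the community below assembly depth),
which carry little Shannon weight — the HVDI lands within 1.4 % of the true
Shannon index.  The same rare tail is why the Chao1 form (used for
rarefaction, where penalizing rare contigs is the point) sits far above
`S_obs`.

A command-line interface mirrors the library:

```bash
hvdi simulate --seed 7 --n-genomes 10 --n-reads 12000 --out-dir run/
hvdi qc run/reads.fasta --out run/kept.fasta
hvdi cluster run/kept.fasta --out-dir run/
hvdi diversity run/corrected_spectrum.tsv
hvdi validate-grid --genotype-counts 10,50 --reps 3 --seed 1
```

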