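"""Synthetic toy genomes, annotations and VCFs.

These generators define the test substrate for the whole package: random
uniform-composition chromosomes, multi-exon gene models laid out without
overlap, and biallelic VCF sites consistent with the genome.  They are
deliberately simple — no repeat structure, GC bias or realistic gene
architecture — so every downstream truth value can be recomputed by
hand or by brute force.
"""

from __future__ import annotations

import os

import numpy as np

from truthbench.genome import AnnotationSet, Genome, TranscriptModel, write_fasta, write_gtf

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_genome(chrom_sizes: dict[str, int], rng: np.random.Generator) -> Genome:
    genome = Genome()
    for name, size in chrom_sizes.items():
        idx = rng.integers(0, 4, size=size)
        genome.add(name, _BASES[idx].tobytes().decode("ascii"))
    return genome


def random_annotations(genome: Genome, n_genes: int, rng: np.random.Generator,
                       exons_per_gene: tuple[int, int] = (1, 6),
                       exon_len: tuple[int, int] = (80, 300),
                       intron_len: tuple[int, int] = (60, 1500),
                       intergenic: tuple[int, int] = (100, 500)) -> AnnotationSet:
    """Place ``n_genes`` non-overlapping multi-exon genes round-robin over
    chromosomes; strand alternates.  Each gene gets one transcript."""
    annotations = AnnotationSet()
    chroms = list(genome.chromosomes)
    cursors = {c: int(rng.integers(*intergenic)) for c in chroms}
    placed = 0
    attempts = 0
    while placed < n_genes and attempts < n_genes * 10:
        attempts += 1
        chrom = chroms[placed % len(chroms)]
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exons = []
        pos = cursors[chrom]
        for i in range(n_exons):
            if i > 0:
                pos += int(rng.integers(*intron_len))
            length = int(rng.integers(*exon_len))
            exons.append((pos, pos + length))
            pos += length
        if pos >= genome.length(chrom):
            cursors[chrom] = genome.length(chrom)  # chromosome full
            continue
        strand = "+" if placed % 2 == 0 else "-"
        gid = f"gene_{placed}"
        annotations.add(TranscriptModel(gid, f"{gid}_t1", chrom, strand, exons))
        cursors[chrom] = pos + int(rng.integers(*intergenic))
        placed += 1
    return annotations


def random_vcf_sites(genome: Genome, n_sites: int, rng: np.random.Generator,
                     indel_fraction: float = 0.1, max_indel_len: int = 15,
                     ) -> list[tuple[str, int, str, str]]:
    """Biallelic sites (chrom, 1-based pos, REF, ALT) with REF taken from
    the genome; ``indel_fraction`` of sites are insertions/deletions."""
    bases = "ACGT"
    chroms = list(genome.chromosomes)
    sizes = np.array([genome.length(c) for c in chroms], dtype=float)
    sites: dict[tuple[str, int], tuple[str, int, str, str]] = {}
    while len(sites) < n_sites:
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        seq = genome[chrom]
        pos = int(rng.integers(1, len(seq) - max_indel_len - 1))
        if (chrom, pos) in sites or seq[pos] == "N":
            continue
        if rng.random() < indel_fraction:
            ln = int(rng.integers(1, max_indel_len + 1))
            anchor = seq[pos]
            if rng.random() < 0.5:
                ins = "".join(bases[i] for i in rng.integers(0, 4, size=ln))
                sites[(chrom, pos)] = (chrom, pos + 1, anchor, anchor + ins)
            else:
                sites[(chrom, pos)] = (chrom, pos + 1, seq[pos:pos + 1 + ln], anchor)
        else:
            ref = seq[pos]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            sites[(chrom, pos)] = (chrom, pos + 1, ref, alt)
    return sorted(sites.values(), key=lambda r: (r[0], r[1]))


def write_vcf_sites(sites, genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, n in genome.lengths().items():
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sites:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def make_fixture(outdir: str, chrom_sizes: dict[str, int] | None = None,
                 n_genes: int = 50, n_vcf_sites: int = 500,
                 seed: int = 0) -> dict[str, str]:
    """Write a toy genome.fa / annotations.gtf / sites.vcf trio; returns
    the paths.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    chrom_sizes = chrom_sizes or {"chr1": 100_000, "chr2": 100_000}
    genome = random_genome(chrom_sizes, rng)
    annotations = random_annotations(genome, n_genes, rng)
    sites = random_vcf_sites(genome, n_vcf_sites, rng)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "annotations.gtf"),
        "vcf": os.path.join(outdir, "sites.vcf"),
    }
    write_fasta(genome, paths["genome"])
    write_gtf(annotations, paths["gtf"])
    write_vcf_sites(sites, genome, paths["vcf"])
    return paths
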