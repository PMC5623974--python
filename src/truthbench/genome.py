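"""Reference sequences and transcript annotations.

Coordinate conventions used throughout the package:

* internal coordinates are 0-based half-open on the forward strand;
* GTF/VCF/SAM emission is 1-based inclusive, BED emission is 0-based
  half-open — conversion happens at the I/O boundary only.

Only ``exon`` feature lines are consumed from GTF; other features are
ignored.  Sequences are held uppercase; ``N`` bases are preserved.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pyranges
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file does not satisfy the expected format."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """An ordered collection of chromosomes (name -> uppercase sequence)."""

    def __init__(self, chromosomes: dict[str, str] | None = None):
        self.chromosomes: dict[str, str] = {}
        if chromosomes:
            for name, seq in chromosomes.items():
                self.add(name, seq)

    def add(self, name: str, sequence: str) -> None:
        if name in self.chromosomes:
            raise FormatError(f"duplicate chromosome name: {name!r}")
        self.chromosomes[name] = sequence.upper()

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.chromosomes == other.chromosomes

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, name: str, start: int, end: int) -> str:
        """Return ``chrom[start:end]`` (0-based half-open), bounds-checked."""
        seq = self.chromosomes[name]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(f"interval [{start},{end}) out of bounds for {name} (len {len(seq)})")
        return seq[start:end]


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of genomic exons.

    ``exons`` are 0-based half-open intervals sorted by start, pairwise
    non-overlapping, with at least one intronic base between consecutive
    exons.  ``strand`` is ``'+'`` or ``'-'``; exon order is genomic
    (ascending) regardless of strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_in_transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


class AnnotationSet:
    """Transcript models keyed by transcript id, with a gene index."""

    def __init__(self, transcripts: list[TranscriptModel] | None = None):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[str]] = {}
        for t in transcripts or []:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        self.transcripts[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, [])
        if t.transcript_id not in self.genes[t.gene_id]:
            self.genes[t.gene_id].append(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.genes[gene_id]]

    def n_genes(self) -> int:
        return len(self.genes)


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome` (order preserved)."""
    genome = Genome()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        genome.add(record.id, str(record.seq))
        n += 1
    if n == 0:
        raise FormatError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Genome, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gtf(path: str | os.PathLike) -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`.

    Requires ``gene_id`` and ``transcript_id`` attributes on every exon
    line; other feature types are ignored.
    """
    df = pyranges.read_gtf(str(path), as_df=True)
    if df.empty:
        return AnnotationSet()
    exons = df[df["Feature"] == "exon"]
    for col in ("gene_id", "transcript_id"):
        if col not in exons.columns or exons[col].isna().any() or (exons[col] == "").any():
            raise FormatError(f"GTF exon line lacking {col} attribute in {path}")
    annotations = AnnotationSet()
    for (tid,), grp in exons.groupby(["transcript_id"], sort=False):
        strands = grp["Strand"].unique()
        if len(strands) != 1:
            raise FormatError(f"transcript {tid} has inconsistent strands")
        annotations.add(
            TranscriptModel(
                gene_id=grp["gene_id"].iloc[0],
                transcript_id=tid,
                chrom=grp["Chromosome"].iloc[0],
                strand=strands[0],
                exons=list(zip(grp["Start"], grp["End"])),
            )
        )
    return annotations


def write_gtf(annotations: AnnotationSet, path: str | os.PathLike, source: str = "truthbench") -> None:
    with open(path, "w") as fh:
        fh.write(gtf_lines(annotations, source))


def gtf_lines(annotations: AnnotationSet, source: str = "truthbench") -> str:
    """Render exon lines (1-based inclusive) for every transcript."""
    out = []
    for t in annotations:
        for start, end in t.exons:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            out.append(
                f"{t.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
    return "".join(out)


def transcript_sequence(genome: Genome, transcript: TranscriptModel) -> str:
    """Spliced transcript sequence: exon substrings concatenated in genomic
    order, reverse-complemented for minus-strand transcripts."""
    seq = "".join(genome.fetch(transcript.chrom, s, e) for s, e in transcript.exons)
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq
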