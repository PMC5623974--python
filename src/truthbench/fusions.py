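"""Gene-fusion construction and junction geometry classification.

A fusion joins the upstream part of one gene (through a randomly chosen
exon) to the downstream part of another gene (from a randomly chosen
exon), with the two chosen exons merged into a single exon to force the
chimeric junction.  Each fusion lives on its own contig, written to a
separate FASTA, with a transcript annotation added on the contig.

Junctions are classified purely from geometry, never from provenance:
two loci on different chromosomes, different strands, or out of
transcription order are NONCOLINEAR; same-chromosome same-strand
junctions in transcription order are COLINEAR_FUSION when the skipped
span exceeds ``colinear_threshold`` (default 300 kb) and SPLICE
otherwise — so a sufficiently large intron of an ordinary gene also
counts as a colinear fusion junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from truthbench.genome import AnnotationSet, Genome, TranscriptModel, reverse_complement

DEFAULT_COLINEAR_THRESHOLD = 300_000


class JunctionClass(str, Enum):
    SPLICE = "SPLICE"
    COLINEAR_FUSION = "COLINEAR_FUSION"
    NONCOLINEAR_FUSION = "NONCOLINEAR_FUSION"


def classify_junction(chrom1: str, pos1: int, strand1: str,
                      chrom2: str, pos2: int, strand2: str,
                      colinear_threshold: int = DEFAULT_COLINEAR_THRESHOLD) -> JunctionClass:
    """Classify the junction from the last base of the upstream side
    (``pos1``) to the first base of the downstream side (``pos2``).

    The span compared against the threshold is the number of skipped
    genomic bases between the two sides (an intron's length, for a
    splice junction).
    """
    if chrom1 != chrom2 or strand1 != strand2:
        return JunctionClass.NONCOLINEAR_FUSION
    if strand1 == "+":
        span = pos2 - pos1 - 1
    else:
        span = pos1 - pos2 - 1
    if span < 0:
        return JunctionClass.NONCOLINEAR_FUSION  # reverse transcription order
    if span > colinear_threshold:
        return JunctionClass.COLINEAR_FUSION
    return JunctionClass.SPLICE


@dataclass(frozen=True)
class ContigSegment:
    """One oriented genomic piece of a fusion contig.

    Contig bases ``[contig_start, contig_start + (end - start))`` equal
    ``genome[chrom][start:end]``, reverse-complemented when ``strand``
    is ``'-'``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    contig_start: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FusionEvent:
    """A constructed fusion: contig name, its two oriented genomic
    segments (in the coordinates of the genome the contig was cut from),
    and the junction breakpoints (last upstream base / first downstream
    base, same coordinate system)."""

    contig_name: str
    gene5: str
    gene3: str
    segment5: ContigSegment
    segment3: ContigSegment

    @property
    def breakpoint5(self) -> tuple[str, int, str]:
        s = self.segment5
        pos = s.end - 1 if s.strand == "+" else s.start
        return (s.chrom, pos, s.strand)

    @property
    def breakpoint3(self) -> tuple[str, int, str]:
        s = self.segment3
        pos = s.start if s.strand == "+" else s.end - 1
        return (s.chrom, pos, s.strand)


class FusionRegistry:
    """Contig name -> FusionEvent lookup used by alignment liftover."""

    def __init__(self, events: list[FusionEvent] | None = None):
        self._by_name = {e.contig_name: e for e in (events or [])}

    def __contains__(self, contig: str) -> bool:
        return contig in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(self._by_name.values())

    def get(self, contig: str) -> FusionEvent:
        if contig not in self._by_name:
            raise KeyError(f"unknown fusion contig {contig!r}")
        return self._by_name[contig]


def _representative_transcript(annotations: AnnotationSet, gene_id: str) -> TranscriptModel:
    """The longest transcript (summed exon length) represents its gene."""
    return max(annotations.gene_transcripts(gene_id), key=lambda t: (t.length, t.transcript_id))


def _oriented_region(genome: Genome, chrom: str, start: int, end: int, strand: str) -> str:
    seq = genome.fetch(chrom, start, end)
    return reverse_complement(seq) if strand == "-" else seq


def generate_fusions(annotations: AnnotationSet, genome: Genome, n_fusions: int,
                     rng: np.random.Generator,
                     ) -> tuple[list[FusionEvent], Genome, AnnotationSet, FusionRegistry]:
    """Create ``n_fusions`` fusion contigs by random exon pairing.

    Two exons are drawn uniformly from the representative transcripts of
    the annotation (resampled until the parent genes differ).  The contig
    is the genomic upstream part of gene A — transcript 5' end through the
    chosen exon, in transcription orientation — concatenated with the
    genomic downstream part of gene B.  The two chosen exons become one
    merged exon in the contig annotation (all contig transcripts are on
    '+').

    Returns (events, contig genome, contig annotations, registry).
    """
    if n_fusions < 0:
        raise ValueError("n_fusions must be >= 0")
    contigs = Genome()
    fusion_annotations = AnnotationSet()
    events: list[FusionEvent] = []
    if n_fusions == 0:
        return events, contigs, fusion_annotations, FusionRegistry([])
    if annotations.n_genes() < 2:
        raise ValueError("need at least 2 genes to build fusions")

    reps = [_representative_transcript(annotations, g) for g in annotations.genes]
    exon_pool = [(ti, ei) for ti, t in enumerate(reps) for ei in range(len(t.exons))]

    for k in range(n_fusions):
        while True:
            ia, ib = rng.integers(0, len(exon_pool), size=2)
            (t5_i, e5_i), (t3_i, e3_i) = exon_pool[int(ia)], exon_pool[int(ib)]
            if reps[t5_i].gene_id != reps[t3_i].gene_id:
                break
        t5, t3 = reps[t5_i], reps[t3_i]
        name = f"fusion_{k}"

        # upstream part: transcript 5' end through the chosen exon (genomic cut)
        ex5 = t5.exons_in_transcription_order()[e5_i]
        if t5.strand == "+":
            up = ContigSegment(t5.chrom, t5.start, ex5[1], "+", 0)
        else:
            up = ContigSegment(t5.chrom, ex5[0], t5.end, "-", 0)
        # downstream part: chosen exon through transcript 3' end
        ex3 = t3.exons_in_transcription_order()[e3_i]
        if t3.strand == "+":
            down = ContigSegment(t3.chrom, ex3[0], t3.end, "+", up.length)
        else:
            down = ContigSegment(t3.chrom, t3.start, ex3[1], "-", up.length)

        seq = (_oriented_region(genome, up.chrom, up.start, up.end, up.strand)
               + _oriented_region(genome, down.chrom, down.start, down.end, down.strand))
        contigs.add(name, seq)

        def to_contig(seg: ContigSegment, gs: int, ge: int) -> tuple[int, int]:
            if seg.strand == "+":
                return (seg.contig_start + gs - seg.start, seg.contig_start + ge - seg.start)
            return (seg.contig_start + seg.end - ge, seg.contig_start + seg.end - gs)

        up_exons = [to_contig(up, max(s, up.start), min(e, up.end))
                    for s, e in t5.exons_in_transcription_order()[:e5_i + 1]]
        down_exons = [to_contig(down, max(s, down.start), min(e, down.end))
                      for s, e in t3.exons_in_transcription_order()[e3_i:]]
        # merge the fused exon pair (they are adjacent at the breakpoint)
        merged = (up_exons[-1][0], down_exons[0][1])
        exons = up_exons[:-1] + [merged] + down_exons[1:]
        fusion_annotations.add(TranscriptModel(
            gene_id=name, transcript_id=f"{name}_t1", chrom=name, strand="+", exons=exons,
        ))
        events.append(FusionEvent(name, t5.gene_id, t3.gene_id, up, down))
    return events, contigs, fusion_annotations, FusionRegistry(events)


def write_fusions_tsv(rows, path: str) -> None:
    """Fusion junction TSV: chrom1, 1-based pos1, strand1, chrom2,
    1-based pos2, strand2, class [, support]."""
    with open(path, "w") as fh:
        fh.write("#chrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\tclass\tsupport\n")
        for (c1, p1, s1, c2, p2, s2, cls), support in rows:
            fh.write(f"{c1}\t{p1 + 1}\t{s1}\t{c2}\t{p2 + 1}\t{s2}\t{cls}\t{support}\n")


def read_fusions_tsv(path: str) -> list[tuple[str, int, str, str, int, str]]:
    """Read fusion predictions/truth (class and support columns optional)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]) - 1, f[2], f[3], int(f[4]) - 1, f[5]))
    return out
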