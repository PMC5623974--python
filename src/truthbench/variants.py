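"""SNV/indel generation, overlap resolution, genome mutation and liftover.

Random mutations are drawn per non-N base as independent Bernoulli trials
at the configured rate (counts are therefore binomial); indel lengths are
uniform on ``1..max_indel_len``.  Mutations may alternatively be taken
from a VCF of biallelic sites, with ``vcf_ratio`` controlling the fraction
of the final set that is VCF-sourced.  Overlap between mutation footprints
is forbidden: the earliest-generated mutation wins.

Applying a mutation set to the genome produces a haploid mutated genome
and a :class:`CoordinateMap` — a piecewise segment map that converts
positions between the mutated and original references exactly (insertions
excepted, which have no original image and lift to their anchor base).
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from truthbench.genome import AnnotationSet, Genome, TranscriptModel

logger = logging.getLogger(__name__)

SNV = "SNV"
INS = "INS"
DEL = "DEL"

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class Mutation:
    """A single variant in original-genome coordinates (0-based).

    ``pos`` is the mutated base for SNVs, the first deleted base for
    deletions, and the anchor base for insertions (the insertion sits
    between ``pos`` and ``pos + 1``).  ``ref`` is empty for insertions and
    ``alt`` empty for deletions.
    """

    kind: str
    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = "random"

    def __post_init__(self):
        if self.kind == SNV and not (len(self.ref) == 1 == len(self.alt) and self.ref != self.alt):
            raise ValueError(f"invalid SNV {self}")
        if self.kind == INS and (self.ref or not self.alt):
            raise ValueError(f"invalid insertion {self}")
        if self.kind == DEL and (self.alt or not self.ref):
            raise ValueError(f"invalid deletion {self}")

    def footprint(self) -> tuple[int, int]:
        """Half-open interval of original-genome bases this mutation owns."""
        if self.kind == DEL:
            return (self.pos, self.pos + len(self.ref))
        return (self.pos, self.pos + 1)


class MutationSet:
    """Per-chromosome, position-sorted, overlap-free mutations."""

    def __init__(self, by_chrom: dict[str, list[Mutation]]):
        self.by_chrom = {c: sorted(ms, key=lambda m: m.pos) for c, ms in by_chrom.items()}

    def __iter__(self):
        for chrom in self.by_chrom:
            yield from self.by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())

    def for_chrom(self, chrom: str) -> list[Mutation]:
        return self.by_chrom.get(chrom, [])


def _random_positions(n_bases: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or n_bases == 0:
        return np.empty(0, dtype=np.int64)
    return np.nonzero(rng.random(n_bases) < rate)[0]


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def generate_random_snvs(genome: Genome, rate_per_base: float,
                         rng: np.random.Generator) -> list[Mutation]:
    """Bernoulli-select each non-N base at ``rate_per_base``; the alternate
    base is uniform over the three bases differing from the reference."""
    if not 0 <= rate_per_base <= 1:
        raise ValueError("rate must be in [0, 1]")
    out: list[Mutation] = []
    for chrom, seq in genome.chromosomes.items():
        pos = _random_positions(len(seq), rate_per_base, rng)
        if pos.size == 0:
            continue
        arr = _seq_array(seq)[pos]
        valid = arr != b"N"
        pos, arr = pos[valid], arr[valid]
        # alt = ref shifted by 1..3 in base order, never equal to ref
        ref_idx = np.searchsorted(np.frombuffer(_BASES.encode(), dtype="S1"), arr)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        for p, r, a in zip(pos.tolist(), arr, alt_idx):
            out.append(Mutation(SNV, chrom, p, r.decode(), _BASES[a]))
    return out


def generate_random_indels(genome: Genome, rate_per_base: float,
                           rng: np.random.Generator, max_indel_len: int = 15,
                           kind: str = INS) -> list[Mutation]:
    """Generate insertions or deletions (``kind``) at ``rate_per_base``.

    Lengths are uniform on ``{1..max_indel_len}``; inserted bases uniform
    over ACGT.  N anchor/start bases are skipped.  A deletion that would
    run past the chromosome end has its length resampled uniformly from
    the lengths that fit.
    """
    if max_indel_len < 1:
        raise ValueError("max_indel_len must be >= 1")
    if kind not in (INS, DEL):
        raise ValueError(f"kind must be {INS} or {DEL}")
    out: list[Mutation] = []
    for chrom, seq in genome.chromosomes.items():
        pos = _random_positions(len(seq), rate_per_base, rng)
        lengths = rng.integers(1, max_indel_len + 1, size=pos.size)
        for p, ln in zip(pos.tolist(), lengths.tolist()):
            if seq[p] == "N":
                continue
            if kind == INS:
                bases = "".join(_BASES[i] for i in rng.integers(0, 4, size=ln))
                out.append(Mutation(INS, chrom, p, "", bases))
            else:
                if p + ln > len(seq):  # resample among lengths that fit
                    ln = int(rng.integers(1, len(seq) - p + 1))
                out.append(Mutation(DEL, chrom, p, seq[p:p + ln], ""))
    return out


def load_vcf_mutations(path: str, genome: Genome | None = None) -> tuple[list[Mutation], int]:
    """Load biallelic SNV/indel records from a VCF.

    Multi-allelic records and records whose REF disagrees with ``genome``
    (when provided) are skipped; the skip count is returned alongside the
    mutations.  Insertions/deletions follow the VCF anchor-base
    convention (POS is the base before the event).
    """
    skipped = 0
    out: list[Mutation] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            pos0 = rec.pos - 1
            if genome is not None:
                if rec.chrom not in genome or genome.fetch(rec.chrom, pos0, pos0 + len(ref)) != ref:
                    warnings.warn(f"VCF REF mismatch at {rec.chrom}:{rec.pos}; record skipped")
                    skipped += 1
                    continue
            if len(ref) == 1 and len(alt) == 1:
                out.append(Mutation(SNV, rec.chrom, pos0, ref, alt, source="vcf"))
            elif len(ref) == 1 and len(alt) > 1 and alt.startswith(ref):
                out.append(Mutation(INS, rec.chrom, pos0, "", alt[1:], source="vcf"))
            elif len(alt) == 1 and len(ref) > 1 and ref.startswith(alt):
                out.append(Mutation(DEL, rec.chrom, pos0 + 1, ref[1:], "", source="vcf"))
            else:
                skipped += 1  # complex/MNV records unsupported
    if skipped:
        logger.info("load_vcf_mutations: skipped %d unsupported/mismatching records", skipped)
    return out, skipped


def mix_sources(vcf_mutations: list[Mutation], genome: Genome, total_target: int,
                vcf_ratio: float, rng: np.random.Generator,
                kind_weights: tuple[float, float, float] = (0.0014, 0.0001, 0.0001),
                max_indel_len: int = 15) -> list[Mutation]:
    """Assemble ``total_target`` mutations, ``round(vcf_ratio * total)`` of
    them sampled without replacement from the VCF list and the remainder
    generated randomly (kinds drawn proportionally to ``kind_weights`` =
    (SNV, INS, DEL) rates, positions uniform over non-N bases).

    A VCF shortfall is filled randomly with a warning.
    """
    if not 0 <= vcf_ratio <= 1:
        raise ValueError("vcf_ratio must be in [0, 1]")
    n_vcf = round(vcf_ratio * total_target)
    if n_vcf > len(vcf_mutations):
        warnings.warn(
            f"VCF provides {len(vcf_mutations)} mutations, {n_vcf} requested; "
            "shortfall generated randomly"
        )
        n_vcf = len(vcf_mutations)
    chosen_idx = rng.choice(len(vcf_mutations), size=n_vcf, replace=False) if n_vcf else []
    chosen = [vcf_mutations[i] for i in sorted(chosen_idx)]

    n_random = total_target - n_vcf
    weights = np.asarray(kind_weights, dtype=float)
    weights /= weights.sum()
    chroms = list(genome.chromosomes)
    sizes = np.array([genome.length(c) for c in chroms], dtype=float)
    randoms: list[Mutation] = []
    while len(randoms) < n_random:
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[ci]
        seq = genome[chrom]
        p = int(rng.integers(0, len(seq)))
        if seq[p] == "N":
            continue
        kind = (SNV, INS, DEL)[int(rng.choice(3, p=weights))]
        if kind == SNV:
            alt = _BASES[(_BASE_INDEX[seq[p]] + int(rng.integers(1, 4))) % 4]
            randoms.append(Mutation(SNV, chrom, p, seq[p], alt))
        elif kind == INS:
            ln = int(rng.integers(1, max_indel_len + 1))
            bases = "".join(_BASES[i] for i in rng.integers(0, 4, size=ln))
            randoms.append(Mutation(INS, chrom, p, "", bases))
        else:
            ln = int(rng.integers(1, min(max_indel_len, len(seq) - p) + 1))
            randoms.append(Mutation(DEL, chrom, p, seq[p:p + ln], ""))
    return chosen + randoms


def resolve_overlaps(mutations: list[Mutation]) -> MutationSet:
    """Drop every mutation whose footprint intersects an earlier-kept one
    (keep-first in generation order), and sort by position."""
    occupied: dict[str, set[int]] = {}
    kept: dict[str, list[Mutation]] = {}
    for m in mutations:
        occ = occupied.setdefault(m.chrom, set())
        s, e = m.footprint()
        span = range(s, e)
        if any(p in occ for p in span):
            continue
        occ.update(span)
        kept.setdefault(m.chrom, []).append(m)
    return MutationSet(kept)


@dataclass
class _Segment:
    """One piece of the mutated genome: either a faithful copy of an
    original-genome run, or inserted bases with no original image."""

    mut_start: int
    mut_end: int
    orig_start: int   # for insertions: position just after the anchor base
    insertion: bool = False

    @property
    def anchor(self) -> int:
        return self.orig_start - 1


class _ChromMap:
    def __init__(self, segments: list[_Segment], mut_length: int, orig_length: int):
        self.segments = segments
        self.mut_length = mut_length
        self.orig_length = orig_length
        self._mut_starts = [s.mut_start for s in segments]
        self._match = [s for s in segments if not s.insertion]
        self._orig_starts = [s.orig_start for s in self._match]

    def lift(self, mut_pos: int) -> tuple[int, bool]:
        if not 0 <= mut_pos < self.mut_length:
            raise IndexError(f"mutated position {mut_pos} out of range")
        seg = self.segments[bisect_right(self._mut_starts, mut_pos) - 1]
        if seg.insertion:
            return seg.anchor, True
        return seg.orig_start + (mut_pos - seg.mut_start), False

    def forward(self, orig_pos: int) -> int:
        """Original -> mutated; positions inside a deletion snap to the
        first surviving base after it."""
        if not 0 <= orig_pos < self.orig_length:
            raise IndexError(f"original position {orig_pos} out of range")
        i = bisect_right(self._orig_starts, orig_pos) - 1
        if i >= 0:
            seg = self._match[i]
            off = orig_pos - seg.orig_start
            if off < seg.mut_end - seg.mut_start:
                return seg.mut_start + off
            i += 1
        else:
            i = 0
        if i < len(self._match):
            return self._match[i].mut_start
        return self.mut_length  # deleted tail

    def pieces(self, mut_start: int, mut_end: int):
        """Decompose a mutated-coordinate interval into map pieces.

        Yields ``(length, orig_start, anchor)`` tuples in order:
        ``orig_start`` is the original coordinate of the piece's first
        base for faithful copies (``anchor`` None), or None for inserted
        runs (``anchor`` = the insertion's anchor base).
        """
        if not 0 <= mut_start <= mut_end <= self.mut_length:
            raise IndexError(f"interval [{mut_start},{mut_end}) out of mutated range")
        i = bisect_right(self._mut_starts, mut_start) - 1
        pos = mut_start
        while pos < mut_end:
            seg = self.segments[i]
            take = min(mut_end, seg.mut_end) - pos
            if seg.insertion:
                yield (take, None, seg.anchor)
            else:
                yield (take, seg.orig_start + (pos - seg.mut_start), None)
            pos += take
            i += 1

    def image_of_interval(self, orig_start: int, orig_end: int) -> tuple[int, int] | None:
        """Mutated-coordinate span covering the surviving image of an
        original interval (insertions in the interior included); None if
        every base of the interval was deleted."""
        lo = None
        hi = None
        for seg in self._match:
            s = max(orig_start, seg.orig_start)
            e = min(orig_end, seg.orig_start + (seg.mut_end - seg.mut_start))
            if s < e:
                ms = seg.mut_start + (s - seg.orig_start)
                me = seg.mut_start + (e - seg.orig_start)
                lo = ms if lo is None else min(lo, ms)
                hi = me if hi is None else max(hi, me)
        if lo is None:
            return None
        return lo, hi


class CoordinateMap:
    """Piecewise bijection (insertions aside) between mutated and original
    coordinates, one segment list per chromosome."""

    def __init__(self):
        self._chroms: dict[str, _ChromMap] = {}

    @classmethod
    def identity(cls, genome: Genome) -> "CoordinateMap":
        cmap = cls()
        for chrom, seq in genome.chromosomes.items():
            n = len(seq)
            cmap._chroms[chrom] = _ChromMap([_Segment(0, n, 0)], n, n)
        return cmap

    def add_chrom(self, chrom: str, segments: list[_Segment], mut_length: int, orig_length: int) -> None:
        self._chroms[chrom] = _ChromMap(segments, mut_length, orig_length)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def chrom_map(self, chrom: str) -> _ChromMap:
        if chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._chroms[chrom]

    def segments(self, chrom: str) -> list[_Segment]:
        return self.chrom_map(chrom).segments

    def lift_position(self, chrom: str, mut_pos: int) -> tuple[str, int, bool]:
        """Mutated -> original position.  Inside inserted bases the flag is
        set and the insertion's anchor base is returned."""
        pos, inside = self.chrom_map(chrom).lift(mut_pos)
        return chrom, pos, inside

    def forward_position(self, chrom: str, orig_pos: int) -> int:
        return self.chrom_map(chrom).forward(orig_pos)


def lift_position(cmap: CoordinateMap, chrom: str, mut_pos: int) -> tuple[str, int, bool]:
    return cmap.lift_position(chrom, mut_pos)


class ConsistencyError(ValueError):
    pass


def apply_mutations(genome: Genome, mutation_set: MutationSet) -> tuple[Genome, CoordinateMap]:
    """Build the haploid mutated genome and its coordinate map.

    SNVs substitute in place (no coordinate change); insertions splice
    ``alt`` in after their anchor; deletions excise ``ref``.  REF alleles
    are validated against the genome.
    """
    mutated = Genome()
    cmap = CoordinateMap()
    for chrom, seq in genome.chromosomes.items():
        muts = mutation_set.for_chrom(chrom)
        for m in muts:
            if m.kind in (SNV, DEL):
                actual = seq[m.pos:m.pos + len(m.ref)]
                if actual != m.ref:
                    raise ConsistencyError(
                        f"ref mismatch at {chrom}:{m.pos + 1}: expected {m.ref!r}, genome has {actual!r}"
                    )
        # SNVs first: in-place substitutions, map-neutral
        arr = list(seq)
        for m in muts:
            if m.kind == SNV:
                arr[m.pos] = m.alt
        base = "".join(arr)

        parts: list[str] = []
        segments: list[_Segment] = []
        cur_orig = 0
        cur_mut = 0
        for m in muts:
            if m.kind == SNV:
                continue
            if m.kind == INS:
                keep_end = m.pos + 1  # anchor base stays with the upstream segment
                if keep_end > cur_orig:
                    parts.append(base[cur_orig:keep_end])
                    segments.append(_Segment(cur_mut, cur_mut + keep_end - cur_orig, cur_orig))
                    cur_mut += keep_end - cur_orig
                    cur_orig = keep_end
                parts.append(m.alt)
                segments.append(_Segment(cur_mut, cur_mut + len(m.alt), cur_orig, insertion=True))
                cur_mut += len(m.alt)
            else:  # DEL
                if m.pos > cur_orig:
                    parts.append(base[cur_orig:m.pos])
                    segments.append(_Segment(cur_mut, cur_mut + m.pos - cur_orig, cur_orig))
                    cur_mut += m.pos - cur_orig
                cur_orig = m.pos + len(m.ref)
        if cur_orig < len(base):
            parts.append(base[cur_orig:])
            segments.append(_Segment(cur_mut, cur_mut + len(base) - cur_orig, cur_orig))
            cur_mut += len(base) - cur_orig
        mutated.add(chrom, "".join(parts))
        cmap.add_chrom(chrom, segments, cur_mut, len(seq))
    return mutated, cmap


def shift_annotations(annotations: AnnotationSet, cmap: CoordinateMap) -> AnnotationSet:
    """Map every exon boundary original -> mutated coordinates.

    An exon keeps the full mutated span of its surviving image (interior
    insertions included); exons whose bases were all deleted are dropped,
    and exons left touching after an intron deletion are merged.
    """
    shifted = AnnotationSet()
    for t in annotations:
        cm = cmap.chrom_map(t.chrom)
        exons: list[tuple[int, int]] = []
        for s, e in t.exons:
            img = cm.image_of_interval(s, e)
            if img is None:
                logger.info("exon %s:%d-%d of %s fully deleted; dropped", t.chrom, s, e, t.transcript_id)
                continue
            exons.append(img)
        merged: list[tuple[int, int]] = []
        for s, e in sorted(exons):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        if merged:
            shifted.add(replace(t, exons=merged))
        else:
            logger.warning("transcript %s lost all exons after mutation; dropped", t.transcript_id)
    return shifted


def write_mutations_tsv(mutations, path: str, support: dict | None = None) -> None:
    """Truth mutations TSV: chrom, 1-based pos, kind, ref, alt, source
    [, support].  For insertions pos is the anchor base."""
    with open(path, "w") as fh:
        cols = ["chrom", "pos", "kind", "ref", "alt", "source"]
        if support is not None:
            cols.append("support")
        fh.write("#" + "\t".join(cols) + "\n")
        for m in mutations:
            row = [m.chrom, str(m.pos + 1), m.kind, m.ref or ".", m.alt or ".", m.source]
            if support is not None:
                row.append(str(support.get((m.chrom, m.pos, m.kind), 0)))
            fh.write("\t".join(row) + "\n")


def read_mutations_tsv(path: str) -> list[Mutation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos, kind, ref, alt = line.rstrip("\n").split("\t")[:5]
            source = line.rstrip("\n").split("\t")[5] if len(line.split("\t")) > 5 else "random"
            out.append(Mutation(kind, chrom, int(pos) - 1,
                                "" if ref == "." else ref,
                                "" if alt == "." else alt, source))
    return out


def write_mutations_vcf(mutations, genome: Genome, path: str) -> None:
    """Truth mutations as a minimal VCF 4.2 (anchor-base convention)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SOURCE,Number=1,Type=String,Description="Mutation source (random or vcf)">\n')
        for chrom, n in genome.lengths().items():
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in sorted(mutations, key=lambda m: (m.chrom, m.pos)):
            if m.kind == SNV:
                pos, ref, alt = m.pos + 1, m.ref, m.alt
            elif m.kind == INS:
                anchor = genome.fetch(m.chrom, m.pos, m.pos + 1)
                pos, ref, alt = m.pos + 1, anchor, anchor + m.alt
            else:
                if m.pos == 0:  # no left anchor base; use the base after
                    anchor = genome.fetch(m.chrom, m.pos + len(m.ref), m.pos + len(m.ref) + 1)
                    pos, ref, alt = 1, m.ref + anchor, anchor
                else:
                    anchor = genome.fetch(m.chrom, m.pos - 1, m.pos)
                    pos, ref, alt = m.pos, anchor + m.ref, anchor
            fh.write(f"{m.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tSOURCE={m.source}\n")
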