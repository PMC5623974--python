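"""Truth encoding: liftover of simulated alignments, read-name codec,
truth database construction and dataset output.

Every simulated read pair carries its true alignments in the read name::

    read_id:(chr,(-)pos,cigar(;)?)+:base64(err_pos?)

i.e. a numeric read id (0..n_pairs-1), a ';'-joined list of SAM-like
alignment records (1-based start, negated for the reverse strand, CIGAR
over M/I/D/N/S), and the 0-based sequencing-error offsets over the
concatenated pair (end 1 then end 2) as comma-joined decimals in
standard base64 with padding stripped.  Both mates share one name:
alignments are concatenated (end 1's records first) and error positions
merged.

Alignments are expressed in *original*-reference coordinates: liftover
through the coordinate map turns bases simulated over an insertion into
I ops, spanned deletions into D ops and introns into N ops; reads
simulated from a fusion contig are split at the registered breakpoint
into two records, each soft-clipping (S) the non-local portion, as in
chimeric SAM conventions.
"""

from __future__ import annotations

import base64
import binascii
import json
import os
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from truthbench.fusions import (
    DEFAULT_COLINEAR_THRESHOLD,
    FusionRegistry,
    JunctionClass,
    classify_junction,
    read_fusions_tsv,
    write_fusions_tsv,
)
from truthbench.genome import Genome
from truthbench.variants import (
    CoordinateMap,
    Mutation,
    MutationSet,
    read_mutations_tsv,
    write_mutations_tsv,
    write_mutations_vcf,
)

_CIGAR_RE = re.compile(r"(\d+)([MIDNS])")
_NAME_RE = re.compile(r"^(\d+):(.*):([A-Za-z0-9+/]*)$")

FASTQ_QUALITY = "I"


class ReadNameError(ValueError):
    pass


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """One truth alignment: chromosome, 0-based leftmost aligned base,
    strand, CIGAR in genomic left-to-right order."""

    chrom: str
    pos: int
    strand: str
    cigar: str

    def cigar_ops(self) -> list[tuple[str, int]]:
        ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(self.cigar)]
        if "".join(f"{n}{op}" for op, n in ops) != self.cigar:
            raise ReadNameError(f"malformed CIGAR {self.cigar!r}")
        return ops

    @property
    def ref_length(self) -> int:
        return sum(n for op, n in self.cigar_ops() if op in "MDN")

    @property
    def ref_end(self) -> int:
        return self.pos + self.ref_length

    @property
    def local_query_length(self) -> int:
        """Read bases this record aligns locally (M + I, excluding S)."""
        return sum(n for op, n in self.cigar_ops() if op in "MI")

    def aligned_ref_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals covered by M or D ops (N gaps excluded)."""
        out = []
        pos = self.pos
        cur = None
        for op, n in self.cigar_ops():
            if op in "MD":
                if cur is None:
                    cur = [pos, pos + n]
                else:
                    cur[1] = pos + n
                pos += n
            elif op == "N":
                if cur is not None:
                    out.append(tuple(cur))
                    cur = None
                pos += n
        if cur is not None:
            out.append(tuple(cur))
        return out

    def insertion_anchors(self) -> list[tuple[int, int]]:
        """(anchor base, length) per I op: the inserted run sits between
        ``anchor`` and ``anchor + 1`` in reference coordinates."""
        out = []
        pos = self.pos
        for op, n in self.cigar_ops():
            if op == "I":
                out.append((pos - 1, n))
            elif op in "MDN":
                pos += n
        return out

    def introns(self) -> list[tuple[int, int]]:
        """Half-open reference intervals of N ops."""
        out = []
        pos = self.pos
        for op, n in self.cigar_ops():
            if op == "N":
                out.append((pos, pos + n))
            if op in "MDN":
                pos += n
        return out


@dataclass
class EncodedReadName:
    read_id: int
    alignments: list[ReadAlignmentRecord]
    err_pos: list[int] = field(default_factory=list)


def encode_read_name(read_id: int, alignments: list[ReadAlignmentRecord],
                     err_pos: list[int]) -> str:
    if read_id < 0:
        raise ValueError("read_id must be >= 0")
    aligns = ";".join(
        f"{r.chrom},{'-' if r.strand == '-' else ''}{r.pos + 1},{r.cigar}"
        for r in alignments
    )
    if err_pos:
        payload = ",".join(str(p) for p in err_pos).encode("ascii")
        b64 = base64.b64encode(payload).decode("ascii").rstrip("=")
    else:
        b64 = ""
    return f"{read_id}:{aligns}:{b64}"


def decode_read_name(name: str) -> EncodedReadName:
    m = _NAME_RE.match(name)
    if not m:
        raise ReadNameError(f"unparseable read name {name!r}")
    read_id = int(m.group(1))
    alignments = []
    aligns_field = m.group(2)
    if aligns_field:
        for part in aligns_field.split(";"):
            fields = part.split(",")
            if len(fields) != 3:
                raise ReadNameError(f"malformed alignment component {part!r} in {name!r}")
            chrom, pos_s, cigar = fields
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ReadNameError(f"bad position in {part!r}") from exc
            strand = "-" if pos < 0 else "+"
            rec = ReadAlignmentRecord(chrom, abs(pos) - 1, strand, cigar)
            rec.cigar_ops()  # validate
            alignments.append(rec)
    err_pos: list[int] = []
    if m.group(3):
        padded = m.group(3) + "=" * (-len(m.group(3)) % 4)
        try:
            payload = base64.b64decode(padded).decode("ascii")
            err_pos = [int(p) for p in payload.split(",")]
        except (binascii.Error, UnicodeDecodeError, ValueError) as exc:
            raise ReadNameError(f"bad error-position field in {name!r}") from exc
    return EncodedReadName(read_id, alignments, err_pos)


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[list] = []
    for op, n in ops:
        if n <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1][1] += n
        else:
            merged.append([op, n])
    return [(op, n) for op, n in merged]


def _ops_to_cigar(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _build_record(chrom: str, blocks: list[tuple[int, int]], strand: str,
                  q0: int, q1: int, read_length: int,
                  cmap: CoordinateMap) -> ReadAlignmentRecord:
    """Lift genomic blocks (ascending, mutated coordinates) on an ordinary
    chromosome into one original-coordinate record covering read bases
    [q0, q1); the remainder is soft-clipped."""
    cm = cmap.chrom_map(chrom)
    ops: list[tuple[str, int]] = []
    start = None
    anchor_fallback = None
    ref_pos = None
    for bi, (bs, be) in enumerate(blocks):
        pending_intron = bi > 0
        for ln, ostart, anchor in cm.pieces(bs, be):
            if ostart is None:
                if anchor_fallback is None:
                    anchor_fallback = anchor
                ops.append(("I", ln))
                continue
            if start is None:
                start = ostart
            if ref_pos is not None and ostart > ref_pos:
                ops.append(("N" if pending_intron else "D", ostart - ref_pos))
            pending_intron = False
            ops.append(("M", ln))
            ref_pos = ostart + ln
    if start is None:  # record entirely inside inserted bases
        start = (anchor_fallback if anchor_fallback is not None else 0) + 1
    lead = q0 if strand == "+" else read_length - q1
    trail = read_length - q1 if strand == "+" else q0
    full = [("S", lead)] + ops + [("S", trail)]
    return ReadAlignmentRecord(chrom, start, strand, _ops_to_cigar(_merge_ops(full)))


def lift_alignment(chrom: str, blocks: list[tuple[str, int, int]] | list[tuple[int, int]],
                   strand: str, read_length: int, cmap: CoordinateMap,
                   registry: FusionRegistry | None = None) -> list[ReadAlignmentRecord]:
    """Lift one read end's exonic blocks to original-reference records.

    ``blocks`` are ascending half-open intervals on ``chrom`` (a mutated
    chromosome or a registered fusion contig); ``strand`` is the end's
    alignment strand on that sequence.  Fusion-contig ends are split at
    the breakpoint into one record per genomic locus, in read order, with
    the non-local portion soft-clipped.
    """
    ivals = [(b[-2], b[-1]) for b in blocks]
    if registry is None or chrom not in registry:
        if chrom not in cmap:
            raise KeyError(f"block on unknown contig {chrom!r}")
        return [_build_record(chrom, ivals, strand, 0, read_length, read_length, cmap)]

    ev = registry.get(chrom)
    cut = ev.segment5.length
    split: list[tuple[int, int]] = []
    for s, e in ivals:
        if s < cut < e:
            split += [(s, cut), (cut, e)]
        else:
            split.append((s, e))
    ordered = split if strand == "+" else split[::-1]
    groups: list[tuple[object, list[tuple[int, int, int, int]]]] = []
    q = 0
    for s, e in ordered:
        seg = ev.segment5 if s < cut else ev.segment3
        if not groups or groups[-1][0] is not seg:
            groups.append((seg, []))
        groups[-1][1].append((s, e, q, q + (e - s)))
        q += e - s
    records = []
    for seg, items in groups:
        q0 = min(i[2] for i in items)
        q1 = max(i[3] for i in items)
        gblocks = []
        for s, e, _, _ in items:
            cs, ce = s - seg.contig_start, e - seg.contig_start
            if seg.strand == "+":
                gblocks.append((seg.start + cs, seg.start + ce))
            else:
                gblocks.append((seg.end - ce, seg.end - cs))
        gblocks.sort()
        rstrand = strand if seg.strand == "+" else _flip(strand)
        records.append(_build_record(seg.chrom, gblocks, rstrand, q0, q1, read_length, cmap))
    return records


def lift_pair(pair, cmap: CoordinateMap, registry: FusionRegistry | None,
              read_length: int) -> tuple[list[ReadAlignmentRecord], list[ReadAlignmentRecord]]:
    """Lift both ends of a :class:`SimulatedReadPair`."""
    chrom1 = pair.blocks1[0][0]
    chrom2 = pair.blocks2[0][0]
    end1 = lift_alignment(chrom1, pair.blocks1, pair.strand1, read_length, cmap, registry)
    end2 = lift_alignment(chrom2, pair.blocks2, pair.strand2, read_length, cmap, registry)
    return end1, end2


def pair_read_name(pair, end1: list[ReadAlignmentRecord],
                   end2: list[ReadAlignmentRecord], read_length: int) -> str:
    err = sorted(pair.errors1) + [read_length + p for p in sorted(pair.errors2)]
    return encode_read_name(pair.read_id, end1 + end2, err)


class TruthDB:
    """Read-supported mutations, splice junctions and fusion junctions.

    ``splices`` maps (chrom, intron_start, intron_end, strand) — 0-based
    half-open intron — to its read support; ``fusions`` maps
    (chrom1, pos1, strand1, chrom2, pos2, strand2, class) to support;
    ``mutations`` holds (Mutation, support) pairs.
    """

    def __init__(self):
        self.mutations: list[tuple[Mutation, int]] = []
        self.splices: dict[tuple[str, int, int, str], int] = {}
        self.fusions: dict[tuple[str, int, str, str, int, str, str], int] = {}

    def counts(self) -> dict[str, int]:
        kinds = {"SNV": 0, "INS": 0, "DEL": 0}
        for m, _ in self.mutations:
            kinds[m.kind] += 1
        colinear = sum(1 for k in self.fusions if k[6] == JunctionClass.COLINEAR_FUSION.value)
        return {
            "snv": kinds["SNV"], "insertion": kinds["INS"], "deletion": kinds["DEL"],
            "splice": len(self.splices),
            "colinear_fusion": colinear,
            "noncolinear_fusion": len(self.fusions) - colinear,
        }


def _effective_records(records: list[ReadAlignmentRecord], end_index: int,
                       ) -> list[tuple[ReadAlignmentRecord, str]]:
    """Records of one end in transcription order with transcription-strand
    annotation (end 2 is sequenced antisense to its transcript)."""
    if end_index == 0:
        return [(r, r.strand) for r in records]
    return [(r, _flip(r.strand)) for r in reversed(records)]


def build_truth_db(pairs_with_records, mutation_set: MutationSet,
                   colinear_threshold: int = DEFAULT_COLINEAR_THRESHOLD) -> TruthDB:
    """Scan lifted reads and collect every truth event supported by at
    least one read.

    ``pairs_with_records`` yields ``(pair, end1_records, end2_records)``.
    A SNV or deletion is supported when a read's lifted footprint (M/D
    reference span) covers its position; an insertion when a read carries
    an I op at its anchor (coverage of the anchor base alone does not
    express the inserted sequence).  Each N op contributes its intron
    (reported as a colinear fusion when longer than the threshold);
    consecutive records of one end contribute a junction classified from
    geometry.
    """
    db = TruthDB()
    sub_positions: dict[str, list[int]] = {}
    sub_entries: dict[str, list[Mutation]] = {}
    ins_by_anchor: dict[tuple[str, int], Mutation] = {}
    flat: list[Mutation] = []
    for chrom, muts in mutation_set.by_chrom.items():
        subs = [m for m in muts if m.kind != "INS"]
        sub_positions[chrom] = [m.pos for m in subs]
        sub_entries[chrom] = subs
        for m in muts:
            if m.kind == "INS":
                ins_by_anchor[(chrom, m.pos)] = m
        flat.extend(muts)
    index_of = {id(m): i for i, m in enumerate(flat)}
    support = [0] * len(flat)

    for pair, end1, end2 in pairs_with_records:
        for end_index, records in ((0, end1), (1, end2)):
            eff = _effective_records(records, end_index)
            for rec, tstrand in eff:
                # SNV/deletion support from the M/D footprint
                positions = sub_positions.get(rec.chrom)
                if positions:
                    muts = sub_entries[rec.chrom]
                    for s, e in rec.aligned_ref_intervals():
                        for i in range(bisect_left(positions, s), bisect_right(positions, e - 1)):
                            support[index_of[id(muts[i])]] += 1
                # insertion support from I ops
                for anchor, _ln in rec.insertion_anchors():
                    m = ins_by_anchor.get((rec.chrom, anchor))
                    if m is not None:
                        support[index_of[id(m)]] += 1
                # introns
                for istart, iend in rec.introns():
                    if iend - istart > colinear_threshold:
                        if tstrand == "+":
                            key = (rec.chrom, istart - 1, tstrand, rec.chrom, iend, tstrand,
                                   JunctionClass.COLINEAR_FUSION.value)
                        else:
                            key = (rec.chrom, iend, tstrand, rec.chrom, istart - 1, tstrand,
                                   JunctionClass.COLINEAR_FUSION.value)
                        db.fusions[key] = db.fusions.get(key, 0) + 1
                    else:
                        key = (rec.chrom, istart, iend, tstrand)
                        db.splices[key] = db.splices.get(key, 0) + 1
            # junctions between consecutive records (fusion breakpoints)
            for (ra, sa), (rb, sb) in zip(eff, eff[1:]):
                p1 = ra.ref_end - 1 if sa == "+" else ra.pos
                p2 = rb.pos if sb == "+" else rb.ref_end - 1
                cls = classify_junction(ra.chrom, p1, sa, rb.chrom, p2, sb, colinear_threshold)
                if cls is JunctionClass.SPLICE:
                    intron = (p1 + 1, p2) if sa == "+" else (p2 + 1, p1)
                    key = (ra.chrom, intron[0], intron[1], sa)
                    db.splices[key] = db.splices.get(key, 0) + 1
                else:
                    key = (ra.chrom, p1, sa, rb.chrom, p2, sb, cls.value)
                    db.fusions[key] = db.fusions.get(key, 0) + 1

    db.mutations = [(m, c) for m, c in zip(flat, support) if c > 0]
    return db


MANIFEST_NAME = "manifest.json"


def write_outputs(pairs_with_records, truth_db: TruthDB, outdir: str,
                  genome: Genome, read_length: int,
                  manifest_extra: dict | None = None) -> dict:
    """Write the dataset directory: paired FASTQ with truth-encoded names,
    truth mutation TSV/VCF, splice BED6, fusion TSV and a JSON manifest.

    Returns the manifest dictionary.
    """
    os.makedirs(outdir, exist_ok=True)
    n_pairs = 0
    with open(os.path.join(outdir, "reads_1.fastq"), "w") as f1, \
         open(os.path.join(outdir, "reads_2.fastq"), "w") as f2:
        for pair, end1, end2 in pairs_with_records:
            name = pair_read_name(pair, end1, end2, read_length)
            qual = FASTQ_QUALITY * read_length
            f1.write(f"@{name}\n{pair.seq1}\n+\n{qual}\n")
            f2.write(f"@{name}\n{pair.seq2}\n+\n{qual}\n")
            n_pairs += 1

    muts = [m for m, _ in truth_db.mutations]
    supp = {(m.chrom, m.pos, m.kind): c for m, c in truth_db.mutations}
    write_mutations_tsv(muts, os.path.join(outdir, "mutations.tsv"), support=supp)
    write_mutations_vcf(muts, genome, os.path.join(outdir, "mutations.vcf"))

    with open(os.path.join(outdir, "splices.bed"), "w") as fh:
        for (chrom, istart, iend, strand), count in sorted(truth_db.splices.items()):
            name = f"{chrom}:{istart + 1}-{iend}"
            fh.write(f"{chrom}\t{istart}\t{iend}\t{name}\t{count}\t{strand}\n")

    write_fusions_tsv(
        [((c1, p1, s1, c2, p2, s2, cls), count)
         for (c1, p1, s1, c2, p2, s2, cls), count in sorted(truth_db.fusions.items())],
        os.path.join(outdir, "fusions.tsv"),
    )

    manifest = {
        "n_read_pairs": n_pairs,
        "read_length": read_length,
        "chromosomes": genome.lengths(),
        "truth_counts": truth_db.counts(),
    }
    manifest.update(manifest_extra or {})
    with open(os.path.join(outdir, MANIFEST_NAME), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def load_truth_dir(path: str) -> tuple[TruthDB, dict]:
    """Load a dataset directory written by :func:`write_outputs`."""
    with open(os.path.join(path, MANIFEST_NAME)) as fh:
        manifest = json.load(fh)
    db = TruthDB()
    for m in read_mutations_tsv(os.path.join(path, "mutations.tsv")):
        db.mutations.append((m, 1))
    with open(os.path.join(path, "splices.bed")) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, _, score, strand = line.rstrip("\n").split("\t")[:6]
            db.splices[(chrom, int(s), int(e), strand)] = int(score)
    for row in _read_fusion_rows(os.path.join(path, "fusions.tsv")):
        db.fusions[row[0]] = row[1]
    return db, manifest


def _read_fusion_rows(path: str):
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            support = int(f[7]) if len(f) > 7 else 1
            yield (f[0], int(f[1]) - 1, f[2], f[3], int(f[4]) - 1, f[5], f[6]), support
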