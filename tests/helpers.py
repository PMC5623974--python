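"""Independent oracles used across the test suite.

Everything here is deliberately naive — per-base edit scripts, all-pairs
matching with plain loops, direct FASTQ walks — so that agreement with
the package's indexed/piecewise implementations is meaningful.
"""

from __future__ import annotations

from truthbench.fusions import JunctionClass, classify_junction
from truthbench.genome import reverse_complement
from truthbench.naming import decode_read_name


def brute_force_base_map(orig_len: int, mutations) -> list[int | None]:
    """Per-base original index of every mutated-genome base (None for
    inserted bases), built by walking the position-sorted mutation list."""
    out: list[int | None] = []
    cursor = 0
    for m in sorted(mutations, key=lambda m: m.pos):
        while cursor < m.pos:
            out.append(cursor)
            cursor += 1
        if m.kind == "SNV":
            out.append(cursor)
            cursor += 1
        elif m.kind == "INS":
            out.append(cursor)
            cursor += 1
            out.extend([None] * len(m.alt))
        else:
            cursor += len(m.ref)
    while cursor < orig_len:
        out.append(cursor)
        cursor += 1
    return out


def _consume(preds_candidates, n_truth: int, count_ignored_as_fp: bool):
    """First-TP / min-distance accounting over pre-computed candidate
    lists: each element of ``preds_candidates`` is a list of
    (distance, truth_index) already satisfying the match rule."""
    tp = fp = ignored = 0
    consumed: set[int] = set()
    for cands in preds_candidates:
        if not cands:
            fp += 1
            continue
        cands.sort()
        _, idx = cands[0]
        if idx in consumed:
            ignored += 1
            if count_ignored_as_fp:
                fp += 1
        else:
            consumed.add(idx)
            tp += 1
    return tp, fp, n_truth - len(consumed), ignored


def brute_force_splices(preds, truth, threshold, count_ignored_as_fp=False):
    """All-pairs splice matcher: overlap + d = |ds|+|de| <= threshold."""
    rows = []
    for p in preds:
        cands = []
        for i, t in enumerate(truth):
            if p.chrom != t.chrom:
                continue
            if "." not in (p.strand, t.strand) and p.strand != t.strand:
                continue
            if p.start > t.end or t.start > p.end:
                continue
            d = abs(p.start - t.start) + abs(p.end - t.end)
            if d <= threshold:
                cands.append((d, i))
        rows.append(cands)
    return _consume(rows, len(truth), count_ignored_as_fp)


def brute_force_mutations(preds, truth, threshold, count_ignored_as_fp=False):
    """All-pairs mutation matcher: same kind, |dpos| <= threshold, SNV alt
    equality, indel length agreement within threshold."""
    rows = []
    for p in preds:
        cands = []
        for i, t in enumerate(truth):
            if p.chrom != t.chrom or p.kind != t.kind:
                continue
            if abs(p.pos - t.pos) > threshold:
                continue
            if t.kind == "SNV" and p.alt != t.alt:
                continue
            if t.kind == "INS" and abs(len(p.alt) - len(t.alt)) > threshold:
                continue
            if t.kind == "DEL" and abs(len(p.ref) - len(t.ref)) > threshold:
                continue
            cands.append((abs(p.pos - t.pos), i))
        rows.append(cands)
    return _consume(rows, len(truth), count_ignored_as_fp)


def _canon(row):
    c1, p1, s1, c2, p2, s2 = row
    if (c2, p2) < (c1, p1):
        flip = {"+": "-", "-": "+"}
        return (c2, p2, flip[s2], c1, p1, flip[s1])
    return row


def brute_force_fusions(preds, truth, threshold, count_ignored_as_fp=False):
    """All-pairs fusion matcher on orientation-normalized side pairs."""
    truth_c = [_canon(t) for t in truth]
    rows = []
    for p in preds:
        pc = _canon(p)
        cands = []
        for i, t in enumerate(truth_c):
            if (pc[0], pc[3]) != (t[0], t[3]) or (pc[2], pc[5]) != (t[2], t[5]):
                continue
            d = abs(pc[1] - t[1]) + abs(pc[4] - t[4])
            if d <= threshold:
                cands.append((d, i))
        rows.append(cands)
    return _consume(rows, len(truth), count_ignored_as_fp)


def _record_query_interval(rec, read_length):
    ops = rec.cigar_ops()
    lead = ops[0][1] if ops[0][0] == "S" else 0
    trail = ops[-1][1] if ops[-1][0] == "S" else 0
    if rec.strand == "+":
        return lead, read_length - trail
    return trail, read_length - lead


def split_records_by_end(alignments, read_length):
    """Partition a name's concatenated records into per-end groups using
    the documented convention that per-record local query lengths (M+I)
    sum to the read length within each end."""
    ends, cur, acc = [], [], 0
    for rec in alignments:
        cur.append(rec)
        acc += rec.local_query_length
        if acc == read_length:
            ends.append(cur)
            cur, acc = [], 0
        elif acc > read_length:
            raise AssertionError("record group overruns the read length")
    assert not cur, "records do not tile the read pair"
    return ends


def reconstruct_truth_from_reads(dataset_dir, genome, read_length,
                                 colinear_threshold=300_000):
    """Re-derive every truth event from read names + original genome only.

    Returns dict with key sets: snv/ins/del as (chrom, pos), splices as
    (chrom, intron_start, intron_end), fusions as full side-pair keys.
    Sequencing errors (decoded from the names) are skipped when calling
    substitutions.
    """
    out = {"snv": set(), "ins": set(), "del": set(), "splices": set(), "fusions": set()}
    with open(f"{dataset_dir}/reads_1.fastq") as f1, open(f"{dataset_dir}/reads_2.fastq") as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline(), f1.readline()
            f2.readline()
            s2 = f2.readline().strip()
            f2.readline(), f2.readline()
            decoded = decode_read_name(h1[1:].strip())
            ends = split_records_by_end(decoded.alignments, read_length)
            errs = [
                {p for p in decoded.err_pos if p < read_length},
                {p - read_length for p in decoded.err_pos if p >= read_length},
            ]
            for ei, (records, seq) in enumerate(zip(ends, (s1, s2))):
                for rec in records:
                    tstrand = rec.strand if ei == 0 else ("-" if rec.strand == "+" else "+")
                    _scan_record(rec, seq, errs[ei], genome, read_length, out,
                                 tstrand, colinear_threshold)
                ordered = records if ei == 0 else list(reversed(records))
                strands = [r.strand if ei == 0 else ("-" if r.strand == "+" else "+")
                           for r in ordered]
                for (ra, sa), (rb, sb) in zip(zip(ordered, strands),
                                              zip(ordered[1:], strands[1:])):
                    p1 = ra.ref_end - 1 if sa == "+" else ra.pos
                    p2 = rb.pos if sb == "+" else rb.ref_end - 1
                    cls = classify_junction(ra.chrom, p1, sa, rb.chrom, p2, sb,
                                            colinear_threshold)
                    if cls is JunctionClass.SPLICE:
                        intron = (p1 + 1, p2) if sa == "+" else (p2 + 1, p1)
                        out["splices"].add((ra.chrom, intron[0], intron[1]))
                    else:
                        out["fusions"].add((ra.chrom, p1, sa, rb.chrom, p2, sb, cls.value))
    return out


def _scan_record(rec, seq, errors, genome, read_length, out, tstrand, colinear_threshold):
    q0, q1 = _record_query_interval(rec, read_length)
    segment = seq[q0:q1]
    gseq = reverse_complement(segment) if rec.strand == "-" else segment

    def read_offset(i):  # read coordinate of genomic-order index i
        return q0 + i if rec.strand == "+" else q0 + (len(segment) - 1 - i)

    pos, qi = rec.pos, 0
    for op, n in rec.cigar_ops():
        if op == "M":
            ref = genome[rec.chrom][pos:pos + n]
            for k in range(n):
                if gseq[qi + k] != ref[k] and read_offset(qi + k) not in errors:
                    out["snv"].add((rec.chrom, pos + k))
            pos += n
            qi += n
        elif op == "I":
            out["ins"].add((rec.chrom, pos - 1))
            qi += n
        elif op == "D":
            out["del"].add((rec.chrom, pos))
            pos += n
        elif op == "N":
            if n > colinear_threshold:  # a huge intron is a colinear fusion junction
                if tstrand == "+":
                    key = (rec.chrom, pos - 1, tstrand, rec.chrom, pos + n, tstrand,
                           "COLINEAR_FUSION")
                else:
                    key = (rec.chrom, pos + n, tstrand, rec.chrom, pos - 1, tstrand,
                           "COLINEAR_FUSION")
                out["fusions"].add(key)
            else:
                out["splices"].add((rec.chrom, pos, pos + n))
            pos += n
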