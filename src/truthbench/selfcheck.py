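"""Export a dataset's own truth as prediction files.

Feeding a simulated dataset's truth back into the evaluator is the
basic self-consistency check of the whole suite: every event must come
back as a true positive (precision = recall = F-score = 1).  The
exporters here produce pipeline-shaped files (SAM, BED, VCF, TSV)
directly from a truth directory.
"""

from __future__ import annotations

import os

from truthbench import naming
from truthbench.fusions import write_fusions_tsv
from truthbench.variants import DEL, INS, SNV


def export_truth_predictions(dataset_dir: str, outdir: str) -> dict[str, str]:
    """Write truth-derived prediction files for every event type.

    Alignments come from decoding the FASTQ read names (one SAM record
    per end, taking the first encoded truth record for end 1 and the
    last for end 2); the other events are format conversions of the
    truth files.  Returns a mapping event -> path.
    """
    db, manifest = naming.load_truth_dir(dataset_dir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "alignment": os.path.join(outdir, "alignments.sam"),
        "splice": os.path.join(outdir, "splices.bed"),
        "snv": os.path.join(outdir, "mutations.vcf"),
        "insertion": os.path.join(outdir, "mutations.vcf"),
        "deletion": os.path.join(outdir, "mutations.vcf"),
        "fusion": os.path.join(outdir, "fusions.tsv"),
    }

    with open(paths["alignment"], "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in manifest["chromosomes"].items():
            sam.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        with open(os.path.join(dataset_dir, "reads_1.fastq")) as fq:
            while True:
                header = fq.readline()
                if not header:
                    break
                seq = fq.readline().strip()
                fq.readline(), fq.readline()
                name = header[1:].strip()
                decoded = naming.decode_read_name(name)
                for flag_end, rec in ((0x40, decoded.alignments[0]),
                                      (0x80, decoded.alignments[-1])):
                    flag = 0x1 | 0x2 | flag_end | (0x10 if rec.strand == "-" else 0)
                    cigar = rec.cigar if flag_end == 0x40 else f"{len(seq)}M"
                    # the mate's sequence is not at hand; emit the end-1
                    # sequence with a length-matched CIGAR — the evaluator
                    # only uses name, position and reference span
                    sam.write(f"{name}\t{flag}\t{rec.chrom}\t{rec.pos + 1}\t60\t"
                              f"{cigar}\t*\t0\t0\t{seq}\t*\tNH:i:1\n")

    with open(paths["splice"], "w") as bed:
        for (chrom, s, e, strand), _count in sorted(db.splices.items()):
            bed.write(f"{chrom}\t{s}\t{e}\tj\t0\t{strand}\n")

    _write_mutation_vcf(db, manifest, paths["snv"])

    write_fusions_tsv(
        [((c1, p1, s1, c2, p2, s2, cls), count)
         for (c1, p1, s1, c2, p2, s2, cls), count in sorted(db.fusions.items())],
        paths["fusion"])
    return paths


def _write_mutation_vcf(db: naming.TruthDB, manifest: dict, path: str) -> None:
    # anchor bases are unknown without the genome; synthesize placeholder
    # anchors ('A') — evaluation compares positions, kinds, lengths and
    # SNV alternate bases only
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, n in manifest["chromosomes"].items():
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m, _count in sorted(db.mutations, key=lambda x: (x[0].chrom, x[0].pos)):
            if m.kind == SNV:
                fh.write(f"{m.chrom}\t{m.pos + 1}\t.\t{m.ref}\t{m.alt}\t.\t.\t.\n")
            elif m.kind == INS:
                fh.write(f"{m.chrom}\t{m.pos + 1}\t.\tA\tA{m.alt}\t.\t.\t.\n")
            elif m.kind == DEL:
                fh.write(f"{m.chrom}\t{m.pos}\t.\tA{m.ref}\tA\t.\t.\t.\n")
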