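import numpy as np
import pytest

from helpers import brute_force_fusions, brute_force_mutations, brute_force_splices
from truthbench.evaluate import (
    ConfusionCounts,
    GenomicInterval,
    GITree,
    compute_metrics,
    evaluate_alignments,
    evaluate_fusions,
    evaluate_mutations,
    evaluate_splices,
    run_benchmark,
)
from truthbench.naming import ReadAlignmentRecord, encode_read_name
from truthbench.variants import DEL, INS, SNV, Mutation


class TestGITree:
    def test_empty_tree_returns_nothing(self):
        tree = GITree()
        assert tree.query(GenomicInterval("c", 10, 20, "+")) == []

    def test_exact_match_returned(self):
        tree = GITree()
        gi = GenomicInterval("c", 10, 20, "+")
        tree.insert(gi, "x")
        assert tree.query(gi) == ["x"]

    def test_strand_partitioning_and_undefined_strand(self):
        tree = GITree()
        tree.insert(GenomicInterval("c", 10, 20, "+"), "plus")
        tree.insert(GenomicInterval("c", 10, 20, "."), "both")
        assert sorted(tree.query(GenomicInterval("c", 15, 16, "-"))) == ["both"]
        assert sorted(tree.query(GenomicInterval("c", 15, 16, "+"))) == ["both", "plus"]
        assert sorted(tree.query(GenomicInterval("c", 15, 16, "."))) == ["both", "plus"]

    def test_query_equals_brute_force_scan(self, rng):
        entries = [GenomicInterval("c", int(s), int(s + rng.integers(1, 500)),
                                   str(rng.choice(["+", "-"])))
                   for s in rng.integers(0, 50_000, 1000)]
        tree = GITree()
        for i, gi in enumerate(entries):
            tree.insert(gi, i)
        for _ in range(1000):
            s = int(rng.integers(0, 50_000))
            probe = GenomicInterval("c", s, s + int(rng.integers(1, 300)),
                                    str(rng.choice(["+", "-"])))
            expected = {i for i, t in enumerate(entries)
                        if t.strand == probe.strand
                        and probe.start <= t.end and t.start <= probe.end}
            assert set(tree.query(probe)) == expected


class TestMetrics:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (0, 0, 0, (0.0, 0.0, 0.0)),
        (10, 0, 0, (1.0, 1.0, 1.0)),
        (90, 10, 110, (0.9, 0.45, 0.6)),
    ])
    def test_formulas_and_degenerate_convention(self, tp, fp, fn, expected):
        m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn))
        assert (m.precision, m.recall, pytest.approx(m.fscore)) == expected


def _junction(start, end, chrom="c", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestSpliceEvaluation:
    TRUTH = [_junction(1000, 2000)]

    @pytest.mark.parametrize("dstart,dend,is_tp", [
        (0, 0, True), (5, 5, True), (10, 0, True), (6, 4, True),
        (6, 5, False), (11, 0, False),
    ])
    def test_distance_threshold_boundary(self, dstart, dend, is_tp):
        pred = [_junction(1000 + dstart, 2000 + dend)]
        counts = evaluate_splices(pred, self.TRUTH, threshold=10)
        assert (counts.tp, counts.fp) == ((1, 0) if is_tp else (0, 1))

    def test_minimum_distance_candidate_consumed(self):
        # candidates at d=4 (1000,2000) and d=3 (1003,2004): the d=3 one wins
        truth = [_junction(1000, 2000), _junction(1003, 2004)]
        counts = evaluate_splices([_junction(1002, 2002)], truth, threshold=10)
        assert counts.tp == 1 and counts.fn == 1
        assert counts.tp_ids == ["c:1004-2004:+"]

    def test_duplicate_prediction_ignored_not_fp(self):
        pred = [_junction(1000, 2000), _junction(1000, 2000)]
        counts = evaluate_splices(pred, self.TRUTH, threshold=10)
        assert (counts.tp, counts.fp, counts.ignored) == (1, 0, 1)
        counts = evaluate_splices(pred, self.TRUTH, threshold=10, count_ignored_as_fp=True)
        assert (counts.tp, counts.fp) == (1, 1)

    def test_strand_mismatch_is_fp(self):
        counts = evaluate_splices([_junction(1000, 2000, strand="-")], self.TRUTH, 10)
        assert counts.fp == 1


class TestMutationEvaluation:
    TRUTH_SNV = [Mutation(SNV, "c", 500, "A", "G")]

    @pytest.mark.parametrize("offset,alt,is_tp", [
        (0, "G", True), (5, "G", True), (-5, "G", True),
        (6, "G", False), (0, "T", False),
    ])
    def test_snv_offset_and_alt_rules(self, offset, alt, is_tp):
        pred = [Mutation(SNV, "c", 500 + offset, "A", alt)]
        counts = evaluate_mutations(pred, self.TRUTH_SNV, threshold=5, kind=SNV)
        assert (counts.tp == 1) is is_tp

    @pytest.mark.parametrize("length,is_tp", [(5, True), (10, True), (11, False)])
    def test_insertion_length_agreement(self, length, is_tp):
        truth = [Mutation(INS, "c", 500, "", "AAAAA")]
        pred = [Mutation(INS, "c", 500, "", "A" * length)]
        counts = evaluate_mutations(pred, truth, threshold=5, kind=INS)
        assert (counts.tp == 1) is is_tp

    def test_deletion_length_agreement(self):
        truth = [Mutation(DEL, "c", 500, "AAAA", "")]
        ok = evaluate_mutations([Mutation(DEL, "c", 503, "AAA", "")], truth, 5, kind=DEL)
        assert ok.tp == 1
        bad = evaluate_mutations([Mutation(DEL, "c", 503, "A" * 10, "")], truth, 5, kind=DEL)
        assert bad.fp == 1

    def test_kind_confusion_never_matches(self):
        truth = [Mutation(INS, "c", 500, "", "AA")]
        counts = evaluate_mutations([Mutation(DEL, "c", 500, "AA", "")], truth, 5, kind=DEL)
        assert counts.tp == 0 and counts.fp == 1 and counts.fn == 0  # truth filtered by kind


class TestFusionEvaluation:
    LENGTHS = {"chr1": 1_000_000, "chr2": 1_000_000}
    TRUTH = [("chr1", 5000, "+", "chr2", 7000, "-")]

    @pytest.mark.parametrize("d1,d2,is_tp", [
        (0, 0, True), (12, 8, True), (12, 9, False), (20, 0, True), (21, 0, False),
    ])
    def test_combined_breakpoint_distance_boundary(self, d1, d2, is_tp):
        pred = [("chr1", 5000 + d1, "+", "chr2", 7000 + d2, "-")]
        counts = evaluate_fusions(pred, self.TRUTH, self.LENGTHS, threshold=20)
        assert (counts.tp == 1) is is_tp

    def test_composite_strand_mismatch_is_fp(self):
        pred = [("chr1", 5000, "+", "chr2", 7000, "+")]
        counts = evaluate_fusions(pred, self.TRUTH, self.LENGTHS, threshold=20)
        assert counts.fp == 1

    def test_orientation_normalization_matches_swapped_sides(self):
        # the same junction written in the other orientation still matches
        pred = [("chr2", 7000, "+", "chr1", 5000, "-")]
        counts = evaluate_fusions(pred, self.TRUTH, self.LENGTHS, threshold=20)
        assert counts.tp == 1

    def test_unknown_chromosome_prediction_skipped(self):
        with pytest.warns(UserWarning, match="unknown chromosome"):
            counts = evaluate_fusions([("chrX", 1, "+", "chr1", 2, "+")],
                                      self.TRUTH, self.LENGTHS, 20)
        assert counts.fp == 0 and counts.fn == 1


def _write_sam(path, records, lengths, tags=()):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for chrom, ln in lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for name, flag, chrom, pos1, cigar, tag in records:
            seq_len = sum(int(n) for n, op in
                          __import__("re").findall(r"(\d+)([MIS])", cigar))
            fh.write(f"{name}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t"
                     f"{'A' * seq_len}\t*{tag}\n")


class TestAlignmentEvaluation:
    LENGTHS = {"c": 100_000}

    def _name(self, read_id=0, pos=999, cigar="101M;"):
        recs = [ReadAlignmentRecord("c", pos, "+", "101M"),
                ReadAlignmentRecord("c", pos + 300, "-", "101M")]
        return encode_read_name(read_id, recs, [])

    def test_exact_and_one_base_overlap_are_tp(self, tmp_path):
        name = self._name(pos=999)
        sam = tmp_path / "a.sam"
        _write_sam(sam, [
            (name, 0x41, "c", 1000, "101M", ""),      # exact (end 1)
            (name, 0x81, "c", 1100, "101M", ""),      # overlaps truth end1 by 1 base
        ], self.LENGTHS)
        counts = evaluate_alignments(str(sam), n_read_units=2)
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)

    def test_no_overlap_is_fp_and_missing_read_is_fn(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(sam, [(self._name(pos=999), 0x41, "c", 50_000, "101M", "")],
                   self.LENGTHS)
        counts = evaluate_alignments(str(sam), n_read_units=4)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 4)

    def test_multimapped_record_ignored_under_max_hits(self, tmp_path):
        name = self._name(pos=999)
        sam = tmp_path / "a.sam"
        _write_sam(sam, [(name, 0x41, "c", 1000, "101M", "\tNH:i:5")], self.LENGTHS)
        counts = evaluate_alignments(str(sam), n_read_units=2, max_hits=1)
        assert (counts.tp, counts.fp, counts.fn, counts.ignored) == (0, 0, 2, 1)

    def test_only_first_qualifying_record_evaluated(self, tmp_path):
        name = self._name(pos=999)
        sam = tmp_path / "a.sam"
        _write_sam(sam, [
            (name, 0x41, "c", 50_000, "101M", ""),  # first encountered: FP
            (name, 0x41, "c", 1000, "101M", ""),    # correct but ignored
        ], self.LENGTHS)
        counts = evaluate_alignments(str(sam), n_read_units=2)
        assert (counts.tp, counts.fp) == (0, 1)


def _random_junctions(rng, n, chroms=("c1", "c2")):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, 100_000))
        out.append(GenomicInterval(str(rng.choice(chroms)), s,
                                   s + int(rng.integers(50, 5000)),
                                   str(rng.choice(["+", "-"]))))
    return out


def _perturb_junction(rng, t):
    return GenomicInterval(t.chrom, t.start + int(rng.integers(-8, 9)),
                           t.end + int(rng.integers(-8, 9)), t.strand)


class TestOracleEquivalence:
    """TP/FP/FN of every evaluator equals an all-pairs brute-force matcher
    honoring the same rules, on randomized truth/prediction sets."""

    def test_splices_match_brute_force(self):
        rng = np.random.default_rng(202)
        for trial in range(30):
            truth = _random_junctions(rng, int(rng.integers(5, 80)))
            preds = [_perturb_junction(rng, truth[int(rng.integers(0, len(truth)))])
                     if rng.random() < 0.7 else j
                     for j in _random_junctions(rng, int(rng.integers(5, 80)))]
            as_fp = bool(rng.random() < 0.5)
            counts = evaluate_splices(preds, truth, 10, count_ignored_as_fp=as_fp)
            assert (counts.tp, counts.fp, counts.fn, counts.ignored) == \
                brute_force_splices(preds, truth, 10, as_fp)

    def test_mutations_match_brute_force(self):
        rng = np.random.default_rng(203)
        bases = "ACGT"
        for trial in range(30):
            truth, preds = [], []
            for _ in range(int(rng.integers(5, 100))):
                kind = str(rng.choice([SNV, INS, DEL]))
                pos = int(rng.integers(0, 5000))
                ln = int(rng.integers(1, 12))
                if kind == SNV:
                    m = Mutation(SNV, "c", pos, "A", bases[int(rng.integers(1, 4))])
                elif kind == INS:
                    m = Mutation(INS, "c", pos, "", "A" * ln)
                else:
                    m = Mutation(DEL, "c", pos, "A" * ln, "")
                (truth if rng.random() < 0.5 else preds).append(m)
                if rng.random() < 0.4:  # near-duplicate on the other side
                    preds.append(Mutation(m.kind, "c", pos + int(rng.integers(-7, 8)),
                                          m.ref, m.alt or m.alt))
            for kind in (SNV, INS, DEL):
                counts = evaluate_mutations(preds, truth, 5, kind=kind)
                t = [x for x in truth if x.kind == kind]
                p = [x for x in preds if x.kind == kind]
                assert (counts.tp, counts.fp, counts.fn, counts.ignored) == \
                    brute_force_mutations(p, t, 5)

    def test_fusions_match_brute_force(self):
        rng = np.random.default_rng(204)
        lengths = {"c1": 200_000, "c2": 200_000}
        for trial in range(30):
            def row():
                return (str(rng.choice(["c1", "c2"])), int(rng.integers(0, 100_000)),
                        str(rng.choice(["+", "-"])), str(rng.choice(["c1", "c2"])),
                        int(rng.integers(0, 100_000)), str(rng.choice(["+", "-"])))
            truth = [row() for _ in range(int(rng.integers(3, 40)))]
            preds = []
            for t in truth:
                if rng.random() < 0.6:
                    preds.append((t[0], t[1] + int(rng.integers(-15, 16)), t[2],
                                  t[3], t[4] + int(rng.integers(-15, 16)), t[5]))
            preds += [row() for _ in range(int(rng.integers(0, 20)))]
            counts = evaluate_fusions(preds, truth, lengths, 20)
            assert (counts.tp, counts.fp, counts.fn, counts.ignored) == \
                brute_force_fusions(preds, truth, 20)


class TestInvariants:
    def test_conservation_and_threshold_monotonicity(self):
        rng = np.random.default_rng(205)
        for _ in range(20):
            truth = _random_junctions(rng, 40)
            preds = [_perturb_junction(rng, t) for t in truth[:30]]
            preds += _random_junctions(rng, 10)
            last_tp = -1
            for threshold in (0, 2, 5, 10, 20, 50):
                counts = evaluate_splices(preds, truth, threshold)
                assert counts.tp + counts.fn == len(truth)
                assert counts.tp + counts.fp <= len(preds)
                assert counts.tp >= last_tp
                last_tp = counts.tp


class TestRunBenchmark:
    def _dataset(self, tmp_path, toy_genome):
        from truthbench.naming import TruthDB, write_outputs
        db = TruthDB()
        db.mutations = [(Mutation(SNV, "chr1", 100 + 10 * i, "A", "G"), 1)
                        for i in range(200)]
        outdir = tmp_path / "ds"
        write_outputs([], db, str(outdir), toy_genome, 101)
        return outdir

    def test_zero_pipelines_gives_empty_report(self, tmp_path, toy_genome):
        outdir = self._dataset(tmp_path, toy_genome)
        report = run_benchmark({"truth": str(outdir), "pipelines": []})
        assert report.empty

    def test_planted_confusion_counts_reproduced(self, tmp_path, toy_genome):
        # 90 correct SNVs, 10 planted FPs, 110 unmatched truths
        outdir = self._dataset(tmp_path, toy_genome)
        vcf = tmp_path / "p.vcf"
        lines = ["##fileformat=VCFv4.2", "##contig=<ID=chr1,length=100000>",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        for i in range(90):
            lines.append(f"chr1\t{101 + 10 * i}\t.\tA\tG\t.\t.\t.")
        for i in range(10):
            lines.append(f"chr1\t{50_000 + 100 * i}\t.\tA\tG\t.\t.\t.")
        vcf.write_text("\n".join(lines) + "\n")
        report = run_benchmark({"truth": str(outdir),
                                "pipelines": [{"name": "p", "snv": str(vcf)}]})
        row = report.iloc[0]
        assert (row.TP, row.FP, row.FN) == (90, 10, 110)
        assert (row.precision, row.recall, row.fscore) == (0.9, 0.45, pytest.approx(0.6))

    def test_missing_file_fails_row_but_not_run(self, tmp_path, toy_genome):
        outdir = self._dataset(tmp_path, toy_genome)
        vcf = tmp_path / "ok.vcf"
        vcf.write_text("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=100000>\n"
                       "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                       "chr1\t100\t.\tA\tG\t.\t.\t.\n")
        report = run_benchmark({"truth": str(outdir), "pipelines": [
            {"name": "broken", "snv": str(tmp_path / "missing.vcf")},
            {"name": "ok", "snv": str(vcf)},
        ]})
        assert report.attrs["n_errors"] == 1
        assert "error" in report.columns
        ok_rows = report[report.pipeline == "ok"]
        # VCF pos 100 sits 1 base from the truth SNV at 101: within threshold
        assert len(ok_rows) == 1 and ok_rows.iloc[0].TP == 1

    def test_report_sorted_by_fscore_descending(self, tmp_path, toy_genome):
        outdir = self._dataset(tmp_path, toy_genome)

        def vcf_with(path, n_good, n_bad):
            lines = ["##fileformat=VCFv4.2", "##contig=<ID=chr1,length=100000>",
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
            lines += [f"chr1\t{101 + 10 * i}\t.\tA\tG\t.\t.\t." for i in range(n_good)]
            lines += [f"chr1\t{60_000 + 100 * i}\t.\tA\tG\t.\t.\t." for i in range(n_bad)]
            path.write_text("\n".join(lines) + "\n")
            return str(path)

        report = run_benchmark({"truth": str(outdir), "pipelines": [
            {"name": "weak", "snv": vcf_with(tmp_path / "w.vcf", 50, 50)},
            {"name": "strong", "snv": vcf_with(tmp_path / "s.vcf", 190, 2)},
        ]})
        assert list(report.pipeline) == ["strong", "weak"]
        assert report.fscore.is_monotonic_decreasing
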