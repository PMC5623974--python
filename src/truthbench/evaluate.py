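"""Qualitative benchmark evaluation against a simulated truth database.

Truth events are indexed in per-(chromosome, strand) interval trees so a
prediction can be matched against nearby truth entries in logarithmic
time.  Matching rules per event type:

* **alignments** — the first SAM record encountered for each read end
  whose NH does not exceed ``max_hits`` is evaluated; it is a TP when it
  overlaps any truth alignment of that read (decoded from the read name)
  by at least one base on the same chromosome.  Reads never evaluated
  count as FN; the recall denominator is the number of simulated read
  ends.
* **splice junctions** — candidates are overlapping truth junctions;
  a prediction matches when ``d = |Δstart| + |Δend| <= threshold``
  (default 10), taking the minimum-distance candidate.
* **SNVs / insertions / deletions** — candidates are truth mutations of
  the same kind within ``±threshold`` positions (default 5); SNVs must
  also carry the correct alternate base, indels a length within the
  threshold of the truth length.
* **fusions** — each side pair (chr1, pos1, strand1, chr2, pos2,
  strand2) is transformed into a composite interval with
  ``chr = chr1·chr2``, ``start = pos1``, ``end = len(chr1) + pos2`` and
  ``strand = strand1·strand2``; matching then follows the splice rule
  with the fusion threshold (default 20).  Side pairs are orientation-
  normalized (lexicographically, flipping both strands on swap) before
  comparison.

When several predictions hit the same truth entry, only the first is a
TP; later duplicates are ignored — excluded from both TP and FP — unless
``count_ignored_as_fp`` is set.  A truth entry never matched is an FN.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam
import yaml
from intervaltree import IntervalTree

from truthbench import naming
from truthbench.variants import DEL, INS, SNV, Mutation

logger = logging.getLogger(__name__)

DEFAULT_SPLICE_THRESHOLD = 10
DEFAULT_MUTATION_THRESHOLD = 5
DEFAULT_FUSION_THRESHOLD = 20
DEFAULT_MAX_HITS = 1

UNDEFINED_STRAND = "."


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = UNDEFINED_STRAND

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")


@dataclass
class EvalThresholds:
    splice: int = DEFAULT_SPLICE_THRESHOLD
    mutation: int = DEFAULT_MUTATION_THRESHOLD
    fusion: int = DEFAULT_FUSION_THRESHOLD
    max_hits: int = DEFAULT_MAX_HITS


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    ignored: int = 0
    tp_ids: list = field(default_factory=list)


@dataclass
class MetricTriple:
    precision: float
    recall: float
    fscore: float


def compute_metrics(counts: ConfusionCounts) -> MetricTriple:
    """Precision, recall and F-score; degenerate denominators give 0, so
    empty outputs rank last."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    fscore = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return MetricTriple(precision, recall, fscore)


class GITree:
    """Per-(chromosome, strand) interval trees over truth intervals.

    Entries with undefined strand are indexed on both strands; queries
    with undefined strand search both strands.
    """

    def __init__(self):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._n = 0

    def insert(self, gi: GenomicInterval, payload) -> None:
        strands = ("+", "-") if gi.strand == UNDEFINED_STRAND else (gi.strand,)
        for s in strands:
            self._trees.setdefault((gi.chrom, s), IntervalTree()).addi(
                gi.start, gi.end + 1, payload)
        self._n += 1

    def query(self, gi: GenomicInterval) -> list:
        strands = ("+", "-") if gi.strand == UNDEFINED_STRAND else (gi.strand,)
        seen = {}
        for s in strands:
            tree = self._trees.get((gi.chrom, s))
            if tree is None:
                continue
            for iv in tree.overlap(gi.start, gi.end + 1):
                seen[id(iv.data)] = iv.data
        return list(seen.values())

    def __len__(self) -> int:
        return self._n


def build_gi_tree(entries) -> GITree:
    """Index ``(GenomicInterval, payload)`` pairs."""
    tree = GITree()
    for gi, payload in entries:
        tree.insert(gi, payload)
    return tree


class _Matcher:
    """Shared first-TP / minimum-distance bookkeeping."""

    def __init__(self, n_truth: int, count_ignored_as_fp: bool):
        self.counts = ConfusionCounts()
        self.consumed: set[int] = set()
        self.n_truth = n_truth
        self.count_ignored_as_fp = count_ignored_as_fp

    def offer(self, candidates: list[tuple[float, int, object]]) -> None:
        """``candidates``: (distance, truth_index, truth_id) already
        filtered to those satisfying the match rule; empty means FP."""
        if not candidates:
            self.counts.fp += 1
            return
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, idx, tid = candidates[0]
        if idx in self.consumed:
            self.counts.ignored += 1
            if self.count_ignored_as_fp:
                self.counts.fp += 1
            return
        self.consumed.add(idx)
        self.counts.tp += 1
        self.counts.tp_ids.append(tid)

    def finish(self) -> ConfusionCounts:
        self.counts.fn = self.n_truth - len(self.consumed)
        return self.counts


def evaluate_splices(predictions: list[GenomicInterval], truth: list[GenomicInterval],
                     threshold: int = DEFAULT_SPLICE_THRESHOLD,
                     count_ignored_as_fp: bool = False) -> ConfusionCounts:
    tree = build_gi_tree((t, (i, t)) for i, t in enumerate(truth))
    matcher = _Matcher(len(truth), count_ignored_as_fp)
    for p in predictions:
        cands = []
        for i, t in tree.query(p):
            d = abs(p.start - t.start) + abs(p.end - t.end)
            if d <= threshold:
                cands.append((d, i, f"{t.chrom}:{t.start + 1}-{t.end}:{t.strand}"))
        matcher.offer(cands)
    return matcher.finish()


def evaluate_mutations(predictions: list[Mutation], truth: list[Mutation],
                       threshold: int = DEFAULT_MUTATION_THRESHOLD,
                       kind: str | None = None,
                       count_ignored_as_fp: bool = False) -> ConfusionCounts:
    """Evaluate SNV/INS/DEL predictions of one ``kind`` (inferred from the
    truth list when None).  Point events: a candidate lies within
    ``±threshold`` of the prediction; SNVs additionally require the
    correct alternate base, indels a length difference ``<= threshold``."""
    if kind is not None:
        truth = [t for t in truth if t.kind == kind]
        predictions = [p for p in predictions if p.kind == kind]
    tree = build_gi_tree(
        (GenomicInterval(t.chrom, t.pos, t.pos), (i, t)) for i, t in enumerate(truth))
    matcher = _Matcher(len(truth), count_ignored_as_fp)
    for p in predictions:
        window = GenomicInterval(p.chrom, p.pos - threshold, p.pos + threshold)
        cands = []
        for i, t in tree.query(window):
            if abs(p.pos - t.pos) > threshold:
                continue
            if t.kind == SNV and p.alt != t.alt:
                continue
            if t.kind in (INS, DEL):
                plen = len(p.alt) if t.kind == INS else len(p.ref)
                tlen = len(t.alt) if t.kind == INS else len(t.ref)
                if abs(plen - tlen) > threshold:
                    continue
            cands.append((abs(p.pos - t.pos), i, f"{t.chrom}:{t.pos + 1}:{t.kind}"))
        matcher.offer(cands)
    return matcher.finish()


FusionSidePair = tuple[str, int, str, str, int, str]


def _canonical_fusion(row: FusionSidePair) -> FusionSidePair:
    """Orientation-normalize: order sides lexicographically by chromosome
    (then position), flipping both strands when swapped."""
    c1, p1, s1, c2, p2, s2 = row
    if (c2, p2) < (c1, p1):
        flip = {"+": "-", "-": "+"}
        return (c2, p2, flip[s2], c1, p1, flip[s1])
    return row


def evaluate_fusions(predictions: list[FusionSidePair], truth: list[FusionSidePair],
                     chrom_lengths: dict[str, int],
                     threshold: int = DEFAULT_FUSION_THRESHOLD,
                     count_ignored_as_fp: bool = False) -> ConfusionCounts:
    """Composite-interval fusion matching (see module docstring)."""

    def transform(row: FusionSidePair):
        c1, p1, s1, c2, p2, s2 = _canonical_fusion(row)
        if c1 not in chrom_lengths or c2 not in chrom_lengths:
            return None
        return GenomicInterval(f"{c1}|{c2}", p1, chrom_lengths[c1] + p2, s1 + s2)

    truth_gis = []
    for t in truth:
        gi = transform(t)
        if gi is None:
            raise KeyError(f"truth fusion names unknown chromosome: {t}")
        truth_gis.append((gi, t))
    tree = GITree()
    for i, (gi, t) in enumerate(truth_gis):
        tree.insert(GenomicInterval(gi.chrom, gi.start, gi.end, gi.strand[0]), (i, gi, t))
    matcher = _Matcher(len(truth_gis), count_ignored_as_fp)
    for p in predictions:
        gi = transform(p)
        if gi is None:
            warnings.warn(f"fusion prediction names unknown chromosome, skipped: {p}")
            continue
        window = GenomicInterval(gi.chrom, gi.start - threshold, gi.end + threshold, gi.strand[0])
        cands = []
        for i, tgi, t in tree.query(window):
            if tgi.strand != gi.strand:
                continue
            d = abs(gi.start - tgi.start) + abs(gi.end - tgi.end)
            if d <= threshold:
                cands.append((d, i, f"{t[0]}:{t[1] + 1}:{t[2]}|{t[3]}:{t[4] + 1}:{t[5]}"))
        matcher.offer(cands)
    return matcher.finish()


def evaluate_alignments(sam_path: str, n_read_units: int,
                        max_hits: int = DEFAULT_MAX_HITS,
                        count_ignored_as_fp: bool = False) -> ConfusionCounts:
    """Evaluate a SAM/BAM of alignments whose read names encode the truth.

    One unit per read end; the first record encountered per unit with
    ``NH <= max_hits`` is scored (TP on >= 1 base same-chromosome overlap
    with any truth alignment of the read).  ``fn`` is the number of
    simulated units never scored as TP.
    """
    counts = ConfusionCounts()
    seen: set[tuple[str, int]] = set()
    undecodable = 0
    with pysam.AlignmentFile(sam_path, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            unit = (rec.query_name, 2 if rec.is_paired and rec.is_read2 else 1)
            if unit in seen:
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
            if nh > max_hits:
                counts.ignored += 1
                if count_ignored_as_fp:
                    seen.add(unit)
                    counts.fp += 1
                continue
            seen.add(unit)
            try:
                decoded = naming.decode_read_name(rec.query_name)
            except naming.ReadNameError:
                undecodable += 1
                continue
            pstart, pend = rec.reference_start, rec.reference_end
            hit = any(
                a.chrom == rec.reference_name and pstart < a.ref_end and a.pos < pend
                for a in decoded.alignments
            )
            if hit:
                counts.tp += 1
                counts.tp_ids.append(f"{decoded.read_id}/{unit[1]}")
            else:
                counts.fp += 1
    if undecodable:
        warnings.warn(f"{undecodable} alignments had undecodable read names and were skipped")
    counts.fn = max(0, n_read_units - counts.tp)
    return counts


# ---------------------------------------------------------------------------
# prediction file parsing


def read_bed_junctions(path: str) -> list[GenomicInterval]:
    """Splice junction predictions from BED (introns, 0-based half-open;
    strand from column 6 when present)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else UNDEFINED_STRAND
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def junctions_from_sam(path: str) -> list[GenomicInterval]:
    """Extract splice junction predictions from the N ops of a SAM/BAM."""
    out = {}
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            pos = rec.reference_start
            for op, ln in rec.cigartuples:
                if op == 3:  # N
                    strand = "-" if rec.is_reverse else "+"
                    out[(rec.reference_name, pos, pos + ln, strand)] = None
                if op in (0, 2, 3, 7, 8):  # consumes reference
                    pos += ln
    return [GenomicInterval(*k) for k in out]


def read_vcf_predictions(path: str) -> list[Mutation]:
    """Parse VCF predictions into normalized mutations.

    Multi-allelic records are split into one candidate per alternate
    allele; shared ref/alt prefixes are left-trimmed before classifying
    each allele as SNV, insertion or deletion.
    """
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                ref, a, pos0 = rec.ref.upper(), alt.upper(), rec.pos - 1
                while len(ref) > 1 and len(a) > 1 and ref[0] == a[0]:
                    ref, a, pos0 = ref[1:], a[1:], pos0 + 1
                if len(ref) == 1 and len(a) == 1:
                    if ref != a:
                        out.append(Mutation(SNV, rec.chrom, pos0, ref, a, source="prediction"))
                elif len(ref) == 1 and a.startswith(ref):
                    out.append(Mutation(INS, rec.chrom, pos0, "", a[1:], source="prediction"))
                elif len(a) == 1 and ref.startswith(a):
                    out.append(Mutation(DEL, rec.chrom, pos0 + 1, ref[1:], "", source="prediction"))
                # other complex alleles are not comparable; skip silently
    return out


# ---------------------------------------------------------------------------
# YAML-driven benchmark runner

EVENT_TYPES = ("alignment", "splice", "snv", "insertion", "deletion", "fusion")


def _truth_mutations(db: naming.TruthDB, kind: str) -> list[Mutation]:
    return [m for m, _ in db.mutations if m.kind == kind]


def _truth_splice_gis(db: naming.TruthDB) -> list[GenomicInterval]:
    return [GenomicInterval(c, s, e, strand) for (c, s, e, strand) in db.splices]


def _truth_fusion_rows(db: naming.TruthDB) -> list[FusionSidePair]:
    return [(c1, p1, s1, c2, p2, s2) for (c1, p1, s1, c2, p2, s2, _cls) in db.fusions]


def run_benchmark(config: dict | str, output_dir: str | None = None) -> pd.DataFrame:
    """Run every pipeline x event evaluation described by a YAML config.

    Config keys: ``truth`` (dataset directory), optional ``thresholds``
    (splice/mutation/fusion/max_hits), ``count_ignored_as_fp``,
    ``output_tp`` and ``pipelines`` — a list of ``{name, alignment: sam,
    splice: bed, snv|insertion|deletion: vcf, fusion: tsv}`` entries
    (any subset of events per pipeline).

    Returns the report as a DataFrame ordered by F-score (descending
    within each event type); with ``output_dir`` also writes
    ``report.tsv`` and, when ``output_tp``, one TP-identifier list per
    pipeline x event.
    """
    if isinstance(config, str):
        with open(config) as fh:
            try:
                config = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ValueError(f"invalid YAML configuration: {exc}") from exc
    if not isinstance(config, dict) or "truth" not in config:
        raise ValueError("benchmark configuration must be a mapping with a 'truth' key")

    db, manifest = naming.load_truth_dir(config["truth"])
    tconf = config.get("thresholds") or {}
    thresholds = EvalThresholds(
        splice=tconf.get("splice", DEFAULT_SPLICE_THRESHOLD),
        mutation=tconf.get("mutation", DEFAULT_MUTATION_THRESHOLD),
        fusion=tconf.get("fusion", DEFAULT_FUSION_THRESHOLD),
        max_hits=tconf.get("max_hits", config.get("max_hits", DEFAULT_MAX_HITS)),
    )
    as_fp = bool(config.get("count_ignored_as_fp", False))
    chrom_lengths = manifest["chromosomes"]
    n_units = 2 * manifest["n_read_pairs"]

    rows = []
    tp_lists: dict[tuple[str, str], list] = {}
    errors = 0
    for pipeline in config.get("pipelines", []) or []:
        name = pipeline.get("name", "pipeline")
        for event in EVENT_TYPES:
            if event not in pipeline:
                continue
            path = pipeline[event]
            try:
                counts = _evaluate_event(event, path, db, thresholds, chrom_lengths,
                                         n_units, as_fp)
            except Exception as exc:  # keep evaluating the other entries
                logger.error("%s/%s failed: %s", name, event, exc)
                rows.append({"pipeline": name, "event": event, "error": str(exc)})
                errors += 1
                continue
            metrics = compute_metrics(counts)
            rows.append({
                "pipeline": name, "event": event,
                "TP": counts.tp, "FP": counts.fp, "FN": counts.fn,
                "precision": metrics.precision, "recall": metrics.recall,
                "fscore": metrics.fscore,
            })
            tp_lists[(name, event)] = counts.tp_ids
        logger.info("evaluated pipeline %s", name)

    report = pd.DataFrame(rows)
    if not report.empty and "fscore" in report.columns:
        report = report.sort_values(["event", "fscore"], ascending=[True, False],
                                    kind="stable").reset_index(drop=True)
    report.attrs["n_errors"] = errors
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        report.to_csv(os.path.join(output_dir, "report.tsv"), sep="\t", index=False)
        if config.get("output_tp", False):
            for (pname, event), ids in tp_lists.items():
                with open(os.path.join(output_dir, f"{pname}.{event}.tp.txt"), "w") as fh:
                    fh.writelines(f"{i}\n" for i in ids)
    return report


def _evaluate_event(event: str, path: str, db: naming.TruthDB,
                    thresholds: EvalThresholds, chrom_lengths: dict[str, int],
                    n_units: int, as_fp: bool) -> ConfusionCounts:
    if event == "alignment":
        return evaluate_alignments(path, n_units, thresholds.max_hits, as_fp)
    if event == "splice":
        preds = (junctions_from_sam(path) if path.endswith((".sam", ".bam"))
                 else read_bed_junctions(path))
        return evaluate_splices(preds, _truth_splice_gis(db), thresholds.splice, as_fp)
    if event in ("snv", "insertion", "deletion"):
        kind = {"snv": SNV, "insertion": INS, "deletion": DEL}[event]
        preds = read_vcf_predictions(path)
        return evaluate_mutations(preds, _truth_mutations(db, kind),
                                  thresholds.mutation, kind=kind,
                                  count_ignored_as_fp=as_fp)
    if event == "fusion":
        from truthbench.fusions import read_fusions_tsv
        preds = read_fusions_tsv(path)
        return evaluate_fusions(preds, _truth_fusion_rows(db), chrom_lengths,
                                thresholds.fusion, as_fp)
    raise ValueError(f"unknown event type {event!r}")
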