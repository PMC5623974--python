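"""End-to-end simulation: mutate, fuse, sequence, lift, encode, write.

The pipeline is: (1) inject SNVs/indels (random and/or VCF-guided) into
the reference, producing a haploid mutated genome and its coordinate
map; (2) shift the annotations onto the mutated reference and build
fusion contigs from it; (3) draw an expression profile, fragment
transcripts and simulate paired-end reads with substitution errors;
(4) lift every simulated alignment back to original-reference
coordinates, encode the truth in the read names, and write the dataset
directory (paired FASTQ + truth files + manifest).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from truthbench import fusions as fusion_mod
from truthbench import naming, reads, variants
from truthbench.fusions import DEFAULT_COLINEAR_THRESHOLD
from truthbench.genome import AnnotationSet, Genome, read_fasta, read_gtf, transcript_sequence

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    genome: str | Genome = ""
    gtf: str | AnnotationSet = ""
    vcf: str | None = None
    snv_rate: float = 0.0014
    ins_rate: float = 0.0001
    del_rate: float = 0.0001
    max_indel_len: int = 15
    vcf_ratio: float = 0.95
    n_fusions: int = 0
    read_length: int = 101
    n_read_pairs: int = 10_000
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    error_rate: float = 0.001
    k: float = -0.7
    x0: float = 15_000.0
    x1: float | None = None
    n_molecules: int = 1_000_000
    colinear_threshold: int = DEFAULT_COLINEAR_THRESHOLD
    seed: int = 42
    outdir: str = "dataset"

    def __post_init__(self):
        for rate in (self.snv_rate, self.ins_rate, self.del_rate, self.vcf_ratio):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_fusions < 0 or self.n_read_pairs < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class SimulationResult:
    mutated_genome: Genome
    coordinate_map: variants.CoordinateMap
    mutation_set: variants.MutationSet
    fusion_events: list
    truth_db: naming.TruthDB
    manifest: dict
    pairs_with_records: list = field(default_factory=list)


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_simulation(config: SimulationConfig) -> SimulationResult:
    rng = np.random.default_rng(config.seed)

    _stage("load inputs")
    genome = config.genome if isinstance(config.genome, Genome) else read_fasta(config.genome)
    annotations = config.gtf if isinstance(config.gtf, AnnotationSet) else read_gtf(config.gtf)

    _stage("mutation generation")
    random_muts = (
        variants.generate_random_snvs(genome, config.snv_rate, rng)
        + variants.generate_random_indels(genome, config.ins_rate, rng,
                                          config.max_indel_len, kind=variants.INS)
        + variants.generate_random_indels(genome, config.del_rate, rng,
                                          config.max_indel_len, kind=variants.DEL)
    )
    if config.vcf:
        vcf_muts, _ = variants.load_vcf_mutations(config.vcf, genome)
        muts = variants.mix_sources(
            vcf_muts, genome, total_target=len(random_muts),
            vcf_ratio=config.vcf_ratio, rng=rng,
            kind_weights=(config.snv_rate, config.ins_rate, config.del_rate),
            max_indel_len=config.max_indel_len)
    else:
        muts = random_muts
    mutation_set = variants.resolve_overlaps(muts)

    _stage("apply mutations")
    mutated, cmap = variants.apply_mutations(genome, mutation_set)
    shifted = variants.shift_annotations(annotations, cmap)

    _stage("fusion construction")
    events, contigs, fusion_annotations, registry = fusion_mod.generate_fusions(
        shifted, mutated, config.n_fusions, rng)

    _stage("read simulation")
    models = {t.transcript_id: t for t in shifted}
    models.update({t.transcript_id: t for t in fusion_annotations})
    combined = Genome(dict(mutated.chromosomes))
    for name, seq in contigs.chromosomes.items():
        combined.add(name, seq)
    sequences = {tid: transcript_sequence(combined, m) for tid, m in models.items()}
    lengths = {tid: len(s) for tid, s in sequences.items()}

    protocol = reads.SimulationProtocol(
        read_length=config.read_length, n_read_pairs=config.n_read_pairs,
        fragment_mean=config.fragment_mean, fragment_sd=config.fragment_sd,
        error_rate=config.error_rate)
    params = reads.ProfileParams(k=config.k, x0=config.x0, x1=config.x1,
                                 n_molecules=config.n_molecules)
    profile = reads.draw_expression_profile(sorted(models), params, rng)
    fragments = reads.fragment_and_sample(profile, lengths, protocol, rng)

    _stage("liftover and truth")
    pairs_with_records = []
    for read_id, frag in enumerate(fragments):
        pair = reads.make_read_pair(frag, sequences[frag.transcript_id], read_id, protocol, rng)
        reads.project_to_genome(pair, frag, models[frag.transcript_id], protocol.read_length)
        end1, end2 = naming.lift_pair(pair, cmap, registry, protocol.read_length)
        pairs_with_records.append((pair, end1, end2))
    truth_db = naming.build_truth_db(pairs_with_records, mutation_set,
                                     config.colinear_threshold)

    _stage("write outputs")
    # outdir is omitted: the manifest lives inside it, and recording it
    # would make otherwise identical runs differ byte-for-byte
    config_dict = {k: v for k, v in vars(config).items()
                   if k != "outdir" and isinstance(v, (int, float, str, bool, type(None)))}
    manifest = naming.write_outputs(
        pairs_with_records, truth_db, config.outdir, genome,
        protocol.read_length,
        manifest_extra={"seed": config.seed, "config": config_dict,
                        "n_fusion_contigs": len(events)})
    return SimulationResult(mutated, cmap, mutation_set, events, truth_db,
                            manifest, pairs_with_records)
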