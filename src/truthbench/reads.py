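"""Built-in paired-end RNA-seq read generator.

Expression follows a mixed power/exponential rank law: transcripts are
assigned distinct ranks ``x`` uniformly at random and weighted by
``x**k * exp(-x/x0 - (x/x1)**2)``; molecule counts are multinomial.
Fragments are sampled per molecule (transcript drawn proportionally to
its molecule count), with Normal(fragment_mean, fragment_sd) lengths
rounded and clamped to ``[read_length, transcript_length]`` and uniform
start positions.  Each fragment yields a read pair: end 1 is the first
``read_length`` bases, end 2 the reverse complement of the last
``read_length`` bases.  Sequencing errors are uniform per-base
substitutions with recorded positions.

Any generator producing :class:`SimulatedReadPair` records satisfies the
plug-in contract expected by the truth-encoding stage, so an external
read simulator can be substituted for this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from truthbench.genome import TranscriptModel, reverse_complement

_BASES = "ACGT"


@dataclass
class ProfileParams:
    """Rank-law parameters: exponent ``k``, exponential decay ``x0``,
    quadratic decay ``x1`` (both in rank units) and the total number of
    expressed molecules."""

    k: float = -0.7
    x0: float = 15_000.0
    x1: float | None = None   # defaults to x0**2
    n_molecules: int = 1_000_000

    def __post_init__(self):
        if self.x1 is None:
            self.x1 = self.x0 ** 2
        if self.n_molecules < 1 or self.x0 <= 0 or self.x1 <= 0:
            raise ValueError("invalid profile parameters")


@dataclass
class SimulationProtocol:
    read_length: int = 101
    n_read_pairs: int = 10_000
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    error_rate: float = 0.001

    def __post_init__(self):
        if self.read_length <= 0 or self.n_read_pairs < 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class Fragment:
    transcript_id: str
    start: int    # transcript coordinate, 0-based
    length: int


@dataclass
class SimulatedReadPair:
    """A read pair with its truth: sequences, per-end 0-based error
    offsets, and per-end exonic alignment blocks in mutated-genome or
    fusion-contig coordinates (ascending genomic order; ``strand`` is the
    alignment strand of that end)."""

    read_id: int
    transcript_id: str
    seq1: str
    seq2: str
    errors1: list[int] = field(default_factory=list)
    errors2: list[int] = field(default_factory=list)
    blocks1: list[tuple[str, int, int]] = field(default_factory=list)
    blocks2: list[tuple[str, int, int]] = field(default_factory=list)
    strand1: str = "+"
    strand2: str = "-"


def rank_weights(n: int, params: ProfileParams) -> np.ndarray:
    x = np.arange(1, n + 1, dtype=float)
    w = x ** params.k * np.exp(-x / params.x0 - (x / params.x1) ** 2)
    return w / w.sum()


def draw_expression_profile(transcript_ids: list[str], params: ProfileParams,
                            rng: np.random.Generator) -> dict[str, int]:
    """Assign ranks 1..T by random permutation and draw multinomial
    molecule counts over the normalized rank weights."""
    if not transcript_ids:
        raise ValueError("need at least one transcript")
    n = len(transcript_ids)
    weights = rank_weights(n, params)
    ranks = rng.permutation(n)  # transcript i gets rank ranks[i]+1
    counts = rng.multinomial(params.n_molecules, weights)
    return {tid: int(counts[ranks[i]]) for i, tid in enumerate(transcript_ids)}


def fragment_and_sample(profile: dict[str, int], transcript_lengths: dict[str, int],
                        protocol: SimulationProtocol, rng: np.random.Generator) -> list[Fragment]:
    """Draw ``n_read_pairs`` fragments.  Transcripts shorter than the read
    length (or with zero molecules) are excluded from sampling."""
    eligible = [tid for tid, c in profile.items()
                if c > 0 and transcript_lengths[tid] >= protocol.read_length]
    if not eligible:
        raise ValueError("no transcript is long and expressed enough to sample from")
    counts = np.array([profile[t] for t in eligible], dtype=float)
    idx = rng.choice(len(eligible), size=protocol.n_read_pairs, p=counts / counts.sum())
    raw_len = np.rint(rng.normal(protocol.fragment_mean, protocol.fragment_sd,
                                 size=protocol.n_read_pairs)).astype(int)
    fragments = []
    for i, ti in enumerate(idx):
        tid = eligible[int(ti)]
        tlen = transcript_lengths[tid]
        flen = int(min(max(raw_len[i], protocol.read_length), tlen))
        start = int(rng.integers(0, tlen - flen + 1))
        fragments.append(Fragment(tid, start, flen))
    return fragments


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    if error_rate <= 0:
        return seq, []
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size == 0:
        return seq, []
    arr = list(seq)
    positions = []
    for p in hits.tolist():
        orig = arr[p]
        choices = [b for b in _BASES if b != orig]
        arr[p] = choices[int(rng.integers(0, len(choices)))]
        positions.append(p)
    return "".join(arr), positions


def make_read_pair(fragment: Fragment, transcript_seq: str, read_id: int,
                   protocol: SimulationProtocol, rng: np.random.Generator) -> SimulatedReadPair:
    """Sequence both ends of a fragment with substitution errors."""
    L = protocol.read_length
    frag = transcript_seq[fragment.start:fragment.start + fragment.length]
    if len(frag) < L:
        raise ValueError("fragment shorter than read length")
    end1, err1 = _inject_errors(frag[:L], protocol.error_rate, rng)
    end2, err2 = _inject_errors(reverse_complement(frag[-L:]), protocol.error_rate, rng)
    return SimulatedReadPair(read_id, fragment.transcript_id, end1, end2, err1, err2)


def transcript_interval_to_blocks(model: TranscriptModel, t_start: int, t_end: int,
                                  ) -> list[tuple[str, int, int]]:
    """Project a transcript-coordinate interval through the exon chain
    into genomic blocks, returned in ascending genomic order."""
    if not 0 <= t_start < t_end <= model.length:
        raise ValueError(f"interval [{t_start},{t_end}) outside transcript of length {model.length}")
    blocks = []
    cum = 0
    for s, e in model.exons_in_transcription_order():
        exon_len = e - s
        lo = max(t_start, cum)
        hi = min(t_end, cum + exon_len)
        if lo < hi:
            if model.strand == "+":
                blocks.append((model.chrom, s + lo - cum, s + hi - cum))
            else:
                blocks.append((model.chrom, e - (hi - cum), e - (lo - cum)))
        cum += exon_len
    return sorted(blocks, key=lambda b: b[1])


def project_to_genome(pair: SimulatedReadPair, fragment: Fragment,
                      model: TranscriptModel, read_length: int) -> None:
    """Fill the pair's alignment blocks.  End 1 aligns on the transcript
    strand, end 2 on the opposite strand."""
    s = fragment.start
    pair.blocks1 = transcript_interval_to_blocks(model, s, s + read_length)
    pair.blocks2 = transcript_interval_to_blocks(
        model, s + fragment.length - read_length, s + fragment.length)
    pair.strand1 = model.strand
    pair.strand2 = "-" if model.strand == "+" else "+"
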