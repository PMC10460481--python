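"""Synthetic genomes and NGS read simulation.

The simulator produces everything the estimator's precision experiments
need without external data: random genomes (optionally with engineered
repeats to exercise the list-building filters), uniform fixed-length
single-end reads with a per-base error model, and contaminated read
mixtures.

Error model, per base and mutually exclusive: the base is replaced by
``N`` with probability ``p_N``, by a uniformly chosen *different* base
with probability ``p_sub``, and left unchanged otherwise.  Reads are drawn
uniformly over the genome, from either strand with probability 1/2.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kmer_core import codes_to_seq, seq_to_codes

__all__ = [
    "SimulationConfig",
    "Repeat",
    "ReadBatch",
    "generate_genome",
    "sanitize_reference",
    "simulate_reads",
    "compose_sample",
    "simulate_sample",
    "write_fasta",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Repeat:
    """Copy genome segment ``[start, end)`` onto position ``dest``.

    ``mismatches`` random positions of the copy are substituted, which
    creates pairs of k-mers at small Hamming distance — exactly what the
    isolation filter must reject.
    """

    start: int
    end: int
    dest: int
    mismatches: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults mirror the simulation protocol the estimator is evaluated
    under: 100 bp single-end reads, 1% N rate and 1% substitution rate per
    base, with contamination expressed as the fraction of sample
    nucleotides that come from the target genome.
    """

    depth: float
    read_length: int = 100
    p_N: float = 0.01
    p_sub: float = 0.01
    human_fraction: float = 1.0
    genome_length: int | None = None
    contaminant_lengths: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_N < 0 or self.p_sub < 0 or self.p_N + self.p_sub > 1:
            raise ValueError("need p_N, p_sub >= 0 and p_N + p_sub <= 1")
        if not 0 < self.human_fraction <= 1:
            raise ValueError("human_fraction must be in (0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class ReadBatch:
    """A set of equal-length reads as a (n_reads, read_length) code matrix."""

    seqs: np.ndarray  # uint8 base codes; 4 = N
    names: list[str]

    def __post_init__(self) -> None:
        self.seqs = np.atleast_2d(np.asarray(self.seqs, dtype=np.uint8))

    def __len__(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1] if len(self) else 0

    @property
    def n_nucl(self) -> int:
        return int(self.seqs.size)

    def sequences(self) -> list[str]:
        return [codes_to_seq(row) for row in self.seqs]

    @staticmethod
    def concat(batches: Sequence["ReadBatch"]) -> "ReadBatch":
        batches = [b for b in batches if len(b)]
        if not batches:
            return ReadBatch(np.zeros((0, 0), np.uint8), [])
        lengths = {b.read_length for b in batches}
        if len(lengths) != 1:
            raise ValueError("cannot concatenate batches of differing read length")
        seqs = np.concatenate([b.seqs for b in batches], axis=0)
        names = [n for b in batches for n in b.names]
        return ReadBatch(seqs, names)

    def shuffled(self, rng: np.random.Generator) -> "ReadBatch":
        order = rng.permutation(len(self))
        return ReadBatch(self.seqs[order], [self.names[i] for i in order])

    def to_fastq(self, path: str | Path) -> None:
        """Write as FASTQ (gzipped if the path ends in .gz); quality is constant."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        qual = "I" * self.read_length
        with opener(path, "wt") as fh:
            self.write_fastq_handle(fh, qual)

    def write_fastq_handle(self, fh: io.TextIOBase, qual: str | None = None) -> None:
        if qual is None:
            qual = "I" * self.read_length
        for name, row in zip(self.names, self.seqs):
            fh.write(f"@{name}\n{codes_to_seq(row)}\n+\n{qual}\n")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_genome(
    length: int,
    seed,
    repeat_spec: Sequence[Repeat] | None = None,
    name: str = "synthetic",
) -> tuple[str, str]:
    """Generate an i.i.d. uniform ACGT genome; returns ``(name, sequence)``.

    ``repeat_spec`` entries are applied in order, each overwriting the
    destination with a (possibly mismatched) copy of the source segment.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _as_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    for rep in repeat_spec or ():
        seg = codes[rep.start : rep.end].copy()
        if rep.mismatches:
            pos = rng.choice(seg.size, size=rep.mismatches, replace=False)
            seg[pos] = (seg[pos] + rng.integers(1, 4, size=rep.mismatches, dtype=np.uint8)) % 4
        codes[rep.dest : rep.dest + seg.size] = seg
    return name, codes_to_seq(codes)


def sanitize_reference(seq: str, rng) -> str:
    """Replace every non-ACGT character with a uniform random base."""
    rng = _as_rng(rng)
    codes = seq_to_codes(seq)
    bad = codes > 3
    n_bad = int(bad.sum())
    if n_bad:
        codes = codes.copy()
        codes[bad] = rng.integers(0, 4, size=n_bad, dtype=np.uint8)
    return codes_to_seq(codes)


def _genome_codes(genome) -> np.ndarray:
    if isinstance(genome, np.ndarray):
        return genome
    if isinstance(genome, tuple):  # (name, seq) pair from generate_genome
        genome = genome[1]
    return seq_to_codes(genome)


def n_reads_for_depth(depth: float, genome_length: int, read_length: int) -> int:
    """Read count achieving a target depth: round-half-even of D*L/len."""
    if depth <= 0:
        return 0
    return int(np.rint(depth * genome_length / read_length))


def simulate_reads(
    genome,
    depth: float,
    *,
    read_length: int = 100,
    p_N: float = 0.01,
    p_sub: float = 0.01,
    rng,
    label: str = "target",
    n_reads: int | None = None,
) -> ReadBatch:
    """Draw uniform single-end reads from ``genome`` with the error model.

    ``genome`` may be a sequence string, a ``(name, seq)`` pair, or a uint8
    code array (must be ACGT-only; run :func:`sanitize_reference` first if
    not).  ``n_reads`` overrides the depth-derived count when given.
    """
    rng = _as_rng(rng)
    codes = _genome_codes(genome)
    L = codes.size
    if L < read_length:
        raise ValueError(f"genome length {L} shorter than read length {read_length}")
    if codes.max(initial=0) > 3:
        raise ValueError("genome contains non-ACGT bases; sanitize_reference first")
    if n_reads is None:
        n_reads = n_reads_for_depth(depth, L, read_length)
    if n_reads <= 0:
        return ReadBatch(np.zeros((0, read_length), np.uint8), [])

    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads = codes[starts[:, None] + np.arange(read_length)]
    rev = strands == 1
    if rev.any():
        reads[rev] = 3 - reads[rev][:, ::-1]

    # per-base exclusive events from a single uniform draw
    u = rng.random(reads.shape)
    sub_mask = (u >= p_N) & (u < p_N + p_sub)
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()), dtype=np.uint8)
        reads[sub_mask] = (reads[sub_mask] + shift) % 4
    reads[u < p_N] = 4  # N

    names = [
        f"{label}:{s}:{'-' if r else '+'}:{i}"
        for i, (s, r) in enumerate(zip(starts, strands))
    ]
    return ReadBatch(reads, names)


def compose_sample(
    target_reads: ReadBatch,
    contaminant_genomes: Sequence,
    human_fraction: float,
    *,
    read_length: int = 100,
    p_N: float = 0.01,
    p_sub: float = 0.01,
    rng,
) -> ReadBatch:
    """Mix target reads with contaminant reads at a given target fraction.

    Total contaminant nucleotides are ``target_nucl * (1-f)/f`` for
    ``f = human_fraction``, split equally (by nucleotides) among the
    contaminant genomes, each simulated with the same read/error model.
    The combined reads are shuffled deterministically under ``rng``.
    """
    if not 0 < human_fraction <= 1:
        raise ValueError("human_fraction must be in (0, 1]")
    rng = _as_rng(rng)
    if human_fraction == 1.0:
        if contaminant_genomes:
            logger.info("human_fraction=1: ignoring %d contaminant genomes", len(contaminant_genomes))
        return target_reads.shuffled(rng)
    total_cont = target_reads.n_nucl * (1 - human_fraction) / human_fraction
    per_genome = total_cont / len(contaminant_genomes)
    batches = [target_reads]
    for i, genome in enumerate(contaminant_genomes):
        codes = _genome_codes(genome)
        n = int(np.rint(per_genome / read_length))
        batches.append(
            simulate_reads(
                codes, 0.0, read_length=read_length, p_N=p_N, p_sub=p_sub,
                rng=rng, label=f"contaminant-{i}", n_reads=n,
            )
        )
    return ReadBatch.concat(batches).shuffled(rng)


def simulate_sample(config: SimulationConfig) -> tuple[tuple[str, str], ReadBatch]:
    """End-to-end convenience: genome + contaminants + mixed sample.

    Returns the target genome record and the final shuffled read batch.
    All randomness fans out deterministically from ``config.seed``.
    """
    if config.genome_length is None:
        raise ValueError("simulate_sample needs config.genome_length")
    ss = np.random.SeedSequence(config.seed)
    g_ss, c_ss, r_ss, m_ss = ss.spawn(4)
    genome = generate_genome(config.genome_length, np.random.default_rng(g_ss), name="target")
    contaminants = [
        generate_genome(L, np.random.default_rng(s), name=f"contaminant-{i}")
        for i, (L, s) in enumerate(zip(config.contaminant_lengths,
                                       c_ss.spawn(max(1, len(config.contaminant_lengths)))))
    ]
    target = simulate_reads(
        genome, config.depth, read_length=config.read_length,
        p_N=config.p_N, p_sub=config.p_sub, rng=np.random.default_rng(r_ss),
    )
    sample = compose_sample(
        target, contaminants, config.human_fraction,
        read_length=config.read_length, p_N=config.p_N, p_sub=config.p_sub,
        rng=np.random.default_rng(m_ss),
    )
    return genome, sample


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write ``(name, seq)`` records as (optionally gzipped) FASTA."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
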