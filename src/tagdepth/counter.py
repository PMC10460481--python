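"""Counting database k-mers in sequencing reads.

Every ACGT-only window of every read is canonicalized and looked up
against the union of tag and error k-mer codes; hits increment per-k-mer
counts.  Alongside the counts the sample tallies needed by the estimator
are accumulated: ``n_nucl`` (every base, N included), ``n_kmer`` (valid
k-windows) and ``n_reads``.

Quality strings are ignored.  FASTQ is parsed four lines per record, with
tolerance for a missing final newline; plain and gzipped files are
accepted, and paired-end data is simply two files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .kmer_core import canonical_scan, seq_to_codes
from .list_builder import KmerDatabase
from .simulator import ReadBatch

__all__ = [
    "CountResult",
    "FastqFormatError",
    "count_sample",
    "count_reads",
    "merge_counts",
    "write_counts",
    "read_counts",
]

_CHUNK_BASES = 4_000_000


class FastqFormatError(ValueError):
    """Malformed FASTQ record (truncation or seq/qual length mismatch)."""


@dataclass
class CountResult:
    """Observed k-mer counts plus sample tallies for one or more files."""

    tag_counts: np.ndarray  # int64, aligned with db.tags
    err_counts: np.ndarray  # int64, aligned with db.errors
    n_nucl: int = 0
    n_kmer: int = 0
    n_reads: int = 0
    source_files: list[str] = field(default_factory=list)
    db_fingerprint: tuple = ()

    def copy(self) -> "CountResult":
        return CountResult(
            self.tag_counts.copy(), self.err_counts.copy(),
            self.n_nucl, self.n_kmer, self.n_reads,
            list(self.source_files), self.db_fingerprint,
        )


class _DbLookup:
    """Sorted union of tag and error codes with back-references."""

    def __init__(self, db: KmerDatabase):
        tw, ew = db.tag_words, db.err_words
        words = np.concatenate([tw, ew])
        kind = np.concatenate([np.zeros(tw.size, np.int8), np.ones(ew.size, np.int8)])
        idx = np.concatenate([np.arange(tw.size), np.arange(ew.size)])
        order = np.argsort(words, kind="stable")
        self.words = words[order]
        self.kind = kind[order]
        self.idx = idx[order]
        self.n_tag = tw.size
        self.n_err = ew.size

    def add_hits(self, canon: np.ndarray, tag_counts: np.ndarray, err_counts: np.ndarray) -> None:
        if canon.size == 0 or self.words.size == 0:
            return
        pos = np.minimum(np.searchsorted(self.words, canon), self.words.size - 1)
        hit = self.words[pos] == canon
        sel = pos[hit]
        kinds = self.kind[sel]
        idxs = self.idx[sel]
        t = idxs[kinds == 0]
        e = idxs[kinds == 1]
        if t.size:
            tag_counts += np.bincount(t, minlength=self.n_tag)
        if e.size:
            err_counts += np.bincount(e, minlength=self.n_err)


def _empty_result(db: KmerDatabase) -> CountResult:
    return CountResult(
        tag_counts=np.zeros(len(db.tags), np.int64),
        err_counts=np.zeros(len(db.errors), np.int64),
        db_fingerprint=db.fingerprint(),
    )


def _iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file, validating record structure."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rec = 0
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.startswith("@"):
                raise FastqFormatError(f"{path}: record {rec}: header does not start with '@'")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual and not plus:
                raise FastqFormatError(f"{path}: record {rec}: truncated record")
            seq, qual = seq.rstrip("\n"), qual.rstrip("\n")
            if not plus.startswith("+"):
                raise FastqFormatError(f"{path}: record {rec}: missing '+' separator line")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: record {rec}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            yield seq
            rec += 1


def _count_chunks(
    read_iter: Iterable[np.ndarray], k: int, lookup: _DbLookup, result: CountResult
) -> None:
    """Consume per-read code arrays in chunks joined by separator bases."""
    sep = np.array([4], np.uint8)  # breaks windows across read boundaries
    buf: list[np.ndarray] = []
    buf_bases = 0

    def flush() -> None:
        nonlocal buf, buf_bases
        if not buf:
            return
        parts: list[np.ndarray] = []
        for i, r in enumerate(buf):
            if i:
                parts.append(sep)
            parts.append(r)
        block = np.concatenate(parts)
        _, canon, tally = canonical_scan(block, k)
        result.n_kmer += tally.n_kmer
        lookup.add_hits(canon, result.tag_counts, result.err_counts)
        buf, buf_bases = [], 0

    for codes in read_iter:
        result.n_nucl += int(codes.size)
        result.n_reads += 1
        buf.append(codes)
        buf_bases += codes.size
        if buf_bases >= _CHUNK_BASES:
            flush()
    flush()


def count_sample(fastq_paths: Sequence[str | Path], db: KmerDatabase) -> CountResult:
    """Count database k-mers over one or more FASTQ files."""
    if not fastq_paths:
        raise ValueError("no FASTQ files given")
    if not db.tags and not db.errors:
        raise ValueError("empty k-mer database")
    result = _empty_result(db)
    lookup = _DbLookup(db)
    for path in fastq_paths:
        result.source_files.append(str(path))
        _count_chunks(
            (seq_to_codes(s) for s in _iter_fastq(path)), db.k, lookup, result
        )
    return result


def count_reads(reads, db: KmerDatabase) -> CountResult:
    """In-memory counterpart of :func:`count_sample`.

    ``reads`` is a :class:`~tagdepth.simulator.ReadBatch` or an iterable of
    sequence strings.
    """
    result = _empty_result(db)
    lookup = _DbLookup(db)
    result.source_files.append("<memory>")
    if isinstance(reads, ReadBatch):
        if len(reads):
            # matrix layout: separator column glued on, scan row-major
            n, L = reads.seqs.shape
            if L >= db.k:
                block = np.concatenate(
                    [reads.seqs, np.full((n, 1), 4, np.uint8)], axis=1
                ).ravel()
                _, canon, tally = canonical_scan(block, db.k)
                result.n_kmer += tally.n_kmer
                lookup.add_hits(canon, result.tag_counts, result.err_counts)
            result.n_nucl += reads.n_nucl
            result.n_reads += len(reads)
    else:
        _count_chunks((seq_to_codes(s) for s in reads), db.k, lookup, result)
    return result


def merge_counts(a: CountResult, b: CountResult) -> CountResult:
    """Field-wise sum of two count results produced against the same database."""
    if a.db_fingerprint != b.db_fingerprint:
        raise ValueError("cannot merge counts produced against different databases")
    return CountResult(
        tag_counts=a.tag_counts + b.tag_counts,
        err_counts=a.err_counts + b.err_counts,
        n_nucl=a.n_nucl + b.n_nucl,
        n_kmer=a.n_kmer + b.n_kmer,
        n_reads=a.n_reads + b.n_reads,
        source_files=a.source_files + b.source_files,
        db_fingerprint=a.db_fingerprint,
    )


def write_counts(result: CountResult, db: KmerDatabase, path: str | Path) -> None:
    """Counts TSV: a stats header block, then kmer/type/count rows."""
    with open(path, "wt") as fh:
        fh.write(f"#n_nucl={result.n_nucl}\n")
        fh.write(f"#n_kmer={result.n_kmer}\n")
        fh.write(f"#n_reads={result.n_reads}\n")
        for t, c in zip(db.tags, result.tag_counts):
            fh.write(f"{t.code.decode()}\ttag\t{int(c)}\n")
        for e, c in zip(db.errors, result.err_counts):
            fh.write(f"{e.code.decode()}\terr\t{int(c)}\n")


def read_counts(path: str | Path, db: KmerDatabase) -> CountResult:
    """Parse a counts TSV written by :func:`write_counts` against ``db``."""
    result = _empty_result(db)
    tag_pos = {t.code.decode(): i for i, t in enumerate(db.tags)}
    err_pos = {e.code.decode(): i for i, e in enumerate(db.errors)}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key in ("n_nucl", "n_kmer", "n_reads"):
                    setattr(result, key, int(val))
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 fields, got {len(fields)}")
            kmer, typ, cnt = fields
            if typ == "tag":
                result.tag_counts[tag_pos[kmer]] = int(cnt)
            elif typ == "err":
                result.err_counts[err_pos[kmer]] = int(cnt)
            else:
                raise ValueError(f"{path}:{ln}: unknown row type {typ!r}")
    result.source_files = [str(path)]
    return result
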