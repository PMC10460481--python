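"""Tag and error k-mer list construction.

A *tag* k-mer is a genomic k-mer that survives three filters:

1. **uniqueness / universality** — present exactly once in the primary
   assembly and exactly once in every additional assembly supplied;
2. **Hamming isolation** — no other genomic k-mer of the primary assembly
   lies within Hamming distance 1 (tested by enumerating the 3k
   single-mismatch neighbors against the genome index, never all-pairs);
3. **window spacing** — the genome is partitioned into 100 bp windows and
   only one k-mer (the leftmost candidate) in every third window is kept,
   guaranteeing >= 200 bp between any two tags so one read can touch at
   most one tag.

An *error* k-mer is a random single-mismatch variant of a tag k-mer that
is absent from the genome and not reachable by one substitution from any
genomic k-mer other than its parent; its counts measure how often
sequencing errors convert a true k-mer into a specific wrong one.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kmer_core import (
    KmerCode,
    canonical_scan,
    canonicalize_words,
    revcomp_words,
    seq_to_codes,
)

__all__ = [
    "GenomeIndex",
    "CandidateSet",
    "TagKmer",
    "ErrorKmer",
    "KmerDatabase",
    "DatabaseFormatError",
    "build_genome_index",
    "select_unique_universal",
    "filter_hamming_isolated",
    "filter_spacing",
    "generate_error_kmers",
    "build_database",
    "write_database",
    "read_database",
]

logger = logging.getLogger(__name__)

DB_MAGIC = "#tagdepth-db v1"


def _sorted_unique(a: np.ndarray) -> np.ndarray:
    # plain sort + dedupe; np.unique is avoided on hot paths
    s = np.sort(a)
    if s.size == 0:
        return s
    keep = np.ones(s.size, bool)
    keep[1:] = s[1:] != s[:-1]
    return s[keep]

WINDOW_1MB = 1_000_000


class DatabaseFormatError(ValueError):
    """Malformed or inconsistent k-mer database file."""


# ---------------------------------------------------------------------------
# genome index

@dataclass
class GenomeIndex:
    """Canonical k-mer census of one assembly.

    ``codes`` is sorted and unique; ``counts[i]`` is how many genomic
    windows (canonically, i.e. each window counted once) carry
    ``codes[i]``.  ``first_record``/``first_pos`` give the locus of the
    first occurrence, which for count-1 k-mers is *the* locus.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    record_names: list[str]
    record_lengths: dict[str, int]
    first_record: np.ndarray
    first_pos: np.ndarray

    @property
    def total_windows(self) -> int:
        return int(self.counts.sum())

    def count_of(self, code: KmerCode) -> int:
        if code.k != self.k:
            return 0
        i = int(np.searchsorted(self.codes, np.uint64(code.word)))
        if i < self.codes.size and int(self.codes[i]) == code.word:
            return int(self.counts[i])
        return 0

    def contains_words(self, words: np.ndarray) -> np.ndarray:
        """Vectorized membership of canonical packed words."""
        pos = np.searchsorted(self.codes, words)
        pos_c = np.minimum(pos, max(self.codes.size - 1, 0))
        if self.codes.size == 0:
            return np.zeros(words.shape, bool)
        return self.codes[pos_c] == words

    def as_dict(self) -> dict[KmerCode, int]:
        """Counts as a plain mapping (small genomes / tests only)."""
        return {
            KmerCode(int(w), self.k): int(c)
            for w, c in zip(self.codes, self.counts)
        }


def _iter_fasta(path: str | Path):
    """Yield (name, sequence) from a plain or gzipped FASTA file."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def build_genome_index(source, k: int) -> GenomeIndex:
    """Census all canonical k-mers of an assembly.

    ``source`` is a FASTA path (plain or .gz), a ``(name, seq)`` pair, or a
    sequence of such pairs.  Raises on an empty or unreadable input.
    """
    if isinstance(source, (str, Path)):
        records = list(_iter_fasta(source))
    elif isinstance(source, tuple) and len(source) == 2 and isinstance(source[0], str):
        records = [source]
    else:
        records = list(source)
    if not records:
        raise DatabaseFormatError("no FASTA records found (empty input)")

    all_codes: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    all_rec: list[np.ndarray] = []
    record_names: list[str] = []
    record_lengths: dict[str, int] = {}
    for rec_id, (name, seq) in enumerate(records):
        record_names.append(name)
        record_lengths[name] = len(seq)
        positions, canon, _ = canonical_scan(seq_to_codes(seq), k)
        all_codes.append(canon)
        all_pos.append(positions)
        all_rec.append(np.full(canon.size, rec_id, np.int32))

    codes = np.concatenate(all_codes) if all_codes else np.zeros(0, np.uint64)
    pos = np.concatenate(all_pos)
    rec = np.concatenate(all_rec)
    order = np.argsort(codes, kind="stable")  # stable: ties keep scan order
    sc = codes[order]
    lead = np.ones(sc.size, bool)
    if sc.size:
        lead[1:] = sc[1:] != sc[:-1]
    starts = np.nonzero(lead)[0]
    counts = np.diff(np.append(starts, sc.size)).astype(np.int64)
    first_idx = order[starts]
    return GenomeIndex(
        k=k,
        codes=sc[starts],
        counts=counts,
        record_names=record_names,
        record_lengths=record_lengths,
        first_record=rec[first_idx],
        first_pos=pos[first_idx],
    )


# ---------------------------------------------------------------------------
# candidate selection

@dataclass
class CandidateSet:
    """Unique-k-mer candidates with their primary-genome locus (array form)."""

    k: int
    codes: np.ndarray  # uint64, canonical
    record_ids: np.ndarray  # int32 into record_names
    positions: np.ndarray  # int64, 0-based leftmost
    record_names: list[str]

    def __len__(self) -> int:
        return int(self.codes.size)

    def to_tuples(self) -> list[tuple[KmerCode, str, int]]:
        return [
            (KmerCode(int(w), self.k), self.record_names[int(r)], int(p))
            for w, r, p in zip(self.codes, self.record_ids, self.positions)
        ]


def select_unique_universal(primary: GenomeIndex, others: Sequence[GenomeIndex]) -> CandidateSet:
    """K-mers with count 1 in the primary and in every other assembly."""
    for o in others:
        if o.k != primary.k:
            raise ValueError(f"k mismatch between indexes: {o.k} != {primary.k}")
    keep = primary.counts == 1
    for o in others:
        pos = np.searchsorted(o.codes, primary.codes)
        pos_c = np.minimum(pos, max(o.codes.size - 1, 0))
        if o.codes.size == 0:
            keep &= False
        else:
            present_once = (o.codes[pos_c] == primary.codes) & (o.counts[pos_c] == 1)
            keep &= present_once
    return CandidateSet(
        k=primary.k,
        codes=primary.codes[keep],
        record_ids=primary.first_record[keep],
        positions=primary.first_pos[keep],
        record_names=list(primary.record_names),
    )


def _present_values(index: GenomeIndex, words: np.ndarray) -> np.ndarray:
    """Distinct values of ``words`` that occur in the index (sort-friendly)."""
    vs = _sorted_unique(words)
    if vs.size == 0 or index.codes.size == 0:
        return np.zeros(0, np.uint64)
    pos = np.searchsorted(index.codes, vs)
    pos_c = np.minimum(pos, index.codes.size - 1)
    return vs[index.codes[pos_c] == vs]


def _mutate_words(words: np.ndarray, k: int, pos: int, delta) -> np.ndarray:
    """Substitute position ``pos`` (0 = leftmost) by orig+delta mod 4."""
    shift = np.uint64(2 * (k - 1 - pos))
    three = np.uint64(3)
    orig = (words >> shift) & three
    new = (orig + np.uint64(delta) if np.isscalar(delta) else orig + delta.astype(np.uint64)) & three
    return (words & ~(three << shift)) | (new << shift)


def _mark_distance1_kmers(index: GenomeIndex) -> np.ndarray:
    """Boolean mark per index code: some *other* genomic k-mer lies within
    strand-aware Hamming distance 1.

    Exact detection by position masking: two k-mers are at distance <= 1 in
    some orientation pair iff, for some position p, their words (one of
    them possibly reverse-complemented) agree everywhere outside p.  For
    each p the distinct genome words and their reverse complements are
    masked at p and sorted; duplicated masked values expose the colliding
    pairs.  A value shared only by the two orientations of one and the
    same k-mer (a near-palindrome one substitution from its own reverse
    complement) is not a pair of distinct genomic k-mers and is ignored.
    """
    U = index.codes  # sorted, unique, canonical
    k = index.k
    n = U.size
    marked = np.zeros(n, bool)
    if n == 0:
        return marked
    RU = revcomp_words(U, k)
    three = np.uint64(3)
    for pos in range(k):
        mask = ~(three << np.uint64(2 * (k - 1 - pos)))
        mu = U & mask
        mr = RU & mask
        s = np.sort(np.concatenate([mu, mr]))
        dup_mask = s[1:] == s[:-1]
        if not dup_mask.any():
            continue
        values = _sorted_unique(s[1:][dup_mask])
        hit_u = _in_sorted(values, mu)
        hit_r = _in_sorted(values, mr)
        ids = np.concatenate([np.nonzero(hit_u)[0], np.nonzero(hit_r)[0]])
        vals = np.concatenate([mu[hit_u], mr[hit_r]])
        order = np.argsort(vals, kind="stable")
        vals, ids = vals[order], ids[order]
        start = 0
        m = vals.size
        for i in range(1, m + 1):
            if i == m or vals[i] != vals[start]:
                grp = ids[start:i]
                if np.unique(grp).size >= 2:  # at least two distinct k-mers
                    marked[grp] = True
                start = i
    return marked


def filter_hamming_isolated(candidates: CandidateSet, primary: GenomeIndex) -> CandidateSet:
    """Drop candidates with another genomic k-mer at Hamming distance 1.

    Distance is strand-aware (canonical convention); a candidate whose own
    reverse complement is one substitution away is *not* removed — that is
    the same genomic locus, not another k-mer.
    """
    marked = _mark_distance1_kmers(primary)
    idx = np.searchsorted(primary.codes, candidates.codes)
    removed = marked[np.minimum(idx, max(primary.codes.size - 1, 0))]
    keep = ~removed
    return CandidateSet(
        k=candidates.k,
        codes=candidates.codes[keep],
        record_ids=candidates.record_ids[keep],
        positions=candidates.positions[keep],
        record_names=candidates.record_names,
    )


# ---------------------------------------------------------------------------
# spacing and the final tag list

@dataclass(frozen=True)
class TagKmer:
    """A selected tag k-mer with its unique locus annotation."""

    code: KmerCode
    record: str
    position: int

    @property
    def window_1mb(self) -> int:
        return self.position // WINDOW_1MB


@dataclass(frozen=True)
class ErrorKmer:
    """A single-mismatch variant of a tag k-mer, absent from the genome.

    ``mm_position``/``mm_base`` are expressed on the parent's canonical
    orientation.
    """

    code: KmerCode
    parent: TagKmer
    mm_position: int
    mm_base: str


def filter_spacing(
    candidates: CandidateSet, window_len: int = 100, keep_every: int = 3
) -> list[TagKmer]:
    """Keep the leftmost candidate of every ``keep_every``-th window.

    Records are partitioned into consecutive ``window_len`` bp windows
    indexed from 0 (restarting at each record); only windows with index
    divisible by ``keep_every`` contribute, and each contributes its
    smallest-position candidate.  Output is sorted by (record, position).
    """
    if len(candidates) == 0:
        return []
    win = candidates.positions // window_len
    eligible = (win % keep_every) == 0
    rec = candidates.record_ids[eligible]
    posn = candidates.positions[eligible]
    codes = candidates.codes[eligible]
    w = win[eligible]

    order = np.lexsort((posn, w, rec))
    rec, posn, codes, w = rec[order], posn[order], codes[order], w[order]
    group = np.ones(rec.size, bool)
    group[1:] = (rec[1:] != rec[:-1]) | (w[1:] != w[:-1])
    return [
        TagKmer(KmerCode(int(c), candidates.k), candidates.record_names[int(r)], int(p))
        for c, r, p in zip(codes[group], rec[group], posn[group])
    ]


# ---------------------------------------------------------------------------
# error k-mer generation

def generate_error_kmers(
    tags: Sequence[TagKmer],
    primary: GenomeIndex,
    n_variants: int = 4,
    rng_seed=0,
) -> list[ErrorKmer]:
    """Random single-mismatch variants of each tag, filtered for isolation.

    Per tag, up to ``n_variants`` distinct variants are drawn uniformly
    without replacement from the 3k possibilities (a random order over all
    3k is fixed up front, and candidates are taken in that order until
    enough are accepted).  A variant is kept only if it is absent from the
    genome, no genomic k-mer other than its parent lies within Hamming
    distance 1, and it collides with no tag code and no previously
    accepted error code.  Deterministic for a fixed ``rng_seed``.
    """
    if not tags:
        return []
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    k = primary.k
    n_tags = len(tags)
    parent_words = np.array([t.code.word for t in tags], np.uint64)
    tag_set = np.sort(parent_words)

    # random try-order over the 3k (position, delta) possibilities per tag
    order = rng.permuted(np.tile(np.arange(3 * k), (n_tags, 1)), axis=1)

    accepted_codes: list[np.ndarray] = []
    accepted_parent: list[np.ndarray] = []
    accepted_pos: list[np.ndarray] = []
    accepted_base: list[np.ndarray] = []
    n_accepted = np.zeros(n_tags, np.int32)
    err_sorted = np.zeros(0, np.uint64)

    for round_i in range(3 * k):
        active = np.nonzero(n_accepted < n_variants)[0]
        if active.size == 0:
            break
        choice = order[active, round_i]
        pos = choice // 3
        delta = (choice % 3 + 1).astype(np.uint64)
        pw = parent_words[active]
        raw = np.zeros(active.size, np.uint64)
        # mutate per distinct position (few distinct values per round)
        for p in np.unique(pos):
            m = pos == p
            raw[m] = _mutate_words(pw[m], k, int(p), delta[m])
        var = canonicalize_words(raw, k)

        ok = ~primary.contains_words(var)
        # no genomic k-mer other than the parent within distance 1
        for npos in range(k):
            for ndelta in (1, 2, 3):
                if not ok.any():
                    break
                nb = canonicalize_words(_mutate_words(var, k, npos, ndelta), k)
                present = _present_values(primary, nb[ok])
                if present.size:
                    hit = np.isin(nb, present) & (nb != canonicalize_words(pw, k))
                    ok &= ~hit
        # collisions with tags and previously accepted errors
        ok &= ~_in_sorted(tag_set, var)
        if err_sorted.size:
            ok &= ~_in_sorted(err_sorted, var)
        # collisions within this round: keep the first (smallest tag index)
        if ok.any():
            vals = var[ok]
            idx = np.nonzero(ok)[0]
            first = np.zeros(vals.size, bool)
            o = np.lexsort((idx, vals))
            sv = vals[o]
            lead = np.ones(sv.size, bool)
            lead[1:] = sv[1:] != sv[:-1]
            first[o] = lead
            ok[idx[~first]] = False

        if ok.any():
            sel = np.nonzero(ok)[0]
            tag_idx = active[sel]
            accepted_codes.append(var[sel])
            accepted_parent.append(tag_idx)
            accepted_pos.append(pos[sel])
            base = (((pw[sel] >> (np.uint64(2) * np.uint64(k - 1) - np.uint64(2) * pos[sel].astype(np.uint64))) & np.uint64(3)) + delta[sel]) & np.uint64(3)
            accepted_base.append(base)
            n_accepted[tag_idx] += 1
            err_sorted = np.sort(np.concatenate([err_sorted, var[sel]]))

    deficit = int(np.sum(n_variants - n_accepted))
    if deficit:
        logger.info("error-kmer generation: %d variants short of %d per tag", deficit, n_variants)

    out: list[ErrorKmer] = []
    if accepted_codes:
        codes = np.concatenate(accepted_codes)
        parents = np.concatenate(accepted_parent)
        mposs = np.concatenate(accepted_pos)
        bases = np.concatenate(accepted_base)
        ord2 = np.lexsort((mposs, parents))
        for i in ord2:
            out.append(
                ErrorKmer(
                    code=KmerCode(int(codes[i]), k),
                    parent=tags[int(parents[i])],
                    mm_position=int(mposs[i]),
                    mm_base="ACGT"[int(bases[i])],
                )
            )
    return out


def _in_sorted(sorted_arr: np.ndarray, values: np.ndarray) -> np.ndarray:
    if sorted_arr.size == 0:
        return np.zeros(values.shape, bool)
    pos = np.minimum(np.searchsorted(sorted_arr, values), sorted_arr.size - 1)
    return sorted_arr[pos] == values


# ---------------------------------------------------------------------------
# database

@dataclass
class KmerDatabase:
    """The tag + error k-mer lists with annotations and provenance."""

    k: int
    tags: list[TagKmer]
    errors: list[ErrorKmer]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tag_words = {t.code.word for t in self.tags}
        err_words = {e.code.word for e in self.errors}
        if len(tag_words) != len(self.tags):
            raise DatabaseFormatError("duplicate tag k-mer codes")
        if len(err_words) != len(self.errors):
            raise DatabaseFormatError("duplicate error k-mer codes")
        if tag_words & err_words:
            raise DatabaseFormatError("tag and error k-mer sets overlap")
        for t in self.tags:
            if t.code.k != self.k:
                raise DatabaseFormatError("tag k-mer length differs from database k")
        for e in self.errors:
            if e.code.k != self.k:
                raise DatabaseFormatError("error k-mer length differs from database k")

    @property
    def tag_words(self) -> np.ndarray:
        return np.array([t.code.word for t in self.tags], np.uint64)

    @property
    def err_words(self) -> np.ndarray:
        return np.array([e.code.word for e in self.errors], np.uint64)

    def fingerprint(self) -> tuple:
        """Cheap identity for checking that counts match this database."""
        tw, ew = self.tag_words, self.err_words
        return (self.k, len(self.tags), len(self.errors),
                int(tw.sum() % (1 << 61)) if tw.size else 0,
                int(ew.sum() % (1 << 61)) if ew.size else 0)


def build_database(
    sources: Sequence,
    k: int = 25,
    window_len: int = 100,
    keep_every: int = 3,
    n_variants: int = 4,
    seed=0,
    hamming_isolation: bool = True,
) -> KmerDatabase:
    """Full list-building pipeline over one or more assemblies.

    The first source is the *primary* assembly: it supplies coordinates and
    is the reference for Hamming isolation; additional sources only tighten
    the uniqueness filter.  Sources may be FASTA paths, ``(name, seq)``
    pairs, or prebuilt :class:`GenomeIndex` objects.
    """
    indexes = [
        s if isinstance(s, GenomeIndex) else build_genome_index(s, k) for s in sources
    ]
    primary, others = indexes[0], indexes[1:]
    candidates = select_unique_universal(primary, others)
    n_unique = len(candidates)
    if hamming_isolation:
        candidates = filter_hamming_isolated(candidates, primary)
    n_isolated = len(candidates)
    tags = filter_spacing(candidates, window_len=window_len, keep_every=keep_every)
    errors = generate_error_kmers(tags, primary, n_variants=n_variants, rng_seed=seed)
    provenance = {
        "k": k,
        "sources": [list(ix.record_lengths) for ix in indexes],
        "window_len": window_len,
        "keep_every": keep_every,
        "n_variants": n_variants,
        "seed": seed if isinstance(seed, int) else None,
        "n_unique": n_unique,
        "n_isolated": n_isolated,
        "n_tags": len(tags),
        "n_errors": len(errors),
    }
    return KmerDatabase(k=k, tags=tags, errors=errors, provenance=provenance)


def write_database(db: KmerDatabase, path: str | Path) -> None:
    """Serialize as TSV: magic/header lines, then one row per k-mer."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(DB_MAGIC + "\n")
        fh.write(f"#k={db.k}\n")
        fh.write(f"#provenance={json.dumps(db.provenance, sort_keys=True)}\n")
        for t in db.tags:
            fh.write(
                f"{t.code.decode()}\ttag\t{t.record}\t{t.position}\t{t.window_1mb}\t.\t.\t.\n"
            )
        for e in db.errors:
            p = e.parent
            fh.write(
                f"{e.code.decode()}\terr\t{p.record}\t{p.position}\t{p.window_1mb}"
                f"\t{p.code.decode()}\t{e.mm_position}\t{e.mm_base}\n"
            )


def read_database(path: str | Path) -> KmerDatabase:
    """Parse a database TSV; validates structure and reports line numbers."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != DB_MAGIC:
        raise DatabaseFormatError(f"{path}: missing or unsupported magic line (expected {DB_MAGIC!r})")
    k = None
    provenance: dict = {}
    tags: list[TagKmer] = []
    tag_by_word: dict[int, TagKmer] = {}
    errors: list[ErrorKmer] = []
    pending_errors: list[tuple[int, list[str]]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#k="):
            k = int(line[3:])
            continue
        if line.startswith("#provenance="):
            provenance = json.loads(line[len("#provenance="):])
            continue
        if line.startswith("#"):
            continue
        if k is None:
            raise DatabaseFormatError(f"{path}:{ln}: k-mer row before #k= header")
        fields = line.split("\t")
        if len(fields) != 8:
            raise DatabaseFormatError(f"{path}:{ln}: expected 8 tab-separated fields, got {len(fields)}")
        kmer, typ, record, position, _win, parent, mm_pos, mm_base = fields
        if len(kmer) != k:
            raise DatabaseFormatError(f"{path}:{ln}: k-mer length {len(kmer)} != k={k}")
        try:
            code = KmerCode(_pack_strict(kmer), k)
        except ValueError as exc:
            raise DatabaseFormatError(f"{path}:{ln}: {exc}") from exc
        if typ == "tag":
            tag = TagKmer(code, record, int(position))
            if code.word in tag_by_word:
                raise DatabaseFormatError(f"{path}:{ln}: duplicate tag k-mer {kmer}")
            tag_by_word[code.word] = tag
            tags.append(tag)
        elif typ == "err":
            pending_errors.append((ln, [kmer, parent, mm_pos, mm_base]))
        else:
            raise DatabaseFormatError(f"{path}:{ln}: unknown row type {typ!r}")
    for ln, (kmer, parent, mm_pos, mm_base) in pending_errors:
        pword = _pack_strict(parent)
        if pword not in tag_by_word:
            raise DatabaseFormatError(f"{path}:{ln}: error k-mer parent {parent} not in tag list")
        errors.append(
            ErrorKmer(
                code=KmerCode(_pack_strict(kmer), k),
                parent=tag_by_word[pword],
                mm_position=int(mm_pos),
                mm_base=mm_base,
            )
        )
    try:
        return KmerDatabase(k=k, tags=tags, errors=errors, provenance=provenance)
    except DatabaseFormatError as exc:
        raise DatabaseFormatError(f"{path}: {exc}") from exc


def _pack_strict(seq: str) -> int:
    word = 0
    for ch in seq:
        idx = "ACGT".find(ch)
        if idx < 0:
            raise DatabaseFormatError(f"invalid k-mer character {ch!r}")
        word = (word << 2) | idx
    return word
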