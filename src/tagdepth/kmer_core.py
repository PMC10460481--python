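"""Canonical k-mer primitives.

K-mers are stored in a packed 2-bit-per-base form (A=0, C=1, G=2, T=3,
leftmost base most significant) and always in *canonical* orientation: the
lexicographically smaller (under A<C<G<T) of a word and its reverse
complement.  Canonical storage makes every downstream identity test —
list membership, read counting, mismatch-neighbor lookups — independent of
the strand a read happens to come from.

Two API levels live here:

* scalar objects (:class:`KmerCode`) and generators (:func:`scan_sequence`)
  for small inputs, tests and oracles;
* vectorized helpers over numpy arrays (``seq_to_codes``,
  ``canonical_scan``, ``revcomp_words``) that the genome indexer, the list
  builder and the read counter use on megabase-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "KmerCode",
    "ScanTally",
    "InvalidAlphabetError",
    "KmerLengthError",
    "encode_canonical",
    "hamming_distance",
    "min_strand_distance",
    "single_mismatch_neighbors",
    "scan_sequence",
    "seq_to_codes",
    "codes_to_seq",
    "canonical_scan",
    "revcomp_words",
]

BASES = "ACGT"
MAX_K = 32  # one 64-bit word

_BYTE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):  # soft-masked FASTA is common
    _BYTE_TO_CODE[_b] = _i

_CODE_TO_BYTE = np.frombuffer(b"ACGTN", dtype=np.uint8).copy()

# masks for 2-bit-group reversal inside a 64-bit word
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


class InvalidAlphabetError(ValueError):
    """Sequence contains a character outside A/C/G/T (after case folding)."""


class KmerLengthError(ValueError):
    """k outside 1..32, or operands of mismatched k."""


# ---------------------------------------------------------------------------
# byte-level sequence conversion

def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Map a sequence to uint8 base codes; non-ACGT characters become 4.

    Lowercase acgt is folded to uppercase.  The result is the common
    currency of all vectorized routines.
    """
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    raw = np.frombuffer(seq, dtype=np.uint8)
    return _BYTE_TO_CODE[raw]


def codes_to_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`seq_to_codes`; any invalid code renders as ``N``."""
    return _CODE_TO_BYTE[np.minimum(codes, 4)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# scalar k-mer object

@dataclass(frozen=True, order=True)
class KmerCode:
    """A fixed-length DNA word in canonical packed 2-bit form."""

    word: int
    k: int = field(compare=True)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise KmerLengthError(f"k={self.k} outside 1..{MAX_K}")
        if not 0 <= self.word < 4**self.k:
            raise ValueError(f"packed word {self.word} does not fit k={self.k}")

    def decode(self) -> str:
        w, k = self.word, self.k
        return "".join(BASES[(w >> (2 * (k - 1 - j))) & 3] for j in range(k))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.decode()


def _pack(seq: str) -> int:
    word = 0
    for ch in seq:
        code = _BYTE_TO_CODE[ord(ch)] if ord(ch) < 256 else 4
        if code > 3:
            raise InvalidAlphabetError(f"non-ACGT character {ch!r}")
        word = (word << 2) | int(code)
    return word


def _revcomp_word(word: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (word & 3))
        word >>= 2
    return rc


def encode_canonical(seq: str) -> KmerCode:
    """Pack ``seq`` and return the canonical (min of word, revcomp) code.

    Raises :class:`KmerLengthError` for k outside 1..32 and
    :class:`InvalidAlphabetError` for non-ACGT characters.
    """
    k = len(seq)
    if not 1 <= k <= MAX_K:
        raise KmerLengthError(f"sequence length {k} outside 1..{MAX_K}")
    fwd = _pack(seq)
    return KmerCode(min(fwd, _revcomp_word(fwd, k)), k)


def hamming_distance(a: KmerCode, b: KmerCode) -> int:
    """Number of differing positions between the stored (canonical) words."""
    if a.k != b.k:
        raise KmerLengthError(f"k mismatch: {a.k} != {b.k}")
    x = a.word ^ b.word
    # collapse each 2-bit base field to one indicator bit, then popcount
    y = (x | (x >> 1)) & int("01" * a.k, 2)
    return y.bit_count()


def min_strand_distance(a: KmerCode, b: KmerCode) -> int:
    """Hamming distance minimized over the two orientations of ``a``.

    This is the distance notion under which canonical-form identities such
    as "an error k-mer is one substitution away from its parent" hold.
    """
    if a.k != b.k:
        raise KmerLengthError(f"k mismatch: {a.k} != {b.k}")
    alt = KmerCode(_revcomp_word(a.word, a.k), a.k)
    return min(hamming_distance(a, b), hamming_distance(alt, b))


def single_mismatch_neighbors(x: KmerCode, canonical: bool = True) -> set[KmerCode]:
    """All words at Hamming distance 1 from the decoded word of ``x``.

    The raw enumeration has exactly ``3k`` words; with ``canonical=True``
    (default) each is returned in canonical form, which may collapse the
    set below ``3k``.
    """
    out: set[KmerCode] = set()
    k = x.k
    for pos in range(k):
        shift = 2 * (k - 1 - pos)
        orig = (x.word >> shift) & 3
        for delta in (1, 2, 3):
            new = (orig + delta) & 3
            word = (x.word & ~(3 << shift)) | (new << shift)
            if canonical:
                word = min(word, _revcomp_word(word, k))
            out.add(KmerCode(word, k))
    return out


# ---------------------------------------------------------------------------
# sequence scanning

@dataclass
class ScanTally:
    """Bookkeeping of a scan: all bases consumed vs ACGT-only windows emitted.

    ``n_nucl`` counts every base including N; ``n_kmer`` counts only the
    k-length windows free of non-ACGT characters.  Their ratio is what
    corrects depth estimates for read-edge and N-induced window loss.
    """

    n_nucl: int = 0
    n_kmer: int = 0

    def __iadd__(self, other: "ScanTally") -> "ScanTally":
        self.n_nucl += other.n_nucl
        self.n_kmer += other.n_kmer
        return self


def scan_sequence(seq: str, k: int) -> tuple[list[tuple[int, KmerCode]], ScanTally]:
    """Scan ``seq`` with a sliding window of length ``k``.

    Returns the list of ``(0-based start, canonical code)`` pairs for every
    ACGT-only window, in left-to-right order, together with the tally.
    Windows overlapping any non-ACGT character are skipped but their bases
    still count in ``n_nucl``.  Intended for small inputs; large scans go
    through :func:`canonical_scan`.
    """
    if k < 1:
        raise KmerLengthError(f"k={k} must be >= 1")
    codes = seq_to_codes(seq)
    positions, canon, tally = canonical_scan(codes, k)
    out = [(int(p), KmerCode(int(w), k)) for p, w in zip(positions, canon)]
    return out, tally


# ---------------------------------------------------------------------------
# vectorized internals

def revcomp_words(words: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed uint64 words (vectorized, O(log) bit ops)."""
    x = ~words.astype(np.uint64)
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def packed_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward packed words for every window start, plus a validity mask.

    Words at invalid positions (windows touching a non-ACGT base) carry no
    meaning and must be filtered with the mask.
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.zeros(0, bool), np.zeros(0, np.uint64)
    fwd = np.zeros(m, np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | (codes[j : j + m] & np.uint8(3)).astype(np.uint64)
    bad = np.concatenate(([0], np.cumsum(codes > 3, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0
    return valid, fwd


def canonical_scan(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, ScanTally]:
    """Positions and canonical packed words of all valid windows, with tally."""
    if k < 1:
        raise KmerLengthError(f"k={k} must be >= 1")
    if k > MAX_K:
        raise KmerLengthError(f"k={k} exceeds {MAX_K}")
    valid, fwd = packed_windows(codes, k)
    tally = ScanTally(n_nucl=int(codes.size), n_kmer=int(valid.sum()))
    f = fwd[valid]
    canon = np.minimum(f, revcomp_words(f, k))
    positions = np.nonzero(valid)[0].astype(np.int64)
    return positions, canon, tally


def canonicalize_words(words: np.ndarray, k: int) -> np.ndarray:
    """Canonical form (min of word and reverse complement), vectorized."""
    return np.minimum(words.astype(np.uint64), revcomp_words(words, k))
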