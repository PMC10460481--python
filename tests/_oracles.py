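"""Independent brute-force oracles used by the tests.

Everything here is deliberately written with plain strings, dicts and
loops — no shared code with the package internals — so that agreement
between package and oracle is meaningful.
"""

from __future__ import annotations

import math

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canonical(s: str) -> str:
    rc = revcomp(s)
    return s if s <= rc else rc


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_windows(seq: str, k: int) -> list[tuple[int, str]]:
    """All ACGT-only k-windows (canonical string form) with positions."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            out.append((i, canonical(w)))
    return out


def genome_kmer_counts(records: list[tuple[str, str]], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, seq in records:
        for _, w in scan_windows(seq, k):
            counts[w] = counts.get(w, 0) + 1
    return counts


def min_strand_hamming(a: str, b: str) -> int:
    return min(hamming(a, b), hamming(revcomp(a), b))


def brute_force_tags(
    records: list[tuple[str, str]],
    k: int,
    others: list[list[tuple[str, str]]] | None = None,
    window_len: int = 100,
    keep_every: int = 3,
) -> list[tuple[str, str, int]]:
    """The whole tag pipeline by brute force: uniqueness by dictionary,
    isolation by all-pairs Hamming over both strands, spacing by direct
    window partition.  Returns (kmer, record, position) sorted."""
    counts = genome_kmer_counts(records, k)
    # locus of each unique k-mer
    locus: dict[str, tuple[str, int]] = {}
    all_windows: list[str] = []
    for name, seq in records:
        for pos, w in scan_windows(seq, k):
            all_windows.append(w)
            if counts[w] == 1:
                locus[w] = (name, pos)
    candidates = {w for w, c in counts.items() if c == 1}
    for other in others or []:
        oc = genome_kmer_counts(other, k)
        candidates = {w for w in candidates if oc.get(w) == 1}
    # all-pairs isolation: drop candidate if ANY other genomic k-mer is
    # within strand-aware Hamming distance 1
    survivors = set()
    for w in candidates:
        ok = True
        for v in counts:
            if v == w:
                continue
            if min_strand_hamming(w, v) <= 1:
                ok = False
                break
        survivors.add(w) if ok else None
    # spacing
    by_window: dict[tuple[str, int], list[tuple[int, str]]] = {}
    for w in survivors:
        name, pos = locus[w]
        win = pos // window_len
        if win % keep_every == 0:
            by_window.setdefault((name, win), []).append((pos, w))
    out = []
    for (name, _win), lst in by_window.items():
        pos, w = min(lst)
        out.append((w, name, pos))
    return sorted(out, key=lambda t: (t[1], t[2]))


def count_tag_hits(reads: list[str], kmers: list[str]) -> list[int]:
    """Per-k-mer occurrence counts by naive substring scanning of every
    read window against the k-mer and its reverse complement."""
    k = len(kmers[0])
    totals = [0] * len(kmers)
    targets = [(w, revcomp(w)) for w in kmers]
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            win = read[i : i + k]
            if any(c not in "ACGT" for c in win):
                continue
            for j, (fwd, rc) in enumerate(targets):
                if win == fwd or win == rc:
                    totals[j] += 1
    return totals


def poisson_tail(c: int, lam: float) -> float:
    """P(X >= c) for X ~ Poisson(lam), by direct summation of the pmf."""
    p_lt = 0.0
    for i in range(c):
        p_lt += math.exp(-lam) * lam**i / math.factorial(i)
    return max(0.0, 1.0 - p_lt)
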