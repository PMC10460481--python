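"""Depth-of-coverage and error-rate estimation from k-mer counts.

Notation (all per-k-mer means are over the *retained* lists after the
contamination cutoff):

* ``D_tag`` — mean observed count of a tag k-mer (tag k-mers seen divided
  by the number of tag k-mers in the list);
* ``D_err`` — the same for error k-mers;
* ``P_e``  — per-nucleotide substitution error rate,
  ``P_e = D_err / (D_err + D_tag/3)``;
* ``D``    — depth of coverage,
  ``D = D_tag * N_nucl / ((1 - P_e)^k * N_kmer)``.

The rationale: a read window covering a tag locus reproduces the tag
k-mer with probability ``(1-P_e)^k`` and a *specific* one-mismatch variant
with probability ``(P_e/3) * (1-P_e)^(k-1)``, so
``D_err/D_tag = (P_e/3)/(1-P_e)``, which inverts to the ``P_e`` formula;
the ``N_nucl/N_kmer`` factor converts k-mer-level depth back to
nucleotide-level depth (window loss at read edges and around N bases).

Contamination that happens to share a k-mer with the list inflates that
k-mer's count far beyond what the sample-wide depth supports.  Such
k-mers are removed from the sample *and* from the list denominators: the
cutoff ``c`` is the smallest count for which even one occurrence at or
above ``c`` anywhere in the list is improbable (union bound, Poisson tail
at the trimmed-mean rate), and k-mers with counts strictly above ``c``
are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .counter import CountResult
from .list_builder import KmerDatabase

__all__ = [
    "CutoffPolicy",
    "EstimateResult",
    "UndefinedEstimateError",
    "compute_cutoff",
    "apply_cutoff",
    "estimate_error_rate",
    "estimate_depth",
    "run_estimation",
]

logger = logging.getLogger(__name__)


class UndefinedEstimateError(ValueError):
    """No usable signal (zero reads, empty retained list, or no hits)."""


@dataclass(frozen=True)
class CutoffPolicy:
    """How the over-representation cutoff is derived.

    ``alpha`` bounds the probability of seeing even one count at or above
    the cutoff in the whole list under the null (homogeneous depth).  The
    per-k-mer rate is the ``trim``-trimmed mean of the counts, so that the
    contaminant-inflated outliers being targeted do not inflate the cutoff
    itself.  With ``refine=True`` the rate is re-estimated once on the
    retained counts and the cutoff recomputed.
    """

    alpha: float = 0.01
    model: str = "poisson"
    trim: float = 0.01
    refine: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.model != "poisson":
            raise ValueError(f"unsupported count model {self.model!r}")


@dataclass
class EstimateResult:
    """Depth/error estimates plus cutoff and filtering diagnostics."""

    d_tag: float
    d_err: float
    p_e: float
    depth: float
    cutoff_tag: int
    cutoff_err: int
    n_tag_used: int
    n_err_used: int
    n_tag_removed: int
    n_err_removed: int
    n_nucl: int
    n_kmer: int
    n_reads: int
    db_provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "error_rate": self.p_e,
            "d_tag": self.d_tag,
            "d_err": self.d_err,
            "cutoff_tag": self.cutoff_tag,
            "cutoff_err": self.cutoff_err,
            "n_tag_used": self.n_tag_used,
            "n_err_used": self.n_err_used,
            "n_tag_removed": self.n_tag_removed,
            "n_err_removed": self.n_err_removed,
            "n_nucl": self.n_nucl,
            "n_kmer": self.n_kmer,
            "n_reads": self.n_reads,
            "db_provenance": self.db_provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def render_text(self) -> str:
        return (
            f"depth of coverage : {self.depth:.6g}\n"
            f"error rate (P_e)  : {self.p_e:.6g}\n"
            f"D_tag / D_err     : {self.d_tag:.6g} / {self.d_err:.6g}\n"
            f"cutoff tag / err  : {self.cutoff_tag} / {self.cutoff_err}\n"
            f"tags used/removed : {self.n_tag_used} / {self.n_tag_removed}\n"
            f"errs used/removed : {self.n_err_used} / {self.n_err_removed}\n"
            f"sample            : {self.n_reads} reads, {self.n_nucl} nucl, {self.n_kmer} k-mers\n"
        )


def _trimmed_rate(counts: np.ndarray, trim: float) -> float:
    n_drop = int(counts.size * trim)
    if n_drop:
        kept = np.sort(counts)[: counts.size - n_drop]
    else:
        kept = counts
    return float(kept.mean()) if kept.size else 0.0


def compute_cutoff(counts: np.ndarray, list_size: int, policy: CutoffPolicy = CutoffPolicy()) -> int:
    """Smallest c >= 1 with ``list_size * P(X >= c) < alpha``, X ~ Poisson(rate).

    The rate is the trimmed mean of ``counts``; all-zero counts give a
    degenerate rate of 0 and cutoff 1.
    """
    if list_size < 1:
        raise ValueError("list_size must be >= 1")
    counts = np.asarray(counts)
    lam = _trimmed_rate(counts, policy.trim)
    if lam == 0.0:
        logger.info("cutoff: all-zero (or fully trimmed) counts; degenerate cutoff 1")
        return 1
    c = 1
    # P(X >= c) = sf(c - 1); the tail is strictly decreasing so this terminates
    while list_size * stats.poisson.sf(c - 1, lam) >= policy.alpha:
        c += 1
    return c


def apply_cutoff(counts: np.ndarray, c: int) -> tuple[np.ndarray, int]:
    """Drop counts strictly above ``c`` (ties at ``c`` are retained)."""
    if c < 1:
        raise ValueError("cutoff must be >= 1")
    counts = np.asarray(counts)
    keep = counts <= c
    return counts[keep], int(counts.size - keep.sum())


def estimate_error_rate(d_tag: float, d_err: float) -> float:
    """``P_e = D_err / (D_err + D_tag/3)``; undefined when both are zero."""
    if d_tag < 0 or d_err < 0:
        raise ValueError("mean counts must be non-negative")
    if d_tag == 0 and d_err == 0:
        raise UndefinedEstimateError("no tag or error k-mers observed")
    return d_err / (d_err + d_tag / 3.0)


def estimate_depth(d_tag: float, p_e: float, k: int, n_nucl: int, n_kmer: int) -> float:
    """``D = D_tag * N_nucl / ((1 - P_e)^k * N_kmer)``."""
    if n_kmer < 1:
        raise UndefinedEstimateError("sample contains no valid k-mer windows")
    if not 0 <= p_e < 1:
        raise UndefinedEstimateError(f"error rate {p_e} outside [0, 1)")
    return d_tag * n_nucl / ((1.0 - p_e) ** k * n_kmer)


def _cutoff_and_mean(counts: np.ndarray, policy: CutoffPolicy) -> tuple[int, np.ndarray, int]:
    c = compute_cutoff(counts, max(counts.size, 1), policy)
    kept, removed = apply_cutoff(counts, c)
    if policy.refine and removed:
        lam = float(kept.mean()) if kept.size else 0.0
        if lam > 0:
            c2 = 1
            while kept.size * stats.poisson.sf(c2 - 1, lam) >= policy.alpha:
                c2 += 1
            if c2 != c:
                c = c2
                kept, removed = apply_cutoff(counts, c)
    return c, kept, removed


def run_estimation(
    counts: CountResult, db: KmerDatabase, policy: CutoffPolicy = CutoffPolicy()
) -> EstimateResult:
    """Cutoff, then means, then the error-rate and depth formulas.

    The cutoff is computed and applied independently to the tag and error
    lists (their expected rates differ by a factor of about ``P_e/3``).
    """
    if counts.db_fingerprint != db.fingerprint():
        raise ValueError("counts were not produced against this database")
    if counts.n_reads == 0 or counts.n_kmer == 0:
        raise UndefinedEstimateError("sample contains no reads / no k-mer windows")
    if not db.tags:
        raise UndefinedEstimateError("database has no tag k-mers")

    cutoff_tag, kept_tag, rm_tag = _cutoff_and_mean(counts.tag_counts, policy)
    if kept_tag.size == 0:
        raise UndefinedEstimateError("cutoff removed every tag k-mer")
    d_tag = float(kept_tag.mean())

    if db.errors:
        cutoff_err, kept_err, rm_err = _cutoff_and_mean(counts.err_counts, policy)
        d_err = float(kept_err.mean()) if kept_err.size else 0.0
        n_err_used = int(kept_err.size)
    else:
        cutoff_err, rm_err, d_err, n_err_used = 0, 0, 0.0, 0

    p_e = estimate_error_rate(d_tag, d_err)
    if p_e >= 1.0:
        raise UndefinedEstimateError("no tag k-mers observed; depth undefined")
    depth = estimate_depth(d_tag, p_e, db.k, counts.n_nucl, counts.n_kmer)
    return EstimateResult(
        d_tag=d_tag,
        d_err=d_err,
        p_e=p_e,
        depth=depth,
        cutoff_tag=cutoff_tag,
        cutoff_err=cutoff_err,
        n_tag_used=int(kept_tag.size),
        n_err_used=n_err_used,
        n_tag_removed=rm_tag,
        n_err_removed=rm_err,
        n_nucl=counts.n_nucl,
        n_kmer=counts.n_kmer,
        n_reads=counts.n_reads,
        db_provenance=dict(db.provenance),
    )
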