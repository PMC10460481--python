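"""Precision-experiment drivers.

These functions tie the simulator, counter and estimator together for the
depth x contamination precision study: simulate reads from a fixed
synthetic genome against a fixed k-mer database, either estimating each
replicate separately (the grid table) or pooling counts across replicates
before estimating (which shrinks the Poisson noise of the pooled estimate
by 1/sqrt(replicates)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .counter import CountResult, count_reads, merge_counts
from .estimator import CutoffPolicy, EstimateResult, run_estimation
from .kmer_core import seq_to_codes
from .list_builder import KmerDatabase
from .simulator import compose_sample, simulate_reads

__all__ = ["PooledRun", "pooled_run", "replicate_counts", "run_precision_grid"]

GRID_DEPTHS = (0.001, 0.0033, 0.01, 0.033, 0.1, 0.333)
GRID_FRACTIONS = (1.0, 0.5, 0.2, 0.1)


def _one_replicate(
    genome_codes: np.ndarray,
    contaminant_codes: Sequence[np.ndarray],
    db: KmerDatabase,
    depth: float,
    human_fraction: float,
    read_length: int,
    p_N: float,
    p_sub: float,
    rng: np.random.Generator,
) -> CountResult:
    target = simulate_reads(
        genome_codes, depth, read_length=read_length, p_N=p_N, p_sub=p_sub, rng=rng
    )
    sample = compose_sample(
        target, contaminant_codes, human_fraction,
        read_length=read_length, p_N=p_N, p_sub=p_sub, rng=rng,
    )
    return count_reads(sample, db)


def replicate_counts(
    genome,
    contaminants: Sequence,
    db: KmerDatabase,
    depth: float,
    human_fraction: float,
    n_replicates: int,
    seed,
    read_length: int = 100,
    p_N: float = 0.01,
    p_sub: float = 0.01,
) -> list[CountResult]:
    """Independent replicate count results under one study condition."""
    genome_codes = genome if isinstance(genome, np.ndarray) else seq_to_codes(
        genome[1] if isinstance(genome, tuple) else genome
    )
    cont_codes = [
        c if isinstance(c, np.ndarray) else seq_to_codes(c[1] if isinstance(c, tuple) else c)
        for c in contaminants
    ]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        out.append(
            _one_replicate(
                genome_codes, cont_codes, db, depth, human_fraction,
                read_length, p_N, p_sub, rng,
            )
        )
    return out


@dataclass
class PooledRun:
    """Pooled estimate for one study condition, with the ground truth."""

    estimate: EstimateResult
    true_depth: float  # summed over the pooled replicates
    true_p_sub: float
    n_replicates: int

    @property
    def depth_rel_err(self) -> float:
        return self.estimate.depth / self.true_depth - 1.0

    @property
    def pe_rel_err(self) -> float:
        return self.estimate.p_e / self.true_p_sub - 1.0


def pooled_run(
    genome,
    contaminants: Sequence,
    db: KmerDatabase,
    depth: float,
    human_fraction: float,
    n_replicates: int,
    seed,
    read_length: int = 100,
    p_N: float = 0.01,
    p_sub: float = 0.01,
    policy: CutoffPolicy = CutoffPolicy(),
) -> PooledRun:
    """Pool replicate counts, then estimate once.

    Pooling counts (and the N_nucl/N_kmer tallies) over r replicates of a
    depth-D simulation yields one sample of depth r*D; the relative error
    of the pooled estimate against r*D measures the method's precision at
    the pooled sample size.
    """
    genome_codes = genome if isinstance(genome, np.ndarray) else seq_to_codes(
        genome[1] if isinstance(genome, tuple) else genome
    )
    cont_codes = [
        c if isinstance(c, np.ndarray) else seq_to_codes(c[1] if isinstance(c, tuple) else c)
        for c in contaminants
    ]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pooled = None
    # merge incrementally: materializing thousands of replicate results
    # would hold gigabytes of count arrays at once
    for child in ss.spawn(n_replicates):
        c = _one_replicate(
            genome_codes, cont_codes, db, depth, human_fraction,
            read_length, p_N, p_sub, np.random.default_rng(child),
        )
        c.source_files = []  # drop the per-replicate bookkeeping
        pooled = c if pooled is None else merge_counts(pooled, c)
    est = run_estimation(pooled, db, policy)
    return PooledRun(
        estimate=est,
        true_depth=depth * n_replicates,
        true_p_sub=p_sub,
        n_replicates=n_replicates,
    )


def run_precision_grid(
    genome,
    contaminants: Sequence,
    db: KmerDatabase,
    depths: Sequence[float] = GRID_DEPTHS,
    fractions: Sequence[float] = GRID_FRACTIONS,
    replicates: int = 1,
    seed=0,
    read_length: int = 100,
    p_N: float = 0.01,
    p_sub: float = 0.01,
    policy: CutoffPolicy = CutoffPolicy(),
) -> pd.DataFrame:
    """Per-replicate estimates over the depth x contamination grid.

    Returns a tidy table with columns depth_true, human_fraction,
    replicate, depth_est, depth_rel_err, pe_est, pe_rel_err.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for depth in depths:
        for frac in fractions:
            counts = replicate_counts(
                genome, contaminants, db, depth, frac, replicates,
                ss.spawn(1)[0], read_length, p_N, p_sub,
            )
            for rep, c in enumerate(counts):
                est = run_estimation(c, db, policy)
                rows.append(
                    {
                        "depth_true": depth,
                        "human_fraction": frac,
                        "replicate": rep,
                        "depth_est": est.depth,
                        "depth_rel_err": est.depth / depth - 1.0,
                        "pe_est": est.p_e,
                        "pe_rel_err": est.p_e / p_sub - 1.0,
                    }
                )
    return pd.DataFrame(rows)
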