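"""Shared fixtures and independent brute-force oracles.

The oracles here recompute results by the most literal method available
(per-base boolean arrays, all-pairs interval scans, explicit hypergeometric
enumeration) and deliberately share no code with the implementation paths
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from epiprior.promoters import GeneModel


# ---------------------------------------------------------------- oracles


def perbase_union(windows: list[tuple[int, int]], length: int) -> np.ndarray:
    """Boolean per-base occupancy of half-open windows on one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for s, e in windows:
        mask[max(s, 0): min(e, length)] = True
    return mask


def brute_force_counts(promoter_fragments, track_intervals) -> int:
    """Number of track intervals sharing >= 1 base with any promoter fragment.

    All-pairs scan; one interval touching several fragments counts once.
    """
    n = 0
    for chrom_t, ts, te in track_intervals:
        hit = any(
            chrom_p == chrom_t and ts < pe and te > ps
            for chrom_p, ps, pe in promoter_fragments
        )
        n += hit
    return n


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration of fixed-margin tables."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(c1, r1) + 1):
        px = hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Hand step-up BH: adj_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def small_gene_model() -> GeneModel:
    """Four genes on two tiny chromosomes, exercising strand and merging."""
    rows = [
        ("gA", "gA.t1", "chr1", "+", 5000),
        ("gA", "gA.t2", "chr1", "+", 6000),
        ("gB", "gB.t1", "chr1", "-", 9000),
        ("gC", "gC.t1", "chr2", "+", 1500),
        ("gD", "gD.t1", "chr2", "-", 12000),
    ]
    return GeneModel(
        records=pd.DataFrame(
            rows, columns=["gene_id", "transcript_id", "chrom", "strand", "tss"]
        ),
        chrom_lengths={"chr1": 20000, "chr2": 13000},
    )


def random_gene_model(rng: np.random.Generator, n_genes: int = 20,
                      chrom_length: int = 50_000, n_chroms: int = 2) -> GeneModel:
    """Small random gene model for randomized oracle suites."""
    rows = []
    for g in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        base = int(rng.integers(0, chrom_length - 3000))
        for t in range(int(rng.integers(1, 4))):
            rows.append((f"g{g}", f"g{g}.t{t}", chrom, strand,
                         base + int(rng.integers(0, 1500))))
    return GeneModel(
        records=pd.DataFrame(
            rows, columns=["gene_id", "transcript_id", "chrom", "strand", "tss"]
        ),
        chrom_lengths={f"chr{i+1}": chrom_length for i in range(n_chroms)},
    )
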