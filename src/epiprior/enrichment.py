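"""Enrichment/depletion of elements in disease-gene promoters.

The null model is resampling: draw gene sets of the disease-set size
uniformly without replacement from all genes (disease genes included, since
the background is "all promoters on the genome"), and record per element how
many drawn genes carry the annotation. The mean annotated count over
resamples is the expected random annotation; a two-sided Fisher exact test
then compares the observed disease count against that rounded expectation,
and an add-one empirical permutation p is reported alongside. P values are
signed for reporting: -log10(p) for enriched elements, +log10(p) (negative
numbers) for depleted ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationMatrix, ElementId

__all__ = [
    "ResampleNull",
    "EnrichmentResult",
    "resample_background",
    "fisher_exact_2x2",
    "signed_log10",
    "bh_adjust",
    "run_enrichment",
    "control_run",
    "results_to_dataframe",
]

logger = logging.getLogger(__name__)

#: relative tolerance when comparing hypergeometric point probabilities,
#: so tables tied with the observed one up to rounding are included (the
#: same guard R's fisher.test uses).
_PMF_REL_TOL = 1e-7

DEFAULT_N_RESAMPLES = 1000
DEFAULT_ALPHA = 0.05

_RESAMPLE_STREAM = 10
_CONTROL_STREAM = 11


@dataclass
class ResampleNull:
    """Null annotated-count distribution for one element."""

    element_id: ElementId
    resample_counts: np.ndarray
    n_resamples: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.resample_counts))

    @property
    def var(self) -> float:
        return float(np.var(self.resample_counts))


@dataclass
class EnrichmentResult:
    element_id: ElementId
    observed: int
    disease_set_size: int
    background_mean: float
    background_var: float
    fisher_p: float
    fisher_p_pooled: float
    empirical_p: float
    direction: str  # "enriched" | "depleted"
    signed_log10_p: float
    adjusted_p: float = float("nan")
    significant: bool = False


def resample_background(
    annotation: AnnotationMatrix,
    disease_set_size: int,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> list[ResampleNull]:
    """Draw ``n_resamples`` uniform gene sets and count annotations per element.

    Each resample draws ``disease_set_size`` genes without replacement from
    all genes; per element the number of drawn genes with a 0/1 annotation of
    1 is recorded. Deterministic for a fixed seed.
    """
    if n_resamples < 1:
        raise ValueError(f"n_resamples must be >= 1, got {n_resamples}")
    n_genes = annotation.n_genes
    if not 0 < disease_set_size <= n_genes:
        raise ValueError(
            f"disease_set_size must be in 1..{n_genes}, got {disease_set_size}"
        )
    rng = np.random.default_rng([seed, _RESAMPLE_STREAM])
    binary = annotation.binary
    counts = np.empty((n_resamples, len(annotation.elements)), dtype=np.int64)
    for r in range(n_resamples):
        idx = rng.choice(n_genes, size=disease_set_size, replace=False)
        counts[r] = binary[idx].sum(axis=0)
    return [
        ResampleNull(eid, counts[:, j].copy(), n_resamples, seed)
        for j, eid in enumerate(annotation.elements)
    ]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities at most the observed table's
    (with a small relative tolerance for ties), margins held fixed. A zero
    margin makes the table degenerate: p = 1 with a logged warning.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError(f"negative cell in 2x2 table: {(a, b, c, d)}")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        logger.warning("degenerate 2x2 table %s: zero margin, p = 1", (a, b, c, d))
        return 1.0
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + _PMF_REL_TOL)].sum())
    return min(p, 1.0)


def signed_log10(p: float, direction: str) -> float:
    """Log-transform a p value with the reporting sign convention.

    Enriched elements map to ``-log10(p)`` (positive), depleted ones to
    ``log10(p)`` (negative), so sign encodes direction and magnitude encodes
    strength.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if direction == "enriched":
        return -math.log10(p)
    if direction == "depleted":
        return math.log10(p)
    raise ValueError(f"direction must be 'enriched' or 'depleted', got {direction!r}")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, original order preserved."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues <= 0) | (pvalues > 1)):
        raise ValueError("p values must be in (0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def _element_results(
    annotation: AnnotationMatrix,
    member_idx: np.ndarray,
    n_resamples: int,
    alpha: float,
    seed: int,
) -> list[EnrichmentResult]:
    size = len(member_idx)
    nulls = resample_background(annotation, size, n_resamples, seed)
    observed = annotation.binary[member_idx].sum(axis=0)
    pooled = annotation.binary.sum(axis=0)  # all-genes annotated counts
    n_genes = annotation.n_genes
    results = []
    for j, null in enumerate(nulls):
        obs = int(observed[j])
        mean = null.mean
        bg = int(round(mean))
        direction = "depleted" if obs < mean else "enriched"
        fisher_p = fisher_exact_2x2(obs, size - obs, bg, size - bg)
        fisher_pooled = fisher_exact_2x2(
            obs, size - obs, int(pooled[j]), n_genes - int(pooled[j])
        )
        if direction == "enriched":
            extreme = int(np.sum(null.resample_counts >= obs))
        else:
            extreme = int(np.sum(null.resample_counts <= obs))
        empirical_p = (extreme + 1) / (null.n_resamples + 1)
        results.append(
            EnrichmentResult(
                element_id=null.element_id,
                observed=obs,
                disease_set_size=size,
                background_mean=mean,
                background_var=null.var,
                fisher_p=fisher_p,
                fisher_p_pooled=fisher_pooled,
                empirical_p=empirical_p,
                direction=direction,
                signed_log10_p=signed_log10(fisher_p, direction),
            )
        )
    adj = bh_adjust([r.fisher_p for r in results])
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
        r.significant = r.fisher_p < alpha
    return results


def run_enrichment(
    annotation: AnnotationMatrix,
    disease_set,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per-element enrichment/depletion of the disease set vs the resampled null.

    Raises if the disease set is empty or contains unknown genes.
    """
    disease_set = set(disease_set)
    if not disease_set:
        raise ValueError("disease set is empty")
    unknown = disease_set - set(annotation.genes)
    if unknown:
        raise ValueError(f"disease genes absent from annotation: {sorted(unknown)[:5]}")
    member_idx = annotation.gene_index(sorted(disease_set))
    return _element_results(annotation, member_idx, n_resamples, alpha, seed)


def control_run(
    annotation: AnnotationMatrix,
    disease_set_size: int,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    control_set=None,
) -> list[EnrichmentResult]:
    """Same pipeline on a random gene set of the disease-set size.

    A negative control reported alongside the real run: its significant
    fraction should sit near ``alpha``. An explicit ``control_set`` may be
    supplied but must have exactly ``disease_set_size`` genes.
    """
    if control_set is not None:
        control_set = set(control_set)
        if len(control_set) != disease_set_size:
            raise ValueError(
                f"control set size {len(control_set)} != disease set size {disease_set_size}"
            )
    else:
        rng = np.random.default_rng([seed, _CONTROL_STREAM])
        idx = rng.choice(annotation.n_genes, size=disease_set_size, replace=False)
        control_set = {annotation.genes[i] for i in idx}
    return run_enrichment(annotation, control_set, n_resamples, alpha, seed)


def results_to_dataframe(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat report table, one row per element."""
    return pd.DataFrame(
        {
            "element": [r.element_id.name for r in results],
            "class": [r.element_id.element_class for r in results],
            "cell_type": [r.element_id.cell_type for r in results],
            "observed": [r.observed for r in results],
            "background_mean": [r.background_mean for r in results],
            "background_var": [r.background_var for r in results],
            "fisher_p": [r.fisher_p for r in results],
            "fisher_p_pooled": [r.fisher_p_pooled for r in results],
            "empirical_p": [r.empirical_p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "direction": [r.direction for r in results],
            "signed_log10_p": [r.signed_log10_p for r in results],
            "significant": [r.significant for r in results],
        }
    )
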