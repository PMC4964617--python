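"""Reverse prediction: rank all genes by the disease element profile.

Every gene's promoter is scored against the elements found significantly
enriched or depleted in the disease set: the number of times the promoter is
annotated by each significant element, weighted by that element's signed
log10 p (enriched elements add, depleted ones subtract in the default
signed mode; absolute mode uses |signed log10 p|), summed over elements.
High-scoring genes carry the disease-associated regulatory profile and are
candidate susceptibility genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationMatrix, ElementId
from .enrichment import EnrichmentResult

__all__ = ["GeneScore", "score_genes", "rank_and_select", "scores_to_dataframe"]

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 20


@dataclass
class GeneScore:
    gene_id: str
    total_score: float
    per_element_contribution: dict[ElementId, float] = field(default_factory=dict)
    rank: int = 0  # 1-based, descending score, ties by gene_id


def score_genes(
    annotation: AnnotationMatrix,
    significant: list[EnrichmentResult],
    weight_mode: str = "signed",
) -> list[GeneScore]:
    """Weighted-count total score for every annotated gene.

    ``significant`` may be a full enrichment result list (non-significant
    rows are dropped here) or a pre-filtered one. Raises if no significant
    element remains, since every score would be trivially zero.
    """
    if weight_mode not in ("signed", "absolute"):
        raise ValueError(f"weight_mode must be 'signed' or 'absolute', got {weight_mode!r}")
    used = [r for r in significant if r.significant]
    if not used:
        raise ValueError(
            "no significant elements to score with; relax alpha or check the enrichment run"
        )
    known = set(annotation.elements)
    missing = [r.element_id for r in used if r.element_id not in known]
    if missing:
        raise ValueError(f"significant elements absent from annotation: {missing[:5]}")
    col = {eid: j for j, eid in enumerate(annotation.elements)}
    weights = np.array(
        [
            r.signed_log10_p if weight_mode == "signed" else abs(r.signed_log10_p)
            for r in used
        ]
    )
    cols = [col[r.element_id] for r in used]
    counts = annotation.counts[:, cols]
    totals = counts @ weights
    scores = []
    for i, gid in enumerate(annotation.genes):
        contrib = {
            r.element_id: float(counts[i, j] * weights[j])
            for j, r in enumerate(used)
            if counts[i, j]
        }
        scores.append(GeneScore(gene_id=gid, total_score=float(totals[i]),
                                per_element_contribution=contrib))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i].total_score, scores[i].gene_id))
    for rank, i in enumerate(order, start=1):
        scores[i].rank = rank
    return scores


def rank_and_select(
    scores: list[GeneScore],
    k: int = DEFAULT_TOP_K,
    exclude=frozenset(),
) -> list[GeneScore]:
    """Top-k genes by descending score, ties broken by gene_id.

    Genes in ``exclude`` (typically the known disease set, so the output
    lists novel candidates) are removed before selection. Asking for more
    genes than remain returns them all, with a log note.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    exclude = set(exclude)
    pool = sorted(
        (s for s in scores if s.gene_id not in exclude),
        key=lambda s: (-s.total_score, s.gene_id),
    )
    if k > len(pool):
        logger.info("requested top %d but only %d genes remain; returning all", k, len(pool))
    return pool[:k]


def scores_to_dataframe(scores: list[GeneScore], decimals: int = 2) -> pd.DataFrame:
    """Ranking table (gene, total score to ``decimals``, rank)."""
    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "total_score": [round(s.total_score, decimals) for s in scores],
            "rank": [s.rank for s in scores],
        }
    )
    return df.sort_values(["rank"]).reset_index(drop=True)
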