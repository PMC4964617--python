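"""Promoter x element overlap annotation.

Each epigenomic element (a TFBS ChIP-seq peak set, a chromatin-state
segment class in one cell type, or a histone-mark peak set) is an interval
track. A gene's promoter is *annotated* by an element if any promoter
fragment shares at least one base with any track interval; overlap is
recorded both as a 0/1 flag (used by the enrichment test, where repeated
overlap still counts once) and as the number of distinct track intervals
touching the promoter (used by the scoring stage).

Tracks of the same mark from different cell types are distinct elements.
Element strand is ignored: peak tracks are unstranded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .promoters import PromoterSet

__all__ = [
    "ElementId",
    "ElementTrack",
    "AnnotationMatrix",
    "annotate_binary",
    "annotate_counts",
    "build_annotation_matrix",
    "read_tracks_bed",
    "write_tracks_bed",
]

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = ("TFBS", "chromatin_state", "histone_mark")


@dataclass(frozen=True)
class ElementId:
    """(name, class, cell type) identity of one epigenomic element."""

    name: str
    element_class: str
    cell_type: str

    @property
    def label(self) -> str:
        return f"{self.name}|{self.element_class}|{self.cell_type}"

    @classmethod
    def from_label(cls, label: str) -> "ElementId":
        parts = label.split("|")
        if len(parts) != 3:
            raise ValueError(f"element label must be name|class|cell_type: {label!r}")
        return cls(*parts)


@dataclass
class ElementTrack:
    """One element's intervals, 0-based half-open; intervals may overlap."""

    element_id: ElementId
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, s, e in self.intervals:
            if e <= s:
                raise ValueError(
                    f"empty interval in track {self.element_id.label}: ({chrom}, {s}, {e})"
                )


@dataclass
class AnnotationMatrix:
    """Gene x element binary flags and interval-overlap counts.

    Invariant: ``binary == (counts >= 1)`` elementwise.
    """

    genes: list[str]
    elements: list[ElementId]
    binary: np.ndarray  # (n_genes, n_elements) of 0/1
    counts: np.ndarray  # (n_genes, n_elements) of non-negative ints

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=np.int8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        shape = (len(self.genes), len(self.elements))
        if self.binary.shape != shape or self.counts.shape != shape:
            raise ValueError("annotation matrix shape mismatch")
        if not np.array_equal(self.binary, (self.counts >= 1).astype(np.int8)):
            raise ValueError("binary flags inconsistent with counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        return np.array([pos[g] for g in gene_ids], dtype=np.intp)

    def to_dataframe(self, which: str = "counts") -> pd.DataFrame:
        data = self.counts if which == "counts" else self.binary
        return pd.DataFrame(
            data, index=self.genes, columns=[e.label for e in self.elements]
        )

    def write_tsv(self, counts_path, binary_path=None) -> None:
        self.to_dataframe("counts").rename_axis("gene_id").to_csv(counts_path, sep="\t")
        if binary_path is not None:
            self.to_dataframe("binary").rename_axis("gene_id").to_csv(
                binary_path, sep="\t"
            )


def _promoter_trees(promoters: PromoterSet) -> dict[str, IntervalTree]:
    """One tree per chromosome; payload is the gene's row index."""
    trees: dict[str, IntervalTree] = {}
    index = {g: i for i, g in enumerate(promoters.gene_order)}
    for gid, fragments in promoters.intervals.items():
        for chrom, s, e in fragments:
            trees.setdefault(chrom, IntervalTree()).addi(s, e, index[gid])
    return trees


def _count_track(
    promoters: PromoterSet,
    track: ElementTrack,
    trees: dict[str, IntervalTree] | None = None,
) -> np.ndarray:
    if trees is None:
        trees = _promoter_trees(promoters)
    counts = np.zeros(len(promoters.gene_order), dtype=np.int64)
    seen_missing: set[str] = set()
    for chrom, s, e in track.intervals:
        tree = trees.get(chrom)
        if tree is None:
            if chrom not in seen_missing:
                seen_missing.add(chrom)
                logger.info(
                    "track %s has intervals on %s absent from promoters; ignored",
                    track.element_id.label, chrom,
                )
            continue
        # one interval touching several fragments of one gene is one event
        genes_hit = {iv.data for iv in tree.overlap(s, e)}
        for gi in genes_hit:
            counts[gi] += 1
    return counts


def annotate_counts(promoters: PromoterSet, track: ElementTrack) -> np.ndarray:
    """Number of track intervals overlapping (>= 1 base) each gene's promoter."""
    return _count_track(promoters, track)


def annotate_binary(promoters: PromoterSet, track: ElementTrack) -> np.ndarray:
    """0/1 per gene: does any track interval overlap the promoter at all?"""
    return (annotate_counts(promoters, track) >= 1).astype(np.int8)


def build_annotation_matrix(
    promoters: PromoterSet, tracks: list[ElementTrack]
) -> AnnotationMatrix:
    """Annotate every gene against every track in one pass."""
    trees = _promoter_trees(promoters)
    counts = np.column_stack(
        [_count_track(promoters, t, trees) for t in tracks]
    ) if tracks else np.zeros((len(promoters.gene_order), 0), dtype=np.int64)
    return AnnotationMatrix(
        genes=list(promoters.gene_order),
        elements=[t.element_id for t in tracks],
        binary=(counts >= 1).astype(np.int8),
        counts=counts,
    )


def write_tracks_bed(tracks: list[ElementTrack], path) -> None:
    """Write all tracks as one BED6 file, metadata encoded in the name column."""
    rows = []
    for t in tracks:
        for chrom, s, e in t.intervals:
            rows.append((chrom, s, e, t.element_id.label, 0, "."))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_tracks_bed(path, manifest: pd.DataFrame | None = None) -> list[ElementTrack]:
    """Read BED3/BED6 tracks.

    Element metadata comes either from the BED name column encoded as
    ``name|class|cell_type`` or from a sidecar ``manifest`` with columns
    ``name, element_class, cell_type`` keyed by the plain BED name.
    """
    bed = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if bed.shape[1] < 4:
        raise ValueError("track BED needs a name column (BED4+) for element identity")
    by_element: dict[ElementId, list[tuple[str, int, int]]] = {}
    meta = None
    if manifest is not None:
        meta = {
            r.name: ElementId(r.name, r.element_class, r.cell_type)
            for r in manifest.itertuples(index=False)
        }
    for row in bed.itertuples(index=False):
        raw_name = str(row[3])
        if meta is not None:
            eid = meta.get(raw_name)
            if eid is None:
                raise ValueError(f"element {raw_name!r} missing from manifest")
        else:
            eid = ElementId.from_label(raw_name)
        by_element.setdefault(eid, []).append((str(row[0]), int(row[1]), int(row[2])))
    return [ElementTrack(eid, ivals) for eid, ivals in by_element.items()]
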