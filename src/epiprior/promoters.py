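"""Per-gene merged promoter extraction.

A promoter is the fixed-length window immediately upstream of a transcript's
transcription start site (TSS): ``[tss - L, tss)`` on the + strand and
``[tss, tss + L)`` on the - strand (upstream is rightward there), clipped to
the chromosome. Genes with several transcripts get the per-transcript windows
merged into disjoint intervals, so a gene's promoter is a union of one or
more fragments. All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneModel",
    "PromoterSet",
    "InputError",
    "extract_promoters",
    "read_gene_model_tsv",
    "read_gene_model_gtf",
]

#: default promoter window, in nucleotides upstream of the TSS
DEFAULT_PROMOTER_LENGTH = 2000

GENE_MODEL_COLUMNS = ["gene_id", "transcript_id", "chrom", "strand", "tss"]


class InputError(ValueError):
    """Malformed gene model or coordinate input."""


@dataclass
class GeneModel:
    """Transcript-level gene model: one row per (gene, transcript) TSS.

    Parameters
    ----------
    records
        DataFrame with columns ``gene_id, transcript_id, chrom, strand, tss``.
        ``tss`` is 0-based; ``strand`` is ``+`` or ``-``.
    chrom_lengths
        Optional map chromosome -> length in bp, used for clipping and
        validation.
    """

    records: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GENE_MODEL_COLUMNS if c not in self.records.columns]
        if missing:
            raise InputError(f"gene model missing columns: {missing}")
        rec = self.records.reset_index(drop=True)[GENE_MODEL_COLUMNS].copy()
        rec["tss"] = rec["tss"].astype(int)
        bad_strand = ~rec["strand"].isin(["+", "-"])
        if bad_strand.any():
            sym = rec.loc[bad_strand, "strand"].iloc[0]
            raise InputError(f"unknown strand symbol {sym!r}")
        if (rec["tss"] < 0).any():
            row = rec.loc[rec["tss"] < 0].iloc[0]
            raise InputError(
                f"negative TSS for {row.gene_id}/{row.transcript_id}: {row.tss}"
            )
        dup = rec.duplicated(subset=["gene_id", "transcript_id"])
        if dup.any():
            row = rec.loc[dup].iloc[0]
            raise InputError(
                f"duplicate (gene_id, transcript_id): ({row.gene_id}, {row.transcript_id})"
            )
        if self.chrom_lengths is not None:
            for row in rec.itertuples():
                limit = self.chrom_lengths.get(row.chrom)
                if limit is not None and row.tss >= limit:
                    raise InputError(
                        f"TSS beyond chromosome end for {row.gene_id}/{row.transcript_id}: "
                        f"{row.tss} >= {limit} ({row.chrom})"
                    )
        self.records = rec

    @property
    def gene_ids(self) -> list[str]:
        """Gene ids in first-appearance order."""
        return list(dict.fromkeys(self.records["gene_id"]))

    @property
    def n_genes(self) -> int:
        return self.records["gene_id"].nunique()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class PromoterSet:
    """Merged promoter fragments per gene.

    ``intervals`` maps gene_id -> sorted disjoint ``(chrom, start, end)``
    fragments (0-based half-open). ``promoter_length`` is the window L each
    fragment was derived from.
    """

    intervals: dict[str, list[tuple[str, int, int]]]
    promoter_length: int = DEFAULT_PROMOTER_LENGTH
    gene_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_order:
            self.gene_order = list(self.intervals)

    def total_bases(self, gene_id: str) -> int:
        return sum(e - s for _, s, e in self.intervals[gene_id])

    def to_bed(self, path) -> None:
        """Write fragments as BED6 with name = gene_id."""
        rows = []
        for gid in self.gene_order:
            for chrom, s, e in self.intervals[gid]:
                rows.append((chrom, s, e, gid, 0, "."))
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def _merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of possibly-overlapping half-open intervals, per chromosome."""
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], e))
        else:
            out.append((chrom, s, e))
    return out


def extract_promoters(
    genes: GeneModel, promoter_length: int = DEFAULT_PROMOTER_LENGTH
) -> PromoterSet:
    """Build per-gene merged promoters from transcript TSS coordinates.

    For each transcript the upstream window is taken strand-aware and clipped
    to ``[0, chrom_length]``; per gene, overlapping windows on the same
    chromosome are merged into single fragments.

    Raises
    ------
    InputError
        If ``promoter_length`` < 1 (strand/coordinate problems are caught at
        :class:`GeneModel` construction).
    """
    if promoter_length < 1:
        raise InputError(f"promoter_length must be >= 1, got {promoter_length}")
    L = int(promoter_length)
    lengths = genes.chrom_lengths or {}
    per_gene: dict[str, list[tuple[str, int, int]]] = {}
    for row in genes.records.itertuples():
        if row.strand == "+":
            start, end = row.tss - L, row.tss
        else:
            start, end = row.tss, row.tss + L
        start = max(start, 0)
        limit = lengths.get(row.chrom)
        if limit is not None:
            end = min(end, limit)
        if end <= start:  # fully clipped away (e.g. + strand TSS at 0)
            continue
        per_gene.setdefault(row.gene_id, []).append((row.chrom, start, end))
    merged = {gid: _merge(ivals) for gid, ivals in per_gene.items()}
    order = [g for g in genes.gene_ids if g in merged]
    return PromoterSet(intervals=merged, promoter_length=L, gene_order=order)


def read_gene_model_tsv(path, chrom_lengths: dict[str, int] | None = None) -> GeneModel:
    """Read the TSV gene-model layout (gene_id, transcript_id, chrom, strand, tss)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneModel(records=df, chrom_lengths=chrom_lengths)


def read_gene_model_gtf(path, chrom_lengths: dict[str, int] | None = None) -> GeneModel:
    """Read a minimal GTF dialect, using transcript feature lines only.

    GTF is 1-based closed; the TSS is the ``start`` for + strand transcripts
    and ``end`` for - strand, converted to a 0-based coordinate. Requires
    ``gene_id`` and ``transcript_id`` attributes.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes",
        ],
        dtype={"chrom": str},
    )
    df = df[df["feature"] == "transcript"]
    if df.empty:
        raise InputError(f"no transcript lines in GTF {path}")
    attrs = df["attributes"].str.extract(
        r'gene_id "(?P<gene_id>[^"]+)".*?transcript_id "(?P<transcript_id>[^"]+)"'
    )
    if attrs.isna().any().any():
        raise InputError("GTF transcript line lacks gene_id/transcript_id attributes")
    tss = df["start"].where(df["strand"] == "+", df["end"]).astype(int) - 1
    rec = pd.DataFrame(
        {
            "gene_id": attrs["gene_id"].to_numpy(),
            "transcript_id": attrs["transcript_id"].to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "strand": df["strand"].to_numpy(),
            "tss": tss.to_numpy(),
        }
    )
    return GeneModel(records=rec, chrom_lengths=chrom_lengths)
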