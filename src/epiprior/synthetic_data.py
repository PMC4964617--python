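"""Toy genomes with planted promoter-element structure.

Stands in for the real inputs of the analysis (a GWAS-derived disease gene
list and ENCODE-style element tracks) so every downstream stage can be
exercised and calibrated. A toy genome carries genes laid out in
non-overlapping slots (so promoters of different genes never collide and
calibration is clean); each element track overlaps a background gene's
promoter with probability ``baseline_hit_prob`` and a planted (disease or
held-out) gene's promoter with the odds-multiplied probability

    p_planted = m * odds_b / (1 + m * odds_b),   odds_b = p_b / (1 - p_b)

for odds multiplier ``m`` — multiplying odds rather than probability keeps
p_planted < 1 for any m. A promoter "hit" places ``intervals_per_hit``
intervals overlapping the promoter; additional noise intervals fall
uniformly in intergenic space. A single integer seed drives everything via
per-operation child streams, so each operation is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .annotation import ELEMENT_CLASSES, ElementId, ElementTrack
from .promoters import GeneModel, PromoterSet, extract_promoters
import pandas as pd

__all__ = [
    "ConfigError",
    "ElementSpec",
    "SimConfig",
    "SimResult",
    "planted_probability",
    "generate_genome",
    "generate_disease_set",
    "generate_planted_sets",
    "generate_tracks",
    "simulate",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


# per-operation child streams of the single config seed
_GENOME_STREAM = 1
_DISEASE_STREAM = 2
_TRACKS_STREAM = 3


@dataclass
class ElementSpec:
    """One synthetic epigenomic element track.

    baseline_hit_prob
        Probability a background gene's promoter is overlapped, in (0, 1).
    planted_odds_multiplier
        Multiplicative odds change in planted promoters: 1.0 is null,
        > 1 planted enrichment, < 1 planted depletion.
    intervals_per_hit
        Intervals placed per promoter hit; an int or an inclusive
        ``(lo, hi)`` range.
    """

    name: str
    element_class: str = "TFBS"
    cell_type: str = "cellA"
    baseline_hit_prob: float = 0.2
    planted_odds_multiplier: float = 1.0
    intervals_per_hit: int | tuple[int, int] = 1
    interval_length: int = 200
    n_intergenic_intervals: int = 25

    def validate(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ConfigError(
                f"element_class must be one of {ELEMENT_CLASSES}, got {self.element_class!r}"
            )
        if not 0 < self.baseline_hit_prob < 1:
            raise ConfigError(
                f"baseline_hit_prob must be in (0, 1), got {self.baseline_hit_prob}"
            )
        if self.planted_odds_multiplier <= 0:
            raise ConfigError(
                f"planted_odds_multiplier must be > 0, got {self.planted_odds_multiplier}"
            )
        lo, hi = _as_range(self.intervals_per_hit, "intervals_per_hit")
        if lo < 1:
            raise ConfigError(f"intervals_per_hit must be >= 1, got {self.intervals_per_hit}")
        if self.interval_length < 1:
            raise ConfigError(f"interval_length must be >= 1, got {self.interval_length}")
        if self.n_intergenic_intervals < 0:
            raise ConfigError(
                f"n_intergenic_intervals must be >= 0, got {self.n_intergenic_intervals}"
            )

    @property
    def element_id(self) -> ElementId:
        return ElementId(self.name, self.element_class, self.cell_type)


def _as_range(value, fieldname: str) -> tuple[int, int]:
    if isinstance(value, (int, np.integer)):
        return int(value), int(value)
    try:
        lo, hi = value
    except (TypeError, ValueError):
        raise ConfigError(f"{fieldname} must be an int or a (lo, hi) pair, got {value!r}")
    lo, hi = int(lo), int(hi)
    if lo > hi:
        raise ConfigError(f"{fieldname} range reversed: {value!r}")
    return lo, hi


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults reflect a realistic desk-scale study: 2000 genes on 4
    chromosomes with 250 disease genes (the real disease gene lists this
    emulates run to a few hundred genes) and 2000-nt promoters.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    n_genes: int = 2000
    transcripts_per_gene: int | tuple[int, int] = (1, 3)
    n_disease_genes: int = 250
    n_holdout_genes: int = 0
    elements: list[ElementSpec] = field(default_factory=list)
    promoter_length: int = 2000
    allow_empty_disease_set: bool = False

    def validate(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "promoter_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_disease_genes < 0:
            raise ConfigError(f"n_disease_genes must be >= 0, got {self.n_disease_genes}")
        if self.n_disease_genes == 0 and not self.allow_empty_disease_set:
            raise ConfigError(
                "n_disease_genes is 0; set allow_empty_disease_set=True if intended"
            )
        if self.n_holdout_genes < 0:
            raise ConfigError(f"n_holdout_genes must be >= 0, got {self.n_holdout_genes}")
        if self.n_disease_genes + self.n_holdout_genes > self.n_genes:
            raise ConfigError(
                f"n_disease_genes + n_holdout_genes "
                f"({self.n_disease_genes} + {self.n_holdout_genes}) exceeds n_genes ({self.n_genes})"
            )
        if self.chrom_length <= self.promoter_length:
            raise ConfigError(
                f"chrom_length ({self.chrom_length}) must exceed promoter_length "
                f"({self.promoter_length})"
            )
        _as_range(self.transcripts_per_gene, "transcripts_per_gene")
        if self._slot_length() < self._min_slot():
            raise ConfigError(
                f"chrom_length too small: each of the {self._genes_per_chrom()} genes per "
                f"chromosome needs >= {self._min_slot()} bp, has {self._slot_length()}"
            )
        for spec in self.elements:
            spec.validate()

    def _genes_per_chrom(self) -> int:
        return -(-self.n_genes // self.n_chromosomes)  # ceil

    def _slot_length(self) -> int:
        return self.chrom_length // self._genes_per_chrom()

    def _min_slot(self) -> int:
        # room for upstream+downstream windows plus transcript TSS spread,
        # guaranteeing promoters of neighbouring genes never touch
        return 5 * self.promoter_length + 1

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        elements = [ElementSpec(**e) for e in raw.pop("elements", [])]
        for key in ("transcripts_per_gene", "intervals_per_hit"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        for e in elements:
            if isinstance(e.intervals_per_hit, list):
                e.intervals_per_hit = tuple(e.intervals_per_hit)
        return cls(elements=elements, **raw)


def planted_probability(baseline_hit_prob: float, odds_multiplier: float) -> float:
    """Hit probability after multiplying the baseline odds by ``odds_multiplier``."""
    odds = odds_multiplier * baseline_hit_prob / (1 - baseline_hit_prob)
    return odds / (1 + odds)


def generate_genome(config: SimConfig) -> GeneModel:
    """Lay out ``n_genes`` genes with per-transcript TSSs on the toy genome.

    Genes occupy disjoint chromosome slots; within a slot the anchor TSS is
    jittered and extra transcripts start within one promoter length of it,
    so multi-transcript promoters overlap and exercise merging. Deterministic
    per seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _GENOME_STREAM])
    L = config.promoter_length
    t_lo, t_hi = _as_range(config.transcripts_per_gene, "transcripts_per_gene")
    slot = config._slot_length()
    margin = 2 * L
    usable = slot - 2 * margin - L
    rows = []
    for g in range(config.n_genes):
        chrom = config.chrom_names[g % config.n_chromosomes]
        slot_idx = g // config.n_chromosomes
        anchor = slot_idx * slot + margin + int(rng.integers(0, max(usable, 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(t_lo, t_hi + 1))
        gid = f"G{g:05d}"
        offsets = [0] + [int(rng.integers(0, L)) for _ in range(n_tx - 1)]
        for t, off in enumerate(offsets):
            rows.append((gid, f"{gid}.T{t + 1}", chrom, strand, anchor + off))
    records = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "chrom", "strand", "tss"])
    return GeneModel(records=records, chrom_lengths=config.chrom_lengths)


def generate_planted_sets(config: SimConfig, genes: GeneModel) -> tuple[set, set]:
    """Disjoint disease and held-out gene sets, drawn uniformly per seed.

    Held-out genes receive the same planted element profile as disease genes
    during track generation but are meant to be withheld from the enrichment
    stage, for recovery experiments.
    """
    config.validate()
    ids = genes.gene_ids
    if config.n_disease_genes + config.n_holdout_genes > len(ids):
        raise ConfigError(
            f"n_disease_genes + n_holdout_genes exceeds available genes ({len(ids)})"
        )
    rng = np.random.default_rng([config.seed, _DISEASE_STREAM])
    perm = rng.permutation(len(ids))
    disease = {ids[i] for i in perm[: config.n_disease_genes]}
    holdout = {
        ids[i]
        for i in perm[config.n_disease_genes : config.n_disease_genes + config.n_holdout_genes]
    }
    return disease, holdout


def generate_disease_set(config: SimConfig, genes: GeneModel) -> set:
    """Uniform random disease gene subset of size ``n_disease_genes``."""
    return generate_planted_sets(config, genes)[0]


def _place_hit(rng, fragments, ilen: int, chrom_length: int):
    chrom, fs, fe = fragments[int(rng.integers(len(fragments)))]
    lo = max(0, fs - ilen + 1)
    hi = min(fe - 1, chrom_length - ilen)
    start = int(rng.integers(lo, hi + 1))
    return chrom, start, start + ilen


def _intergenic_sampler(promoters: PromoterSet, config: SimConfig):
    """Closure sampling intervals that avoid every promoter, per chromosome."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        ivals = sorted(
            (s, e)
            for frags in promoters.intervals.values()
            for c, s, e in frags
            if c == chrom
        )
        starts[chrom] = np.array([s for s, _ in ivals])
        ends[chrom] = np.array([e for _, e in ivals])

    def sample(rng, ilen: int):
        for _ in range(1000):
            chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
            pos = int(rng.integers(0, config.chrom_length - ilen + 1))
            # overlap iff some promoter has start < pos+ilen and end > pos
            i = np.searchsorted(starts[chrom], pos + ilen, side="left")
            if i == 0 or ends[chrom][i - 1] <= pos:
                return chrom, pos, pos + ilen
        raise ConfigError("chrom_length leaves no intergenic space for noise intervals")

    return sample


def generate_tracks(
    config: SimConfig, genes: GeneModel, planted_set
) -> list[ElementTrack]:
    """Element tracks with planted enrichment/depletion in ``planted_set``.

    For each element, every gene's promoter is hit independently — with the
    baseline probability for background genes and the odds-multiplied one
    for genes in ``planted_set`` (typically disease plus held-out genes); a
    hit places ``intervals_per_hit`` intervals overlapping the promoter.
    ``n_intergenic_intervals`` further intervals land uniformly in
    promoter-free space. Deterministic per seed.
    """
    config.validate()
    if not config.elements:
        raise ConfigError("elements list is empty")
    planted_set = set(planted_set)
    unknown = planted_set - set(genes.gene_ids)
    if unknown:
        raise ConfigError(f"planted genes absent from gene model: {sorted(unknown)[:5]}")
    promoters = extract_promoters(genes, config.promoter_length)
    sample_intergenic = _intergenic_sampler(promoters, config)
    rng = np.random.default_rng([config.seed, _TRACKS_STREAM])
    tracks = []
    for spec in config.elements:
        p_planted = planted_probability(spec.baseline_hit_prob, spec.planted_odds_multiplier)
        k_lo, k_hi = _as_range(spec.intervals_per_hit, "intervals_per_hit")
        intervals: list[tuple[str, int, int]] = []
        for gid in promoters.gene_order:
            p = p_planted if gid in planted_set else spec.baseline_hit_prob
            if rng.random() < p:
                k = int(rng.integers(k_lo, k_hi + 1))
                for _ in range(k):
                    intervals.append(
                        _place_hit(rng, promoters.intervals[gid],
                                   spec.interval_length, config.chrom_length)
                    )
        for _ in range(spec.n_intergenic_intervals):
            intervals.append(sample_intergenic(rng, spec.interval_length))
        tracks.append(ElementTrack(element_id=spec.element_id, intervals=intervals))
    return tracks


@dataclass
class SimResult:
    """One full synthetic dataset."""

    config: SimConfig
    genes: GeneModel
    disease_set: set
    holdout_set: set
    tracks: list[ElementTrack]

    def write(self, outdir) -> None:
        """Write gene TSV, tracks BED, disease/holdout lists, and config YAML."""
        from pathlib import Path
        from .annotation import write_tracks_bed

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_tsv(outdir / "genes.tsv")
        write_tracks_bed(self.tracks, outdir / "tracks.bed")
        for fname, ids in (("disease_genes.txt", self.disease_set),
                           ("holdout_genes.txt", self.holdout_set)):
            (outdir / fname).write_text("".join(f"{g}\n" for g in sorted(ids)))
        self.config.to_yaml(outdir / "sim_config.yaml")


def simulate(config: SimConfig) -> SimResult:
    """Generate genome, disease/held-out sets, and tracks in one call."""
    genes = generate_genome(config)
    disease, holdout = generate_planted_sets(config, genes)
    tracks = generate_tracks(config, genes, disease | holdout)
    return SimResult(config=config, genes=genes, disease_set=disease,
                     holdout_set=holdout, tracks=tracks)
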