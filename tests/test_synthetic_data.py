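"""Synthetic generator: determinism, planted odds model, interval bounds."""

import numpy as np
import pytest

from epiprior.promoters import extract_promoters
from epiprior.synthetic_data import (
    ConfigError,
    ElementSpec,
    SimConfig,
    generate_disease_set,
    generate_genome,
    generate_planted_sets,
    generate_tracks,
    planted_probability,
    simulate,
)

from conftest import brute_force_counts


def _cfg(**kw):
    defaults = dict(
        seed=1, n_chromosomes=2, chrom_length=2_000_000, n_genes=100,
        n_disease_genes=20,
        elements=[ElementSpec(name="E0", baseline_hit_prob=0.2)],
    )
    defaults.update(kw)
    return SimConfig(**defaults)


# ------------------------------------------------------------------ genome


def test_genome_counts_and_determinism():
    cfg = _cfg(n_genes=100)
    gm1, gm2 = generate_genome(cfg), generate_genome(cfg)
    assert gm1.n_genes == 100
    assert gm1.records.equals(gm2.records)
    assert set(gm1.records.strand) <= {"+", "-"}
    assert (gm1.records.tss >= 0).all()


def test_genome_seed_changes_output():
    a = generate_genome(_cfg(seed=1)).records
    b = generate_genome(_cfg(seed=2)).records
    assert sorted(a.tss) != sorted(b.tss)


def test_transcript_counts_respect_config():
    gm = generate_genome(_cfg(transcripts_per_gene=3))
    assert (gm.records.groupby("gene_id").size() == 3).all()
    gm = generate_genome(_cfg(transcripts_per_gene=(1, 4)))
    sizes = gm.records.groupby("gene_id").size()
    assert sizes.between(1, 4).all()


@pytest.mark.parametrize(
    "kw,match",
    [
        (dict(n_genes=0), "n_genes"),
        (dict(chrom_length=1000, promoter_length=2000), "chrom_length"),
        (dict(n_disease_genes=200), "n_disease_genes"),
        (dict(elements=[ElementSpec(name="x", baseline_hit_prob=1.5)]), "baseline_hit_prob"),
        (dict(elements=[ElementSpec(name="x", planted_odds_multiplier=0)]), "odds_multiplier"),
    ],
)
def test_config_errors_name_the_field(kw, match):
    with pytest.raises(ConfigError, match=match):
        _cfg(**kw).validate()


# ------------------------------------------------------------- disease set


def test_disease_set_size_determinism_and_flag():
    cfg = _cfg(n_genes=100, n_disease_genes=25)
    gm = generate_genome(cfg)
    d1, d2 = generate_disease_set(cfg, gm), generate_disease_set(cfg, gm)
    assert len(d1) == 25 and d1 == d2
    assert d1 <= set(gm.gene_ids)
    with pytest.raises(ConfigError, match="allow_empty_disease_set"):
        _cfg(n_disease_genes=0).validate()
    empty_ok = _cfg(n_disease_genes=0, allow_empty_disease_set=True)
    assert generate_disease_set(empty_ok, generate_genome(empty_ok)) == set()


def test_holdout_disjoint_from_disease():
    cfg = _cfg(n_genes=100, n_disease_genes=20, n_holdout_genes=20)
    gm = generate_genome(cfg)
    disease, holdout = generate_planted_sets(cfg, gm)
    assert len(disease) == 20 and len(holdout) == 20
    assert not disease & holdout


# ------------------------------------------------------------------ tracks


def test_all_intervals_within_chromosome_bounds():
    cfg = _cfg(n_genes=200, elements=[
        ElementSpec(name="E0", baseline_hit_prob=0.3, intervals_per_hit=(1, 3)),
        ElementSpec(name="E1", element_class="histone_mark", baseline_hit_prob=0.1),
    ])
    sim = simulate(cfg)
    for track in sim.tracks:
        for chrom, s, e in track.intervals:
            assert 0 <= s < e <= cfg.chrom_length
            assert chrom in cfg.chrom_names


def test_background_hit_fraction_near_baseline():
    # realized background fraction within 3 binomial sd of the configured 0.2,
    # overlap recomputed by brute-force scan
    cfg = _cfg(n_genes=2000, n_chromosomes=4, chrom_length=10_000_000,
               n_disease_genes=250)
    sim = simulate(cfg)
    promoters = extract_promoters(sim.genes, cfg.promoter_length)
    background = [g for g in promoters.gene_order if g not in sim.disease_set]
    hits = sum(
        brute_force_counts(promoters.intervals[g], sim.tracks[0].intervals) >= 1
        for g in background
    )
    f = hits / len(background)
    sd = np.sqrt(0.2 * 0.8 / len(background))
    assert abs(f - 0.2) < 3 * sd


def test_null_multiplier_leaves_disease_and_background_indistinguishable():
    # two-proportion z-test pooled over replicate seeds at alpha=0.01
    from scipy.stats import norm

    d_hits = d_tot = b_hits = b_tot = 0
    for seed in range(5):
        cfg = _cfg(seed=seed, n_genes=500, n_chromosomes=2, chrom_length=5_000_000,
                   n_disease_genes=100)
        sim = simulate(cfg)
        promoters = extract_promoters(sim.genes, cfg.promoter_length)
        from epiprior.annotation import annotate_binary

        flags = annotate_binary(promoters, sim.tracks[0])
        in_disease = np.array([g in sim.disease_set for g in promoters.gene_order])
        d_hits += int(flags[in_disease].sum()); d_tot += int(in_disease.sum())
        b_hits += int(flags[~in_disease].sum()); b_tot += int((~in_disease).sum())
    p_pool = (d_hits + b_hits) / (d_tot + b_tot)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / d_tot + 1 / b_tot))
    z = (d_hits / d_tot - b_hits / b_tot) / se
    assert 2 * norm.sf(abs(z)) > 0.01


def test_planted_odds_transform_value_and_realized_rate():
    assert planted_probability(0.2, 3.0) == pytest.approx(3 * 0.25 / (1 + 3 * 0.25))
    assert planted_probability(0.2, 3.0) == pytest.approx(0.42857, abs=1e-4)
    assert planted_probability(0.2, 1.0) == pytest.approx(0.2)
    # realized disease-promoter hit rate near the transformed probability
    cfg = _cfg(seed=3, n_genes=1000, n_chromosomes=2, chrom_length=10_000_000,
               n_disease_genes=400,
               elements=[ElementSpec(name="E0", baseline_hit_prob=0.2,
                                     planted_odds_multiplier=3.0)])
    sim = simulate(cfg)
    promoters = extract_promoters(sim.genes, cfg.promoter_length)
    from epiprior.annotation import annotate_binary

    flags = annotate_binary(promoters, sim.tracks[0])
    in_disease = np.array([g in sim.disease_set for g in promoters.gene_order])
    rate = flags[in_disease].mean()
    sd = np.sqrt(0.42857 * (1 - 0.42857) / in_disease.sum())
    assert abs(rate - 0.42857) < 3 * sd


def test_tracks_require_elements_and_known_planted_genes():
    cfg = _cfg(elements=[])
    gm = generate_genome(_cfg())
    with pytest.raises(ConfigError, match="elements"):
        generate_tracks(cfg, gm, set())
    with pytest.raises(ConfigError, match="absent"):
        generate_tracks(_cfg(), gm, {"not-a-gene"})


def test_intergenic_intervals_avoid_promoters():
    cfg = _cfg(n_genes=50, elements=[
        ElementSpec(name="E0", baseline_hit_prob=0.01, n_intergenic_intervals=200)
    ])
    sim = simulate(cfg)
    promoters = extract_promoters(sim.genes, cfg.promoter_length)
    # nearly all intervals are intergenic here; none of those may touch a promoter
    all_frags = [f for frags in promoters.intervals.values() for f in frags]
    overlapping = brute_force_counts(all_frags, sim.tracks[0].intervals)
    n_hits_expected = len(sim.tracks[0].intervals) - 200  # planted ones only
    assert overlapping == n_hits_expected


def test_write_outputs_and_yaml_round_trip(tmp_path):
    cfg = _cfg(n_genes=30, n_disease_genes=5)
    sim = simulate(cfg)
    sim.write(tmp_path)
    assert (tmp_path / "genes.tsv").exists()
    assert (tmp_path / "tracks.bed").exists()
    listed = (tmp_path / "disease_genes.txt").read_text().split()
    assert set(listed) == sim.disease_set
    back = SimConfig.from_yaml(tmp_path / "sim_config.yaml")
    assert back == cfg
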