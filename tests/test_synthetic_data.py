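"""Generator contracts: determinism, coding, relatedness structure,
phenotype variance decomposition, and causal-variant placement."""

import numpy as np
import pandas as pd
import pytest

from modscreen import association
from modscreen.errors import InvalidConfigError
from modscreen.synthetic_data import (SimulationConfig, simulate_annotation,
                                      simulate_gene_sets, simulate_genotypes,
                                      simulate_phenotypes,
                                      simulate_rnai_experiment,
                                      simulate_screen)


def test_same_seed_bit_identical(small_cfg):
    g1 = simulate_genotypes(small_cfg)
    g2 = simulate_genotypes(small_cfg)
    assert g1.line_ids == g2.line_ids
    assert np.array_equal(g1.calls, g2.calls, equal_nan=True)
    pd.testing.assert_frame_equal(g1.variants, g2.variants)


def test_calls_homozygous_or_missing(small_screen):
    geno = small_screen[0]
    vals = geno.calls[~np.isnan(geno.calls)]
    assert set(np.unique(vals)) <= {0.0, 2.0}


def test_zero_missing_rate_gives_no_missing():
    cfg = SimulationConfig(n_lines=20, n_variants=50, missing_rate=0.0,
                           seed=1)
    geno = simulate_genotypes(cfg)
    assert not np.isnan(geno.calls).any()


def test_realized_maf_bounded():
    cfg = SimulationConfig(n_lines=40, n_variants=300, seed=2)
    geno = simulate_genotypes(cfg)
    af = geno.allele_freq()
    maf = np.fmin(af, 1 - af)
    assert np.all(maf >= 0) and np.all(maf <= 0.5)


def test_mean_realized_maf_near_range_midpoint():
    """Over 10000 variants the mean minor-allele frequency sits within
    0.01 of the midpoint of maf_range."""
    cfg = SimulationConfig(n_lines=200, n_variants=10_000, missing_rate=0.0,
                           seed=3)
    geno = simulate_genotypes(cfg)
    af = geno.allele_freq()
    maf = np.fmin(af, 1 - af)
    mid = sum(cfg.maf_range) / 2
    assert abs(maf.mean() - mid) < 0.01


def test_block_structure_visible_in_grm():
    """Mean within-block kinship exceeds mean between-block kinship,
    judged on K computed directly from the GRM formula."""
    cfg = SimulationConfig(n_lines=40, n_variants=2000, n_blocks=2,
                           missing_rate=0.0, seed=4)
    geno = simulate_genotypes(cfg)
    X = geno.calls
    Xc = X - X.mean(axis=0)
    K = Xc @ Xc.T / X.shape[1]          # independent direct computation
    block = np.arange(40) % 2
    same = block[:, None] == block[None, :]
    off = ~np.eye(40, dtype=bool)
    assert K[same & off].mean() > K[~same].mean()


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigError):
        SimulationConfig(n_lines=1).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(maf_range=(0.2, 0.7)).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(lambda_true=-0.5).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(tau_inv=0.0).validate()


# -- annotation -------------------------------------------------------------

def test_single_gene_annotation():
    genes = simulate_annotation(1, 100_000, seed=5)
    assert len(genes) == 1
    g = genes[0]
    for s, e in g.exons:
        assert g.start <= s <= e <= g.end


def test_annotation_deterministic_and_in_bounds():
    a = simulate_annotation(50, 1_000_000, seed=6)
    b = simulate_annotation(50, 1_000_000, seed=6)
    assert [(g.gene_id, g.start, g.end, g.strand, g.exons, g.utrs)
            for g in a] == \
           [(g.gene_id, g.start, g.end, g.strand, g.exons, g.utrs)
            for g in b]
    # brute-force interval scan of every feature
    for g in a:
        ivs = [(g.start, g.end)] + g.exons + g.utrs
        for s, e in ivs:
            assert 1 <= s <= e <= 1_000_000


def test_annotation_edge_cases_present():
    genes = simulate_annotation(20, 500_000, seed=7)
    gaps = [genes[i + 1].start - genes[i].end - 1 for i in range(19)]
    assert gaps[0] < 2000        # two genes closer than 2 kb
    assert gaps[1] >= 2000       # a >= 2 kb desert


def test_annotation_too_small_chromosome():
    with pytest.raises(InvalidConfigError):
        simulate_annotation(100, 10_000, seed=8)


# -- gene sets --------------------------------------------------------------

def test_gene_set_sizes_and_planted_id():
    genes = [f"G{i}" for i in range(100)]
    sets = simulate_gene_sets(genes, 20, (4, 50), "PL", seed=9,
                              planted_set_size=10)
    assert sets[0][0] == "PL" and len(sets[0][2]) == 10
    for _, _, members in sets:
        assert 4 <= len(members) <= 50 or len(members) == 10
        assert len(set(members)) == len(members)      # without replacement


def test_gene_set_overlap_matches_hypergeometric():
    """Mean overlap of two random size-10 sets from 100 genes is the
    hypergeometric expectation 10*10/100 = 1."""
    genes = [f"G{i}" for i in range(100)]
    overlaps = []
    for seed in range(1000):
        sets = simulate_gene_sets(genes, 3, (10, 10), "PL", seed=seed,
                                  planted_set_size=10)
        overlaps.append(len(set(sets[1][2]) & set(sets[2][2])))
    # Var of one overlap ~0.83; MC s.e. over 1000 draws ~0.03
    assert abs(np.mean(overlaps) - 1.0) < 0.12


def test_gene_set_oversize_rejected():
    with pytest.raises(InvalidConfigError):
        simulate_gene_sets(["a", "b"], 2, (1, 5), "PL", seed=0)


# -- phenotypes -------------------------------------------------------------

def test_noise_free_phenotypes_equal_baseline():
    cfg = SimulationConfig(n_lines=20, n_variants=100, n_genes=10,
                           chrom_length=100_000, n_sets=3,
                           set_size_range=(3, 5), planted_set_size=3,
                           n_causal=0, lambda_true=0.0, replicate_sd=0.0,
                           missing_rate=0.0, seed=10)
    _, _, _, pheno, truth = simulate_screen(cfg)
    assert np.allclose(pheno["eye_area_px"], cfg.baseline_px)
    assert np.allclose(truth.per_line_genetic_values, 0.0)


def test_single_causal_variant_separates_classes_by_2beta():
    cfg = SimulationConfig(n_lines=30, n_variants=200, n_genes=15,
                           chrom_length=150_000, n_sets=3,
                           set_size_range=(3, 6), planted_set_size=3,
                           n_causal=1, causal_effect_size=500.0,
                           lambda_true=0.0, replicate_sd=0.0,
                           missing_rate=0.0, seed=12)
    geno, genes, sets, pheno, truth = simulate_screen(cfg)
    vid = truth.causal_variant_ids[0]
    j = geno.variants.index[geno.variants["variant_id"] == vid][0]
    x = geno.calls[:, j]
    means = pheno.groupby("line_id")["eye_area_px"].mean()
    means = means.loc[geno.line_ids].to_numpy()
    gap = means[x == 2].mean() - means[x == 0].mean()
    assert gap == pytest.approx(np.sign(truth.causal_betas[0]) * 1000.0)


def test_replicate_counts_in_range(small_screen):
    pheno = small_screen[3]
    counts = pheno.groupby("line_id").size()
    assert counts.between(10, 15).all()


def test_variance_ratio_recovered_by_moment_estimator():
    """With beta=0 and replicate_sd^2 = tau_inv, a Haseman-Elston-style
    moment regression of strain-mean products on kinship recovers the
    planted variance ratio: Var(means)/tau_inv -> lambda + 1/r."""
    lam, tau_inv, r = 1.0, 1.0, 4
    ratios = []
    for seed in range(200):
        cfg = SimulationConfig(n_lines=60, n_variants=400, n_genes=10,
                               chrom_length=100_000, n_sets=2,
                               set_size_range=(3, 5), planted_set_size=3,
                               n_causal=0, lambda_true=lam, tau_inv=tau_inv,
                               replicate_sd=np.sqrt(tau_inv),
                               n_replicates_range=(r, r),
                               missing_rate=0.0, seed=seed)
        geno = simulate_genotypes(cfg)
        genes = []
        pheno, _ = simulate_phenotypes(geno, genes, [], cfg)
        means = pheno.groupby("line_id")["eye_area_px"].mean()
        means = means.loc[geno.line_ids].to_numpy()
        K = association.compute_grm(geno).K
        Kn = K / np.mean(np.diag(K))
        y = means - means.mean()
        # moment estimator: regress off-diagonal products on kinship
        iu = np.triu_indices(len(y), k=1)
        prod = np.outer(y, y)[iu]
        kin = Kn[iu]
        sigma_g2 = np.sum(kin * prod) / np.sum(kin * kin)
        ratios.append(sigma_g2 / tau_inv)
    assert abs(np.mean(ratios) - lam) / lam < 0.20


def test_causal_variants_lie_near_planted_genes(small_screen):
    geno, genes, sets, pheno, truth = small_screen
    planted = {g.gene_id: g for g in genes
               if g.gene_id in set(sets[0][2])}
    pos = geno.variants.set_index("variant_id")["pos"]
    for vid in truth.causal_variant_ids:
        p = pos[vid]
        assert any(g.start - 1000 <= p <= g.end + 1000
                   for g in planted.values())


# -- RNAi experiment --------------------------------------------------------

def test_rnai_no_effect_no_noise_identical_groups():
    table = simulate_rnai_experiment(17000, 0.0, [0, 0, 0], 5, seed=13)
    assert np.allclose(table["eye_area_px"], 17000)
    assert table["line_id"].nunique() == 4


def test_rnai_shift_and_determinism():
    t1 = simulate_rnai_experiment(17000, 100.0, [-1500.0], 15, seed=14)
    t2 = simulate_rnai_experiment(17000, 100.0, [-1500.0], 15, seed=14)
    pd.testing.assert_frame_equal(t1, t2)
    grp = t1[t1["line_id"] == "RNAi1"]["eye_area_px"]
    se = 100.0 / np.sqrt(15)
    assert abs(grp.mean() - (17000 - 1500)) < 5 * se


def test_rnai_invalid_params():
    with pytest.raises(InvalidConfigError):
        simulate_rnai_experiment(17000, -1.0, [0.0], 10, seed=0)
    with pytest.raises(InvalidConfigError):
        simulate_rnai_experiment(17000, 1.0, [0.0], 1, seed=0)
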