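"""Synthetic inbred-panel generator with known ground truth.

Emulates a DGRP-like mapping population: ~200 fully inbred (homozygous)
lines genotyped at common variants (MAF >= 0.05), block-structured
relatedness, per-strain replicate phenotype measurements (10-15
individuals per strain), and causal variants concentrated inside the
genes of one planted gene set so the downstream GWAS -> gene assignment
-> GSEA pipeline has a recoverable signal.

The quantitative phenotype follows the mixed-model decomposition used by
the association stage: the genetic value of line i is

    g_i = sum_k x_ik * beta_k + u_i,   u ~ MVN(0, lambda * tau_inv * Kn)

where Kn is the centered genetic relatedness matrix of the simulated
genotypes rescaled to unit mean diagonal (so ``lambda * tau_inv`` is the
average polygenic variance per line, in px^2). Each individual
measurement is ``baseline + g_i + N(0, replicate_sd^2)``; with
``replicate_sd^2 = tau_inv`` and r replicates per strain the strain
means have Var/tau_inv -> lambda + 1/r, the decomposition the
association stage estimates.

Every draw comes from one ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``; identical configs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .types import GeneAnnotation, PanelGenotypes, RelatednessMatrix


@dataclass
class SimulationConfig:
    """All knobs of the synthetic screen; the seed fixes every draw.

    Units: variances in px^2, effect sizes in px per alternate allele
    (genotypes coded 0/2, so a causal variant separates the two
    homozygote classes by ``2 * causal_effect_size``).
    """

    n_lines: int = 200
    n_variants: int = 5000
    n_blocks: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    lambda_true: float = 1.0
    tau_inv: float = 1.0e6
    replicate_sd: float = 400.0
    n_replicates_range: tuple[int, int] = (10, 15)
    n_causal: int = 8
    causal_effect_size: float = 800.0
    planted_set_id: str = "SET_PLANTED"
    seed: int = 0
    # substrate geometry for annotation / gene sets
    chrom: str = "2L"
    chrom_length: int = 3_000_000
    n_genes: int = 300
    n_sets: int = 50
    set_size_range: tuple[int, int] = (4, 30)
    planted_set_size: int = 10
    baseline_px: float = 14_000.0
    block_mutation_rate: float = 0.5

    def validate(self) -> "SimulationConfig":
        if self.n_lines < 2:
            raise InvalidConfigError("n_lines must be >= 2")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5) or lo == hi == 0:
            raise InvalidConfigError("maf_range must be within [0, 0.5]")
        if lo > hi or (hi - lo) < 0 or len(self.maf_range) != 2:
            raise InvalidConfigError("maf_range must be a (low, high) pair")
        if self.lambda_true < 0:
            raise InvalidConfigError("lambda_true must be >= 0")
        if self.tau_inv <= 0:
            raise InvalidConfigError("tau_inv must be > 0")
        if not (0 <= self.missing_rate < 1):
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.replicate_sd < 0:
            raise InvalidConfigError("replicate_sd must be >= 0")
        if self.n_blocks < 1 or self.n_blocks > self.n_lines:
            raise InvalidConfigError("n_blocks must be in [1, n_lines]")
        return self


@dataclass
class GroundTruth:
    """What the generator planted, for judging downstream recovery."""

    causal_variant_ids: list[str]
    causal_betas: list[float]
    planted_set_id: str
    per_line_genetic_values: np.ndarray
    causal_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.causal_variant_ids) != len(self.causal_betas):
            raise InvalidConfigError(
                "causal id and beta lists must have equal length")

    def to_json_dict(self) -> dict:
        return {
            "causal_variant_ids": list(self.causal_variant_ids),
            "causal_betas": [float(b) for b in self.causal_betas],
            "planted_set_id": self.planted_set_id,
            "per_line_genetic_values":
                [float(v) for v in self.per_line_genetic_values],
            "causal_genes": list(self.causal_genes),
        }


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genotypes(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> PanelGenotypes:
    """Simulate homozygous panel genotypes with block relatedness.

    Lines are split round-robin into ``n_blocks`` relatedness blocks. Per
    variant, an alternate-allele frequency is drawn uniformly from
    ``maf_range`` and each block receives an ancestral allele; a line
    copies its block's allele, or redraws a fresh allele with probability
    ``block_mutation_rate``. Within-block allele sharing therefore exceeds
    between-block sharing, making the relatedness matrix non-trivial.
    """
    cfg.validate()
    rng = rng if rng is not None else _rng(cfg.seed)
    n, m = cfg.n_lines, cfg.n_variants
    lo, hi = cfg.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    block_of = np.arange(n) % cfg.n_blocks
    ancestral = rng.random((cfg.n_blocks, m)) < freqs          # per block
    fresh = rng.random((n, m)) < freqs                         # per line
    mutate = rng.random((n, m)) < cfg.block_mutation_rate
    alleles = np.where(mutate, fresh, ancestral[block_of, :])
    calls = alleles.astype(float) * 2.0
    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = np.nan

    pos = np.sort(rng.choice(
        np.arange(1, cfg.chrom_length + 1), size=m, replace=False))
    # alternate simple SNP alleles so ref != alt everywhere
    refs = np.where(np.arange(m) % 2 == 0, "A", "C")
    alts = np.where(np.arange(m) % 2 == 0, "G", "T")
    variants = pd.DataFrame({
        "variant_id": [f"{cfg.chrom}_{p}_{r}_{a}"
                       for p, r, a in zip(pos, refs, alts)],
        "chrom": cfg.chrom,
        "pos": pos.astype(int),
        "ref": refs,
        "alt": [[a] for a in alts],
    })
    line_ids = [f"LINE{i:03d}" for i in range(1, n + 1)]
    return PanelGenotypes(line_ids, variants, calls)


def simulate_annotation(n_genes: int, chrom_length: int, seed,
                        chrom: str = "2L") -> list[GeneAnnotation]:
    """Simulate non-pathological gene models on one chromosome.

    Genes are laid out left to right with random spans (about 1.5-8 kb),
    each with 1-4 exons and optional UTRs at the span ends. Two deliberate
    edge cases are always present when space allows: the first two genes
    sit < 2 kb apart, and a >= 2 kb gene-free desert follows gene 2.
    """
    if n_genes < 1:
        raise InvalidConfigError("n_genes must be >= 1")
    rng = _rng(seed)
    # worst-case span 8 kb + max gap; require a loose fit up front
    if chrom_length < n_genes * 3000:
        raise InvalidConfigError(
            f"chrom_length {chrom_length} too small for {n_genes} genes")
    genes: list[GeneAnnotation] = []
    cursor = 1 + int(rng.integers(0, 500))
    for gi in range(n_genes):
        remaining = n_genes - gi
        max_start = chrom_length - remaining * 3000
        if cursor > max_start:
            cursor = max_start
        span = int(rng.integers(1500, 8001))
        span = min(span, chrom_length - cursor - (remaining - 1) * 3000)
        span = max(span, 1000)
        start, end = cursor, cursor + span - 1
        n_ex = int(rng.integers(1, 5))
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_ex - 2,
                                  replace=False)) if n_ex > 1 else np.array([])
        bounds = np.concatenate([[start], cuts, [end]]).astype(int)
        exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1]))
                 for i in range(n_ex)]
        strand = "+" if rng.random() < 0.5 else "-"
        utrs = []
        if rng.random() < 0.7 and exons[0][1] > exons[0][0]:
            utrs.append((exons[0][0],
                         exons[0][0] + min(150, exons[0][1] - exons[0][0])))
        if rng.random() < 0.7 and exons[-1][1] > exons[-1][0]:
            utrs.append((exons[-1][1] - min(150, exons[-1][1] - exons[-1][0]),
                         exons[-1][1]))
        genes.append(GeneAnnotation(f"G{gi + 1:04d}", chrom, start, end,
                                    strand, exons, sorted(utrs)))
        if gi == 0:
            gap = int(rng.integers(200, 1500))      # two genes < 2 kb apart
        elif gi == 1:
            gap = int(rng.integers(2500, 4000))     # >= 2 kb desert
        else:
            gap = int(rng.integers(200, 2500))
        cursor = end + 1 + gap
    return genes


def simulate_gene_sets(genes: list[str], n_sets: int,
                       size_range: tuple[int, int], planted_set_id: str,
                       seed, planted_set_size: int = 10
                       ) -> list[tuple[str, str, list[str]]]:
    """Draw random gene sets (GMT rows); the first set is the planted one.

    Sets sample genes without replacement; sizes are uniform on
    ``size_range``. The planted set has ``planted_set_size`` members and
    carries ``planted_set_id``.
    """
    lo, hi = size_range
    if hi > len(genes) or planted_set_size > len(genes):
        raise InvalidConfigError("requested set size exceeds gene count")
    if lo < 1 or lo > hi:
        raise InvalidConfigError("bad set size range")
    rng = _rng(seed)
    out = []
    members = [str(g) for g in
               rng.choice(genes, size=planted_set_size, replace=False)]
    out.append((planted_set_id, "planted modifier pathway", members))
    for si in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = [str(g) for g in rng.choice(genes, size=size, replace=False)]
        out.append((f"SET{si + 1:04d}", "random gene set", members))
    return out


def _variants_near_genes(geno: PanelGenotypes, genes: list[GeneAnnotation],
                         gene_ids: set[str], window: int = 1000) -> pd.DataFrame:
    """Variants within +/- window bp of any listed gene body, with the gene."""
    rows = []
    pos = geno.variants["pos"].to_numpy()
    for g in genes:
        if g.gene_id not in gene_ids:
            continue
        mask = ((geno.variants["chrom"] == g.chrom).to_numpy()
                & (pos >= g.start - window) & (pos <= g.end + window))
        for idx in np.nonzero(mask)[0]:
            rows.append((int(idx), g.gene_id))
    return pd.DataFrame(rows, columns=["variant_index", "gene_id"])


def simulate_phenotypes(geno: PanelGenotypes, annotation: list[GeneAnnotation],
                        gene_sets: list[tuple[str, str, list[str]]],
                        cfg: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate replicate phenotypes from planted causal variants.

    Causal variants are drawn from polymorphic variants lying within
    +/- 1 kb of distinct planted-set gene bodies (falling back to reusing
    genes if fewer genes than ``n_causal``). The polygenic term uses the
    centered relatedness matrix of the simulated genotypes.
    """
    cfg.validate()
    rng = rng if rng is not None else _rng(cfg.seed + 1)
    planted = [s for s in gene_sets if s[0] == cfg.planted_set_id]
    if cfg.n_causal > 0 and not planted:
        raise InvalidConfigError(
            f"planted set {cfg.planted_set_id!r} not in gene_sets")

    calls = geno.calls
    filled = np.where(np.isnan(calls), np.nanmean(calls, axis=0), calls)

    causal_idx: list[int] = []
    causal_genes: list[str] = []
    if cfg.n_causal > 0:
        near = _variants_near_genes(geno, annotation, set(planted[0][2]))
        poly = {i for i in range(geno.n_variants)
                if np.nanstd(calls[:, i]) > 0}
        near = near[near["variant_index"].isin(poly)]
        if len(near) < cfg.n_causal:
            raise InvalidConfigError(
                "not enough polymorphic variants near planted-set genes")
        # spread causals over distinct genes first
        for gene_id, grp in near.groupby("gene_id"):
            if len(causal_idx) >= cfg.n_causal:
                break
            pick = int(rng.choice(grp["variant_index"].to_numpy()))
            if pick not in causal_idx:
                causal_idx.append(pick)
                causal_genes.append(gene_id)
        pool = near[~near["variant_index"].isin(causal_idx)]
        while len(causal_idx) < cfg.n_causal and len(pool):
            row = pool.iloc[int(rng.integers(0, len(pool)))]
            causal_idx.append(int(row["variant_index"]))
            causal_genes.append(row["gene_id"])
            pool = pool[pool["variant_index"] != row["variant_index"]]

    betas = np.full(len(causal_idx), cfg.causal_effect_size)
    signs = rng.choice([-1.0, 1.0], size=len(causal_idx))
    betas = betas * signs

    g_fixed = filled[:, causal_idx] @ betas if causal_idx else \
        np.zeros(geno.n_lines)

    if cfg.lambda_true > 0:
        from .association import compute_grm
        K = compute_grm(geno).K
        K = K / np.mean(np.diag(K))          # unit mean diagonal
        cov = cfg.lambda_true * cfg.tau_inv * K
        u = rng.multivariate_normal(np.zeros(geno.n_lines), cov,
                                    method="eigh")
    else:
        u = np.zeros(geno.n_lines)
    g = g_fixed + u
    line_values = cfg.baseline_px + g

    lo, hi = cfg.n_replicates_range
    rows = []
    for i, line in enumerate(geno.line_ids):
        n_rep = int(rng.integers(lo, hi + 1))
        obs = line_values[i] + rng.normal(0.0, cfg.replicate_sd, size=n_rep)
        for r in range(n_rep):
            rows.append((line, "F", r + 1, obs[r]))
    pheno = pd.DataFrame(rows, columns=["line_id", "sex", "replicate",
                                        "eye_area_px"])

    truth = GroundTruth(
        causal_variant_ids=[geno.variants["variant_id"].iloc[i]
                            for i in causal_idx],
        causal_betas=list(betas),
        planted_set_id=cfg.planted_set_id,
        per_line_genetic_values=g,
        causal_genes=causal_genes,
    )
    return pheno, truth


def simulate_rnai_experiment(control_mean: float, control_sd: float,
                             effects: list[float], n_per_group: int,
                             seed, group_ids: list[str] | None = None,
                             control_id: str = "control") -> pd.DataFrame:
    """Simulate a knockdown validation: one control, k treatment groups.

    Each group draws ``n_per_group`` normal observations; treatment group
    j is shifted by ``effects[j]`` px from the control mean.
    """
    if control_sd < 0:
        raise InvalidConfigError("control_sd must be >= 0")
    if n_per_group < 2:
        raise InvalidConfigError("n_per_group must be >= 2")
    rng = _rng(seed)
    if group_ids is None:
        group_ids = [f"RNAi{j + 1}" for j in range(len(effects))]
    rows = []
    obs = control_mean + rng.normal(0.0, control_sd, size=n_per_group) \
        if control_sd > 0 else np.full(n_per_group, control_mean)
    for r, v in enumerate(obs):
        rows.append((control_id, "F", r + 1, v))
    for gid, eff in zip(group_ids, effects):
        obs = control_mean + eff + (
            rng.normal(0.0, control_sd, size=n_per_group)
            if control_sd > 0 else np.zeros(n_per_group))
        for r, v in enumerate(obs):
            rows.append((gid, "F", r + 1, v))
    return pd.DataFrame(rows, columns=["line_id", "sex", "replicate",
                                       "eye_area_px"])


def simulate_screen(cfg: SimulationConfig):
    """Generate one full synthetic screen: genotypes, annotation, sets,
    phenotypes, truth. Convenience wrapper used by the pipeline."""
    cfg.validate()
    geno = simulate_genotypes(cfg)
    genes = simulate_annotation(cfg.n_genes, cfg.chrom_length,
                                seed=cfg.seed + 101, chrom=cfg.chrom)
    sets = simulate_gene_sets([g.gene_id for g in genes], cfg.n_sets,
                              cfg.set_size_range, cfg.planted_set_id,
                              seed=cfg.seed + 202,
                              planted_set_size=cfg.planted_set_size)
    pheno, truth = simulate_phenotypes(geno, genes, sets, cfg)
    return geno, genes, sets, pheno, truth


def config_from_dict(d: dict) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise InvalidConfigError(f"unknown simulation keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("maf_range", "n_replicates_range", "set_size_range"):
        if key in d and isinstance(d[key], (list, tuple)):
            d[key] = tuple(d[key])
    return SimulationConfig(**d).validate()
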