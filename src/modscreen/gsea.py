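"""Variant-level gene set enrichment analysis.

Genes are scored by their best associated variant — score =
-log10(min Wald p over the gene's assigned variants) — and ranked in
descending order. For each gene set a weighted Kolmogorov-Smirnov
running sum walks the ranked list: set members ("hits") add
``|score|^weight_p`` normalized by the total over hits, non-members
subtract ``1/(N - N_H)``; the enrichment score ES is the running sum's
maximum signed deviation from zero. At ``weight_p = 0`` this is the
classical two-sample KS statistic on ranks.

Significance comes from a gene-label permutation null: each permutation
resamples N_H positions without replacement from the ranked list and
recomputes ES. The nominal p uses the add-one convention
``(1 + #{ES_perm >= ES_obs}) / (1 + n_perm)`` (mirrored for negative
observed ES); NES divides ES by the mean same-sign permuted ES, and
Benjamini-Hochberg corrects across sets. Reported sets must then pass
the screen's filters: ES > 0, more than 3 member genes present, and
corrected p < 0.05 — all strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .gene_assignment import INTERGENIC

log = logging.getLogger(__name__)


@dataclass
class GeneSetResult:
    set_id: str
    n_genes_present: int
    es: float
    nes: float
    p_nominal: float
    p_adjusted: float
    leading_edge: list[str]


def rank_genes(assignments: pd.DataFrame, assoc: pd.DataFrame
               ) -> pd.DataFrame:
    """Ranked gene list: descending -log10(min variant p) per gene.

    Intergenic variants are excluded. Ties are broken by lexicographic
    gene id so runs are reproducible. Returns columns
    ``gene_id, score``.
    """
    merged = assoc.merge(assignments, on="variant_id", how="inner")
    genic = merged[merged["gene_id"] != INTERGENIC].dropna(subset=["p_wald"])
    if len(genic) == 0:
        raise ValidationError("no gene-assigned variants to rank")
    min_p = genic.groupby("gene_id")["p_wald"].min()
    score = -np.log10(np.clip(min_p.to_numpy(), 1e-300, None))
    ranked = pd.DataFrame({"gene_id": min_p.index, "score": score})
    ranked = ranked.sort_values(["score", "gene_id"],
                                ascending=[False, True], ignore_index=True)
    return ranked


def enrichment_score(ranked: pd.DataFrame, gene_set: list[str],
                     weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    Errors if the set has no member in the ranked list, or contains the
    entire list (no misses to walk against).
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hit = np.isin(genes, list(set(gene_set)))
    n, n_h = len(genes), int(hit.sum())
    if n_h == 0:
        raise ValidationError("gene set has no member in the ranked list")
    if n_h == n:
        raise ValidationError("gene set covers the entire ranked list")
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:         # all member scores zero: fall back to equal steps
        hit_w = hit.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    dec = (~hit).astype(float) / (n - n_h)
    running = np.cumsum(inc - dec)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_from_hit_positions(idx: np.ndarray, weights: np.ndarray,
                           n: int) -> np.ndarray:
    """Vectorized ES for many permutations.

    ``idx``: (n_perm, n_h) sorted hit positions (0-based) in the ranked
    list; ``weights``: per-position weight profile (length n). The running
    sum's extrema can only occur immediately after a hit (local peak) or
    immediately before one (local trough), so only those 2 * n_h
    candidates are evaluated per permutation.
    """
    n_perm, n_h = idx.shape
    w = weights[idx]
    tot = w.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    cum = np.cumsum(w, axis=1) / tot
    miss = 1.0 / (n - n_h)
    j = np.arange(1, n_h + 1)
    after = cum - (idx + 1 - j) * miss          # value just after hit j
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (idx - (j - 1)) * miss
    cand = np.concatenate([after, before], axis=1)
    pick = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), pick]


def permutation_significance(ranked: pd.DataFrame,
                             sets: list[tuple[str, str, list[str]]],
                             n_perm: int = 1000, seed=0,
                             weight_p: float = 1.0
                             ) -> list[GeneSetResult]:
    """Permutation p values, NES and BH correction for every gene set.

    Sets with no member present in the ranked list are dropped (warning);
    an empty result list is returned if none remain.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(genes)
    weights = np.abs(scores) ** weight_p
    rng = np.random.default_rng(seed)

    tested = []
    in_list = set(genes)
    for set_id, _desc, members in sets:
        present = [g for g in dict.fromkeys(members) if g in in_list]
        n_h = len(present)
        if n_h == 0 or n_h == n:
            log.warning("permutation_significance: set %s skipped "
                        "(%d of %d genes present)", set_id, n_h, n)
            continue
        tested.append((set_id, present))
    if not tested:
        log.warning("permutation_significance: no testable sets")
        return []

    results = []
    null_cache: dict[int, np.ndarray] = {}
    for set_id, present in tested:
        n_h = len(present)
        es, running = enrichment_score(ranked, present, weight_p)
        if n_h not in null_cache:
            keys = rng.random((n_perm, n))
            idx = np.sort(np.argpartition(keys, n_h, axis=1)[:, :n_h], axis=1)
            null_cache[n_h] = _es_from_hit_positions(idx, weights, n)
        null = null_cache[n_h]
        if es >= 0:
            p_nom = (1 + int(np.sum(null >= es))) / (1 + n_perm)
            same = null[null > 0]
        else:
            p_nom = (1 + int(np.sum(null <= es))) / (1 + n_perm)
            same = null[null < 0]
        nes = float(es / np.mean(np.abs(same))) if len(same) else np.nan
        if es < 0:
            nes = -abs(nes) if not np.isnan(nes) else nes
        # leading edge: hits at or before the running-sum extremum
        peak = int(np.argmax(np.abs(running)))
        hit_mask = np.isin(genes, present)
        if es >= 0:
            le = [g for g in genes[: peak + 1][hit_mask[: peak + 1]]]
        else:
            le = [g for g in genes[peak:][hit_mask[peak:]]]
        results.append(GeneSetResult(set_id, n_h, float(es), nes,
                                     float(p_nom), np.nan, le))

    p_adj = multipletests([r.p_nominal for r in results],
                          method="fdr_bh")[1]
    for r, q in zip(results, p_adj):
        r.p_adjusted = float(min(max(q, r.p_nominal), 1.0))
    return results


def filter_results(results: list[GeneSetResult], es_min: float = 0.0,
                   min_genes: int = 4, p_adj_max: float = 0.05
                   ) -> list[GeneSetResult]:
    """The screen's reporting filters, all strict:

    ES > ``es_min`` (enriched at the top of the list), member genes
    present >= ``min_genes`` (default 4, i.e. "more than 3"), and
    corrected p < ``p_adj_max``.
    """
    return [r for r in results
            if r.es > es_min and r.n_genes_present >= min_genes
            and r.p_adjusted < p_adj_max]


def results_to_frame(results: list[GeneSetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_id, r.n_genes_present, r.es, r.nes, r.p_nominal,
          r.p_adjusted, ";".join(r.leading_edge)) for r in results],
        columns=["set_id", "n_genes_present", "es", "nes", "p_nominal",
                 "p_adjusted", "leading_edge"])


def frame_to_results(df: pd.DataFrame) -> list[GeneSetResult]:
    return [GeneSetResult(r.set_id, int(r.n_genes_present), float(r.es),
                          float(r.nes), float(r.p_nominal),
                          float(r.p_adjusted),
                          str(r.leading_edge).split(";")
                          if isinstance(r.leading_edge, str)
                          and r.leading_edge else [])
            for r in df.itertuples(index=False)]
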