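"""Variant-to-gene assignment with a +/- 1 kb window.

A variant belongs to a gene if it falls inside the gene body (span
including UTRs and introns) or within 1 kb of it (inclusive at exactly
1000 bp). Within a gene it is classified by feature: UTR (UTRs are
exonic subregions, so UTR outranks exon for the same base), exon, or
intron; outside, upstream/downstream by strand. When several genes claim
a variant, the gene giving the highest-priority category wins:

    exon > UTR > intron > upstream/downstream (one flank tier)

with equal-priority ties broken by smaller distance to the gene body,
then lexicographic gene id — so assignment never depends on input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import GeneAnnotation

WINDOW_BP = 1000

#: cross-gene priority; lower rank wins
_PRIORITY = {"exon": 0, "UTR": 1, "intron": 2, "upstream": 3, "downstream": 3}

INTERGENIC = "INTERGENIC"


@dataclass
class VariantAssignment:
    variant_id: str
    gene_id: str          # or INTERGENIC
    category: str         # exon | UTR | intron | upstream | downstream | intergenic
    distance_bp: int      # 0 inside the gene body


def classify_variant(chrom: str, pos: int, gene: GeneAnnotation,
                     window: int = WINDOW_BP) -> str | None:
    """Category of a position relative to one gene, or None if out of range."""
    if chrom != gene.chrom:
        return None
    if gene.start <= pos <= gene.end:
        for s, e in gene.utrs:
            if s <= pos <= e:
                return "UTR"
        for s, e in gene.exons:
            if s <= pos <= e:
                return "exon"
        return "intron"
    if gene.start - window <= pos < gene.start:
        return "upstream" if gene.strand == "+" else "downstream"
    if gene.end < pos <= gene.end + window:
        return "downstream" if gene.strand == "+" else "upstream"
    return None


def _distance(pos: int, gene: GeneAnnotation) -> int:
    if pos < gene.start:
        return gene.start - pos
    if pos > gene.end:
        return pos - gene.end
    return 0


def assign_variant(variant_id: str, chrom: str, pos: int,
                   genes: list[GeneAnnotation],
                   window: int = WINDOW_BP) -> VariantAssignment:
    """Assign one variant to its best gene (or INTERGENIC)."""
    best = None
    for g in genes:
        cat = classify_variant(chrom, pos, g, window)
        if cat is None:
            continue
        key = (_PRIORITY[cat], _distance(pos, g), g.gene_id)
        if best is None or key < best[0]:
            best = (key, g, cat)
    if best is None:
        return VariantAssignment(variant_id, INTERGENIC, "intergenic", -1)
    _, g, cat = best
    return VariantAssignment(variant_id, g.gene_id, cat, _distance(pos, g))


def assign_variants(variants: pd.DataFrame, genes: list[GeneAnnotation],
                    window: int = WINDOW_BP) -> pd.DataFrame:
    """Assign every variant; returns a table with one row per variant.

    ``variants`` needs columns ``variant_id, chrom, pos``. Genes are
    bucketed by chromosome and pre-sorted so the scan only visits genes
    whose window can contain the position.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    starts = {c: np.array([g.start for g in lst])
              for c, lst in by_chrom.items()}
    max_span = {c: max((g.end - g.start + 1) for g in lst)
                for c, lst in by_chrom.items()}
    rows = []
    for v in variants.itertuples(index=False):
        cands = by_chrom.get(v.chrom, [])
        if cands:
            # genes with start in (pos - window - max_span, pos + window]
            lo = np.searchsorted(starts[v.chrom],
                                 v.pos - window - max_span[v.chrom] + 1)
            hi = np.searchsorted(starts[v.chrom], v.pos + window,
                                 side="right")
            cands = cands[lo:hi]
        a = assign_variant(v.variant_id, v.chrom, v.pos, cands, window)
        rows.append((a.variant_id, a.gene_id, a.category, a.distance_bp))
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "category",
                                       "distance_bp"])


def candidate_genes(assignments: pd.DataFrame, assoc: pd.DataFrame,
                    p_cutoff: float = 1e-4
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group sub-threshold variants (p strictly below cutoff) by gene.

    Returns ``(candidates, intergenic_hits)``: candidates have columns
    ``gene_id, n_variants, min_p, variant_ids`` sorted by min_p ascending;
    intergenic hits are reported separately.
    """
    if not (0 < p_cutoff < 1):
        raise ValidationError(f"p_cutoff must be in (0, 1), got {p_cutoff}")
    merged = assoc.merge(assignments, on="variant_id", how="left")
    if merged["gene_id"].isna().any():
        missing = merged.loc[merged["gene_id"].isna(), "variant_id"].iloc[0]
        raise ValidationError(f"variant {missing!r} has no assignment")
    hits = merged[merged["p_wald"] < p_cutoff]
    inter = hits[hits["gene_id"] == INTERGENIC][
        ["variant_id", "chrom", "pos", "p_wald"]].reset_index(drop=True)
    genic = hits[hits["gene_id"] != INTERGENIC]
    rows = []
    for gene_id, grp in genic.groupby("gene_id"):
        rows.append((gene_id, len(grp), float(grp["p_wald"].min()),
                     ";".join(sorted(grp["variant_id"]))))
    cands = pd.DataFrame(rows, columns=["gene_id", "n_variants", "min_p",
                                        "variant_ids"])
    cands = cands.sort_values(["min_p", "gene_id"], ignore_index=True)
    return cands, inter
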