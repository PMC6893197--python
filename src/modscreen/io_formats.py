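"""Readers and writers for every external format the pipeline touches.

Formats: VCF 4.2 (GT-only homozygous diploid calls), line x variant
genotype TSV (values 0/2/NA, with a sibling ``.sites.tsv`` carrying variant
metadata), GFF3 gene models, GMT gene sets, per-individual phenotype CSV,
and the fixed-column association result TSV.

All readers reject malformed input with the offending line named rather
than silently repairing it. Coordinates are 1-based inclusive everywhere.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .types import (ASSOC_COLUMNS, PHENO_COLUMNS, GeneAnnotation,
                    PanelGenotypes, validate_phenotypes)

log = logging.getLogger(__name__)

MISSING_TSV = "NA"


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str | None = None,
                   het_policy: str = "missing") -> PanelGenotypes:
    """Read a panel genotype matrix from VCF or TSV.

    ``het_policy`` controls residual heterozygous calls: ``"missing"``
    (default; counted and logged) or ``"error"``. Inbred panels are
    near-isogenic, so heterozygotes are treated as no-calls by default.
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_vcf(path, het_policy)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str, het_policy: str) -> PanelGenotypes:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise ParseError(f"cannot open VCF: {exc}", path=str(path))
    line_ids = list(vcf.samples)
    meta_rows, calls_rows = [], []
    n_het = 0
    seen = set()
    for i, rec in enumerate(vcf):
        vid = rec.ID or f"{rec.CHROM}_{rec.POS}_{rec.REF}_{rec.ALT[0] if rec.ALT else '.'}"
        if vid in seen:
            raise ValidationError(f"duplicate variant id: {vid!r}")
        seen.add(vid)
        row = np.full(len(line_ids), np.nan)
        for j, gt in enumerate(rec.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue
            if a1 != a2:
                if het_policy == "error":
                    raise ValidationError(
                        f"heterozygous call at {vid} sample {line_ids[j]}")
                n_het += 1
                continue
            row[j] = 0.0 if a1 == 0 else 2.0
        meta_rows.append((vid, rec.CHROM, rec.POS, rec.REF, list(rec.ALT)))
        calls_rows.append(row)
    if n_het:
        log.warning("read_genotypes: %d heterozygous call(s) set to missing",
                    n_het)
    variants = pd.DataFrame(meta_rows,
                            columns=["variant_id", "chrom", "pos", "ref", "alt"])
    calls = (np.asarray(calls_rows).T if calls_rows
             else np.empty((len(line_ids), 0)))
    geno = PanelGenotypes(line_ids, variants, calls)
    geno.n_het_coerced = n_het
    return geno


def _read_genotype_tsv(path: str) -> PanelGenotypes:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse genotype TSV: {exc}", path=str(path))
    if df.columns[0] != "line_id":
        raise SchemaError("genotype TSV must start with a line_id column")
    line_ids = df["line_id"].tolist()
    variant_ids = list(df.columns[1:])
    mat = df.iloc[:, 1:].to_numpy()
    calls = np.full(mat.shape, np.nan)
    for j in range(mat.shape[1]):
        for i in range(mat.shape[0]):
            v = mat[i, j]
            if v == MISSING_TSV or v != v:
                continue
            if v not in ("0", "2", "0.0", "2.0"):
                raise ParseError(
                    f"bad genotype value {v!r} for {variant_ids[j]}",
                    path=str(path), line_number=i + 2)
            calls[i, j] = float(v)
    sites_path = _sites_path(path)
    if os.path.exists(sites_path):
        sites = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
        need = {"variant_id", "chrom", "pos", "ref", "alt"}
        if not need.issubset(sites.columns):
            raise SchemaError(f"sites file missing columns: "
                              f"{sorted(need - set(sites.columns))}")
        sites = sites.set_index("variant_id").loc[variant_ids].reset_index()
        variants = pd.DataFrame({
            "variant_id": variant_ids,
            "chrom": sites["chrom"],
            "pos": sites["pos"].astype(int),
            "ref": sites["ref"],
            "alt": [str(a).split(",") for a in sites["alt"]],
        })
    else:
        variants = pd.DataFrame(
            [_parse_variant_id(v) for v in variant_ids],
            columns=["variant_id", "chrom", "pos", "ref", "alt"])
    return PanelGenotypes(line_ids, variants, calls)


def _sites_path(path: str) -> str:
    base = str(path)
    if base.endswith(".tsv"):
        base = base[:-4]
    return base + ".sites.tsv"


def _parse_variant_id(vid: str):
    parts = vid.split("_")
    if len(parts) >= 4 and parts[-3].isdigit():
        chrom = "_".join(parts[:-3])
        return (vid, chrom, int(parts[-3]), parts[-2], parts[-1].split(","))
    return (vid, "unknown", 0, "N", ["N"])


def write_genotypes_vcf(geno: PanelGenotypes, path: str) -> None:
    """Write VCF 4.2 with GT-only homozygous diploid calls (0/0, 1/1, ./.)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=modscreen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.variants["chrom"]):
            sub = geno.variants[geno.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 10000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.line_ids) + "\n")
        for k, row in enumerate(geno.variants.itertuples(index=False)):
            gts = []
            for v in geno.calls[:, k]:
                if np.isnan(v):
                    gts.append("./.")
                elif v == 0:
                    gts.append("0/0")
                else:
                    gts.append("1/1")
            alt = ",".join(row.alt)
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                     f"{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def write_genotypes_tsv(geno: PanelGenotypes, path: str) -> None:
    """Write the line x variant matrix TSV plus its ``.sites.tsv`` sibling."""
    codes = np.where(np.isnan(geno.calls), MISSING_TSV,
                     np.where(geno.calls == 0, "0", "2"))
    df = pd.DataFrame(codes, columns=geno.variants["variant_id"])
    df.insert(0, "line_id", geno.line_ids)
    df.to_csv(path, sep="\t", index=False)
    sites = geno.variants.copy()
    sites["alt"] = [",".join(a) for a in sites["alt"]]
    sites.to_csv(_sites_path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation (GFF3)
# ---------------------------------------------------------------------------

def read_annotation(path: str) -> list[GeneAnnotation]:
    """Read gene models from GFF3 via an in-memory gffutils database.

    Genes without exons are rejected; child features outside the parent
    span raise :class:`ValidationError`. An empty file yields an empty
    list with a warning.
    """
    import gffutils

    if os.path.getsize(path) == 0 or _gff_featureless(path):
        log.warning("read_annotation: no features in %s", path)
        return []
    try:
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:
        raise ParseError(f"cannot parse GFF3: {exc}", path=str(path))
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons, utrs = [], []
        for child in db.children(g.id):
            if child.start < g.start or child.end > g.end:
                raise ValidationError(
                    f"feature {child.id} ({child.start}-{child.end}) outside "
                    f"parent gene {g.id} ({g.start}-{g.end})")
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype in ("five_prime_UTR", "three_prime_UTR"):
                utrs.append((child.start, child.end))
        if not exons:
            raise ValidationError(f"gene {g.id} has no exons")
        genes.append(GeneAnnotation(
            gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end,
            strand=g.strand if g.strand in "+-" else "+",
            exons=sorted(exons), utrs=sorted(utrs)))
    return genes


def _gff_featureless(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return False
    return True


def write_annotation(genes: Iterable[GeneAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\tmodscreen\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tmodscreen\texon\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.utrs):
                # 5' UTR sits on the transcription-start side of the gene
                five = (s == min(x for x, _ in g.utrs)) == (g.strand == "+")
                ftype = "five_prime_UTR" if five else "three_prime_UTR"
                fh.write(f"{g.chrom}\tmodscreen\t{ftype}\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.u{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file into ``(set_id, description, gene_ids)`` tuples.

    Duplicate genes within one set are removed (order preserved) with a
    warning; a line with fewer than three tab-separated fields is a
    :class:`ParseError`.
    """
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line has fewer than 3 fields",
                                 path=str(path), line_number=ln)
            set_id, desc, genes = fields[0], fields[1], fields[2:]
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                log.warning("read_gene_sets: duplicates removed in %s", set_id)
            sets.append((set_id, desc, deduped))
    return sets


def write_gene_sets(sets: Iterable[tuple[str, str, list[str]]],
                    path: str) -> None:
    with open(path, "w") as fh:
        for set_id, desc, genes in sets:
            fh.write("\t".join([set_id, desc] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# phenotypes (CSV)
# ---------------------------------------------------------------------------

def read_phenotypes(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"line_id": str, "sex": str})
    except Exception as exc:
        raise ParseError(f"cannot parse phenotype CSV: {exc}", path=str(path))
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    validate_phenotypes(df)[PHENO_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# association results (TSV)
# ---------------------------------------------------------------------------

def write_assoc_results(results: pd.DataFrame, path: str) -> None:
    """Write the fixed-column association TSV, 12 significant digits."""
    missing = [c for c in ASSOC_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"association table missing columns: {missing}")
    results[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False,
                                  float_format="%.12g")


def read_assoc_results(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str})
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"association table missing columns: {missing}")
    return df[ASSOC_COLUMNS]
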