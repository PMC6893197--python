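"""Core in-memory containers shared across the pipeline.

Genotypes are held as a dense ``line x variant`` float matrix with values
0.0 / 2.0 (homozygous reference / alternate) and ``nan`` for missing calls —
the natural coding for a panel of fully inbred lines where heterozygotes do
not occur. Variant metadata travels in a parallel :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: canonical column order of the association result table
ASSOC_COLUMNS = ["chrom", "pos", "variant_id", "n_obs", "af",
                 "beta", "se", "lambda_hat", "p_wald"]

#: canonical columns of the per-individual phenotype table
PHENO_COLUMNS = ["line_id", "sex", "replicate", "eye_area_px"]

#: canonical columns of the per-strain summary table
STRAIN_COLUMNS = ["line_id", "n", "mean_px", "median_px", "sd_px"]


@dataclass
class PanelGenotypes:
    """Homozygous genotype matrix for a panel of inbred lines.

    Parameters
    ----------
    line_ids : list of str
        Unique panel line identifiers, one per matrix row.
    variants : pandas.DataFrame
        One row per variant with columns ``variant_id, chrom, pos, ref, alt``;
        ``alt`` is a list of alternate allele strings (length 1 for
        biallelic sites).
    calls : numpy.ndarray
        ``(n_lines, n_variants)`` float array with entries 0.0, 2.0 or nan.
    """

    line_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line ids in panel")
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            dup = vid[vid.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant id: {dup!r}")
        if self.calls.shape != (len(self.line_ids), len(self.variants)):
            raise ValidationError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.variants)} variants")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def is_biallelic(self) -> np.ndarray:
        return np.asarray([len(a) == 1 for a in self.variants["alt"]])

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.calls), axis=0)

    def subset_variants(self, mask: np.ndarray) -> "PanelGenotypes":
        return PanelGenotypes(
            line_ids=list(self.line_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            calls=self.calls[:, np.asarray(mask)],
        )

    def subset_lines(self, line_ids: list[str]) -> "PanelGenotypes":
        index = {l: i for i, l in enumerate(self.line_ids)}
        rows = [index[l] for l in line_ids]
        return PanelGenotypes(
            line_ids=list(line_ids),
            variants=self.variants.copy(),
            calls=self.calls[rows, :],
        )


@dataclass
class GeneAnnotation:
    """One gene model: span, strand, exons and optional UTR intervals.

    Coordinates are 1-based inclusive throughout; ``exons`` and ``utrs`` are
    lists of ``(start, end)`` tuples contained in ``[start, end]``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in list(self.exons) + list(self.utrs):
            if s < self.start or e > self.end or s > e:
                raise ValidationError(
                    f"gene {self.gene_id}: child interval ({s}, {e}) outside "
                    f"gene span ({self.start}, {self.end})")

    def introns(self) -> list[tuple[int, int]]:
        """Gene span minus exons, as maximal 1-based inclusive intervals."""
        if not self.exons:
            return [(self.start, self.end)]
        out = []
        pos = self.start
        for s, e in sorted(self.exons):
            if s > pos:
                out.append((pos, s - 1))
            pos = max(pos, e + 1)
        if pos <= self.end:
            out.append((pos, self.end))
        return out


@dataclass
class RelatednessMatrix:
    """Centered marker-based genetic relatedness matrix K.

    Symmetric positive-semidefinite; row/column order follows ``line_ids``.
    """

    line_ids: list[str]
    K: np.ndarray

    def __post_init__(self):
        n = len(self.line_ids)
        if self.K.shape != (n, n):
            raise ValidationError("K shape does not match line count")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValidationError("K is not symmetric to 1e-10")
        tr = np.trace(self.K)
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(tr, 1.0):
            raise ValidationError(
                f"K is not positive semidefinite (min eigenvalue {w.min():g})")

    def subset(self, line_ids: list[str]) -> "RelatednessMatrix":
        index = {l: i for i, l in enumerate(self.line_ids)}
        rows = np.asarray([index[l] for l in line_ids])
        return RelatednessMatrix(list(line_ids), self.K[np.ix_(rows, rows)])


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check the per-individual phenotype table contract and return it.

    Columns ``line_id, sex, replicate, eye_area_px``; areas strictly
    positive; ``(line_id, sex, replicate)`` unique.
    """
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype table missing columns: {missing}")
    if (df["eye_area_px"] <= 0).any():
        bad = df.loc[df["eye_area_px"] <= 0].index[0]
        raise ValidationError(f"non-positive eye_area_px at row {bad}")
    key = df[["line_id", "sex", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate (line_id, sex, replicate): {tuple(dup)}")
    return df
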