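"""Strain-level phenotype summaries, background-effect ANOVA and
cross-model Pearson correlation.

The screen's first question is whether genetic background matters at all:
a one-way fixed-effects ANOVA of individual eye areas grouped by strain.
Strain means (or medians) then feed the association stage, and matched
strain means from two different sensitized models are compared by Pearson
correlation to ask whether the same backgrounds modify both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .types import STRAIN_COLUMNS, validate_phenotypes

log = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_pairs: int


def summarize_strains(pheno: pd.DataFrame,
                      sex_filter: str | None = None) -> pd.DataFrame:
    """Per-strain n / mean / median / SD of eye area.

    ``sex_filter`` keeps only rows of that sex before summarizing; strains
    left with zero observations are dropped with a warning. SD uses the
    n-1 denominator (0.0 for singleton strains).
    """
    validate_phenotypes(pheno)
    if len(pheno) == 0:
        raise ValidationError("empty phenotype table")
    df = pheno
    if sex_filter is not None:
        df = pheno[pheno["sex"] == sex_filter]
        dropped = set(pheno["line_id"]) - set(df["line_id"])
        if dropped:
            log.warning("summarize_strains: %d strain(s) dropped by sex "
                        "filter", len(dropped))
        if len(df) == 0:
            raise ValidationError(
                f"no observations left after sex filter {sex_filter!r}")
    g = df.groupby("line_id")["eye_area_px"]
    out = pd.DataFrame({
        "line_id": list(g.groups),
        "n": g.count().to_numpy(),
        "mean_px": g.mean().to_numpy(),
        "median_px": g.median().to_numpy(),
        "sd_px": g.std(ddof=1).fillna(0.0).to_numpy(),
    })
    return out.sort_values("line_id", ignore_index=True)[STRAIN_COLUMNS]


def strain_effect_anova(pheno: pd.DataFrame) -> AnovaResult:
    """One-way fixed-effects ANOVA: does strain explain eye-size variance?

    Individual observations are grouped by ``line_id``; requires at least
    two strains and a positive within-group degree of freedom.
    """
    validate_phenotypes(pheno)
    groups = [grp["eye_area_px"].to_numpy()
              for _, grp in pheno.groupby("line_id")]
    k, n = len(groups), len(pheno)
    if k < 2:
        raise ValidationError("ANOVA needs >= 2 strains")
    if n - k < 1:
        raise ValidationError("ANOVA needs residual degrees of freedom")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # zero within-group variance, zero between: F=0 p=1
        f, p = 0.0, 1.0
    return AnovaResult(f_stat=float(f), df_between=k - 1, df_within=n - k,
                       p_value=float(p))


def correlate_strain_means(a: pd.DataFrame, b: pd.DataFrame,
                           statistic: str = "mean") -> CorrelationResult:
    """Pearson correlation of matched strain summaries from two models.

    Strain summaries are inner-joined on exact ``line_id``; unmatched
    strains are dropped (count logged). ``statistic`` selects mean or
    median as the per-strain value. Two-sided t-based p value.
    """
    col = {"mean": "mean_px", "median": "median_px"}.get(statistic)
    if col is None:
        raise ValueError(f"statistic must be 'mean' or 'median', "
                         f"got {statistic!r}")
    merged = a[["line_id", col]].merge(b[["line_id", col]], on="line_id",
                                       suffixes=("_a", "_b"))
    n_dropped = (len(a) - len(merged)) + (len(b) - len(merged))
    if n_dropped:
        log.info("correlate_strain_means: %d unmatched strain(s) dropped",
                 n_dropped)
    if len(merged) < 3:
        raise ValidationError(
            f"need >= 3 shared strains, have {len(merged)}")
    r, p = stats.pearsonr(merged[f"{col}_a"], merged[f"{col}_b"])
    return CorrelationResult(r=float(r), p_value=float(p),
                             n_pairs=len(merged))


def strain_range(summary: pd.DataFrame, statistic: str = "mean") -> float:
    """Spread (max - min) of the per-strain statistic across the panel."""
    col = {"mean": "mean_px", "median": "median_px"}[statistic]
    if len(summary) == 0:
        raise ValidationError("empty strain summary")
    return float(summary[col].max() - summary[col].min())
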