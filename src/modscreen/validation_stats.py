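"""Dunnett's many-to-one comparisons for RNAi validation experiments.

Each knockdown group is compared to the shared control with a
pooled-variance two-sample t statistic. Family-wise adjusted two-sided p
values come from the joint null distribution of the k correlated t
statistics (the correlation is induced by the shared control mean and
the shared variance estimate, and handles unbalanced group sizes),
evaluated by seeded Monte Carlo:

    T_j = (Z_j - Z_0) / (S * sqrt(1/n_j + 1/n_0)),
    Z_j ~ N(0, 1/n_j) independent,  S^2 ~ chi2(nu)/nu,  nu = N - k - 1

and p_adj(j) = P(max_j |T_j| >= |t_obs,j|), with an add-one numerator so
no p is exactly zero. A group is called an enhancer (smaller eye =
stronger degeneration) or suppressor only when significant at ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import validate_phenotypes


@dataclass
class DunnettComparison:
    group_id: str
    n: int
    mean_diff: float
    t_stat: float
    p_adjusted: float
    direction: str  # enhancer | suppressor | ns


def dunnett_test(groups: pd.DataFrame, control_id: str,
                 alpha: float = 0.05, n_mc: int = 200_000,
                 seed=0) -> list[DunnettComparison]:
    """Many-to-one Dunnett comparisons of each group against the control.

    ``groups`` is a per-individual phenotype table whose ``line_id``
    column labels the experimental groups, one of which is the control.
    Every group needs n >= 2; the pooled variance must be positive.
    """
    validate_phenotypes(groups)
    ids = list(dict.fromkeys(groups["line_id"]))
    if control_id not in ids:
        raise ValidationError(f"control group {control_id!r} not present")
    treat_ids = [g for g in ids if g != control_id]
    if not treat_ids:
        raise ValidationError("need at least one treatment group")
    obs = {g: groups.loc[groups["line_id"] == g, "eye_area_px"]
           .to_numpy(dtype=float) for g in ids}
    for g, v in obs.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has n < 2")

    n0 = len(obs[control_id])
    mean0 = obs[control_id].mean()
    nu = sum(len(v) - 1 for v in obs.values())
    pooled = sum(((len(v) - 1) * np.var(v, ddof=1)) for v in obs.values()) / nu
    if pooled <= 0:
        raise ValidationError("zero pooled variance")
    s = np.sqrt(pooled)

    ns = np.array([len(obs[g]) for g in treat_ids])
    diffs = np.array([obs[g].mean() - mean0 for g in treat_ids])
    scale = s * np.sqrt(1.0 / ns + 1.0 / n0)
    t_obs = diffs / scale

    # joint null of the k correlated statistics, by Monte Carlo
    rng = np.random.default_rng(seed)
    z0 = rng.normal(0.0, np.sqrt(1.0 / n0), size=n_mc)
    zt = rng.normal(0.0, 1.0, size=(n_mc, len(treat_ids))) / np.sqrt(ns)
    ssim = np.sqrt(rng.chisquare(nu, size=n_mc) / nu)
    tsim = (zt - z0[:, None]) / (ssim[:, None] * np.sqrt(1.0 / ns + 1.0 / n0))
    max_abs = np.max(np.abs(tsim), axis=1)

    out = []
    for g, n, d, t in zip(treat_ids, ns, diffs, t_obs):
        p_adj = (1 + int(np.sum(max_abs >= abs(t)))) / (1 + n_mc)
        if p_adj < alpha:
            direction = "enhancer" if d < 0 else "suppressor"
        else:
            direction = "ns"
        out.append(DunnettComparison(group_id=g, n=int(n),
                                     mean_diff=float(d), t_stat=float(t),
                                     p_adjusted=float(p_adj),
                                     direction=direction))
    return out


def comparisons_to_frame(comps: list[DunnettComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.group_id, c.n, c.mean_diff, c.t_stat, c.p_adjusted, c.direction)
         for c in comps],
        columns=["group_id", "n", "mean_diff", "t_stat", "p_adjusted",
                 "direction"])
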