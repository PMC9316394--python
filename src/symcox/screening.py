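"""Covariate screening by Mann–Whitney U association with the death indicator.

Each covariate's values are split by the event indicator and compared with
the two-sample Mann–Whitney U test (midranks for ties, tie-corrected normal
approximation, optional continuity correction).  Covariates are ranked by
ascending two-sided p-value; binary covariates are screened identically —
the test degrades gracefully to a comparison of proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data_io import COVARIATES, Cohort


@dataclass(frozen=True)
class ScreeningResult:
    """Per-covariate U, tie-corrected z and two-sided p, sorted by p."""

    table: pd.DataFrame  # index: covariate; columns: U, z, p, rank

    @property
    def ranking(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]

    def to_csv(self) -> str:
        return self.table.to_csv()


def mann_whitney(
    values_event,
    values_no_event,
    continuity_correction: bool = True,
) -> tuple[float, float, float]:
    """Mann–Whitney U for the first group, with tie-corrected normal z and p.

    U counts, over all cross-group pairs, the pairs where the first group's
    value is smaller (ties count 1/2); equivalently it comes from the rank
    sum with midranks.  The z statistic uses the tie-corrected variance

        var(U) = n1·n2/12 · [(N+1) − Σ(t³−t)/(N(N−1))]

    and, by default, a 0.5 continuity correction; the two-sided p uses the
    normal approximation.  With every observation tied, z and the variance
    are 0 and p = 1.
    """
    x1 = np.asarray(values_event, dtype=float).ravel()
    x2 = np.asarray(values_no_event, dtype=float).ravel()
    n1, n2 = x1.size, x2.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x1, x2])
    ranks = rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    # U for the first group: number of (i, j) pairs with x1_i < x2_j (+ ties/2)
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mean_u = n1 * n2 / 2.0
    if var_u <= 0:
        return float(u1), 0.0, 1.0
    dev = u1 - mean_u
    if continuity_correction:
        dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    z = dev / math.sqrt(var_u)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return float(u1), float(z), p


def rank_covariates(
    cohort: Cohort,
    covariate_names: Sequence[str] | None = None,
    continuity_correction: bool = True,
) -> ScreeningResult:
    """Rank covariates by Mann–Whitney association with the death indicator.

    Covariates are sorted ascending by two-sided p, ties broken
    alphabetically by covariate name for reproducibility.
    """
    names = list(covariate_names) if covariate_names is not None else list(COVARIATES)
    unknown = [n for n in names if n not in cohort.df.columns]
    if unknown:
        raise KeyError(f"unknown covariates: {unknown}")
    ev = cohort.event == 1
    rows = []
    for name in names:
        x = cohort.column(name)
        u, z, p = mann_whitney(x[ev], x[~ev], continuity_correction)
        rows.append({"covariate": name, "U": u, "z": z, "p": p})
    table = (
        pd.DataFrame(rows)
        .sort_values(["p", "covariate"], kind="stable")
        .set_index("covariate")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return ScreeningResult(table=table)
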