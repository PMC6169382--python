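"""Summary statistics for cross and brood tables.

Pearson contingency chi-square (no continuity correction, so the
degrees of freedom and statistic match standard software defaults),
egg-viability percentages, and per-colony three-allele proportions
with the headline mean/range figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountTable",
    "chisq_contingency",
    "viability_summary",
    "colony_proportions",
    "ColonyProportions",
]


@dataclass
class CountTable:
    """A labelled contingency table of non-negative integer counts."""

    rows: list
    cols: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape must match row/column labels")
        if self.counts.min() < 0:
            raise ValueError("counts must be >= 0")
        if min(self.counts.shape) < 2:
            raise ValueError("table must be at least 2x2")


def chisq_contingency(table) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence.

    Accepts a :class:`CountTable` or a 2-D array. Returns
    ``(statistic, df, p)`` with ``df = (r-1)(c-1)`` and no continuity
    correction. Raises on any zero marginal (expected counts would be
    undefined).
    """
    obs = table.counts if isinstance(table, CountTable) else np.asarray(table)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need a 2-D table at least 2x2")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def viability_summary(rows: Sequence[Tuple[int, int]]) -> list:
    """Hatch percentages, one per ``(scored, hatched)`` row.

    Returns ``100 * hatched / scored`` rounded to one decimal, the
    form egg-viability tables print. Requires ``scored > 0`` and
    ``hatched <= scored``.
    """
    out = []
    for scored, hatched in rows:
        if scored <= 0:
            raise ValueError("scored must be > 0")
        if hatched > scored:
            raise ValueError("hatched cannot exceed scored")
        out.append(round(100.0 * hatched / scored, 1))
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ColonyProportions:
    """Per-colony three-allele percentages and headline figures.

    ``per_colony`` holds one-decimal percentages keyed by colony;
    ``mean_pct``/``min_pct``/``max_pct`` are the headline integers
    (unweighted mean of per-colony percentages, rounded half-up).
    """

    per_colony: dict
    mean_pct: int
    min_pct: int
    max_pct: int


def colony_proportions(counts: Mapping[str, Tuple[int, int]]) -> ColonyProportions:
    """Fraction of three-allele progeny per colony and across colonies.

    ``counts`` maps colony label -> ``(two_allele, three_allele)``
    progeny counts. The headline mean is the unweighted mean of
    per-colony percentages, not the pooled proportion: colonies are
    the sampling unit.
    """
    if not counts:
        raise ValueError("no colonies given")
    per = {}
    for colony, (two, three) in counts.items():
        total = two + three
        if total <= 0:
            raise ValueError(f"colony {colony}: no progeny")
        per[colony] = round(100.0 * three / total, 1)
    vals = [100.0 * three / (two + three) for two, three in counts.values()]
    return ColonyProportions(
        per_colony=per,
        mean_pct=_round_half_up(float(np.mean(vals))),
        min_pct=_round_half_up(min(vals)),
        max_pct=_round_half_up(max(vals)),
    )
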