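"""Small quantitative formulas: PSI from band intensities, isoform ratios,
percent change, two-group t-tests, and predicted-vs-measured concordance.

RT-PCR band intensities are proportional to molar amount x product length,
so PSI from a gel is computed on length-normalized (molar) intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class IsoformBand:
    """One gel band: measured intensity and the PCR product length (nt)."""

    label: str
    intensity: float
    product_length: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"band {self.label}: negative intensity")
        if self.product_length <= 0:
            raise ValueError(f"band {self.label}: product length must be positive")

    @property
    def molar(self) -> float:
        return self.intensity / self.product_length


class UndefinedStatistic(ValueError):
    """The requested quantity is undefined for these inputs."""


def psi_from_bands(inclusion: IsoformBand, skipping: IsoformBand) -> float:
    """PSI = molar inclusion / (molar inclusion + molar skipping)."""
    denom = inclusion.molar + skipping.molar
    if denom == 0:
        raise UndefinedStatistic("both band intensities are zero; PSI undefined")
    return inclusion.molar / denom


def psi_iiib(iiib: float, iiic: float) -> float:
    """Mutually-exclusive-exon inclusion ratio IIIb / (IIIb + IIIc) on molar
    amounts."""
    if iiib < 0 or iiic < 0:
        raise ValueError("amounts must be non-negative")
    if iiib + iiic == 0:
        raise UndefinedStatistic("both isoform amounts are zero; ratio undefined")
    return iiib / (iiib + iiic)


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one group: mean, sample SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("n must be a positive integer")


def percent_change(reference: GroupStats, test: GroupStats) -> float:
    """Percent reduction of the test group relative to the reference mean:
    100 x (ref - test) / ref. Negative values indicate an increase."""
    if reference.mean <= 0:
        raise UndefinedStatistic("reference mean must be positive")
    return 100.0 * (reference.mean - test.mean) / reference.mean


def t_test_two_tailed(
    g1: GroupStats, g2: GroupStats, variance: str = "pooled"
) -> tuple[float, float]:
    """Unpaired two-tailed t-test from group summaries.

    ``variance='pooled'`` is the classical Student test (df = n1 + n2 - 2);
    ``'welch'`` uses the Welch-Satterthwaite approximation. The '+-' values
    reported alongside group means are taken as sample SDs.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("each group needs n >= 2")
    if variance not in ("pooled", "welch"):
        raise ValueError("variance must be 'pooled' or 'welch'")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, 1.0
        raise UndefinedStatistic("zero variance with unequal means")
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n,
        equal_var=(variance == "pooled"),
    )
    return float(t), float(p)


def concordance(predicted, measured) -> tuple[float, float]:
    """Pearson correlation (r, two-tailed p) between predicted and measured
    delta-PSI vectors; p from the t transform with n - 2 df."""
    predicted = list(map(float, predicted))
    measured = list(map(float, measured))
    if len(predicted) != len(measured):
        raise ValueError("vectors must have equal length")
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs")
    if any(not math.isfinite(v) for v in predicted + measured):
        raise ValueError("values must be finite")
    if len(set(predicted)) == 1 or len(set(measured)) == 1:
        raise UndefinedStatistic("zero variance in one vector; correlation undefined")
    res = stats.pearsonr(predicted, measured)
    return float(res.statistic), float(res.pvalue)
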