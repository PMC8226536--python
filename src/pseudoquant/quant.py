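"""The quantification stack: CT calling, ddCT fold change, standard-curve
efficiency, digital-PCR Poisson quantification, and group comparison.

Relative quantification follows the Livak 2^-ddCT convention: per-sample
dCT = mean target CT - mean reference CT (lower dCT = more transcript),
ddCT = group mean difference, fold change = 2^-ddCT. Amplification
efficiency from a dilution series is E = 10^(-1/slope) - 1 and is reported
but never used to correct fold changes. Digital PCR inverts the Poisson
partition model, lambda = -ln(negatives/total); the 95% CI is a
Clopper-Pearson binomial interval on positive partitions pushed through the
same transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

DEFAULT_CT_THRESHOLD = 0.15
#: default partition count and per-partition volume (uL) of a 26k nanoplate;
#: the volume is a documented assumption of this package, not a vendor value.
DEFAULT_PARTITIONS = 26_000
DEFAULT_PARTITION_VOLUME_UL = 0.00091


@dataclass
class CtCall:
    ct: float
    censored: bool = False


@dataclass
class CtMeasurement:
    """Replicate threshold cycles for one sample x assay."""

    sample_id: str
    assay_id: str
    cts: Tuple[float, ...]
    group: Optional[str] = None
    genotype: Optional[dict] = None

    def __post_init__(self):
        if not self.cts:
            raise ValueError("at least one CT replicate required")
        for ct in self.cts:
            if not (0 < ct <= 40):
                raise ValueError(f"CT {ct} outside (0, 40]")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))


@dataclass
class DeltaCt:
    sample_id: str
    target_assay: str
    reference_assay: str
    delta_ct: float


@dataclass
class FoldChange:
    delta_delta_ct: float
    fold_change: float


@dataclass
class DilutionSeries:
    slope: float
    intercept: float
    efficiency: float
    r_squared: float


@dataclass
class DpcrResult:
    total_partitions: int
    positive_partitions: int
    partition_volume_ul: float
    lam: float
    copies_per_ul: float
    ci_low: float
    ci_high: float
    saturated: bool = False


@dataclass
class FractionEstimate:
    target_copies_per_ul: float
    pool_copies_per_ul: float
    fraction: float


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    variant: str


def ct_from_curve(
    fluorescence: Sequence[float],
    threshold: float = DEFAULT_CT_THRESHOLD,
    cycles: Optional[Sequence[float]] = None,
) -> CtCall:
    """Threshold cycle by linear interpolation of the first crossing.

    ``cycles`` defaults to 1..n. A curve that never reaches the threshold is
    censored at the last cycle (flagged, not an error).
    """
    f = np.asarray(fluorescence, dtype=float)
    x = np.asarray(cycles, dtype=float) if cycles is not None else np.arange(1, len(f) + 1, dtype=float)
    if len(f) != len(x) or len(f) < 2:
        raise ValueError("need matching cycle/fluorescence arrays of length >= 2")
    if f[0] >= threshold:
        return CtCall(float(x[0]))
    above = np.nonzero(f >= threshold)[0]
    if len(above) == 0:
        return CtCall(float(x[-1]), censored=True)
    i = int(above[0])
    frac = (threshold - f[i - 1]) / (f[i] - f[i - 1])
    return CtCall(float(x[i - 1] + frac * (x[i] - x[i - 1])))


def delta_ct(target: CtMeasurement, reference: CtMeasurement) -> DeltaCt:
    """Per-sample normalized dCT = mean(target CTs) - mean(reference CTs)."""
    if target.sample_id != reference.sample_id:
        raise ValueError(
            f"sample mismatch: {target.sample_id!r} vs {reference.sample_id!r}"
        )
    return DeltaCt(
        target.sample_id,
        target.assay_id,
        reference.assay_id,
        target.mean_ct - reference.mean_ct,
    )


def fold_change(group_a: Sequence[float], group_b: Sequence[float]) -> FoldChange:
    """Livak fold change of group a relative to group b from per-sample dCTs."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ddct = float(a.mean() - b.mean())
    return FoldChange(ddct, 2.0 ** (-ddct))


def efficiency_from_dilution(points: Sequence[Tuple[float, float]]) -> DilutionSeries:
    """Fit CT on log10 relative input; E = 10^(-1/slope) - 1.

    E = 1 is perfect per-cycle doubling (slope = -1/log10(2) ~ -3.32).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in log10 inputs")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("flat dilution series: efficiency undefined")
    eff = 10.0 ** (-1.0 / res.slope) - 1.0
    return DilutionSeries(float(res.slope), float(res.intercept), float(eff), float(res.rvalue**2))


def dpcr_quantify(
    positives: int,
    total_partitions: int,
    partition_volume_ul: float = DEFAULT_PARTITION_VOLUME_UL,
) -> DpcrResult:
    """Absolute concentration from digital-PCR partition counts.

    lambda = -ln(negatives/total) mean copies per partition; concentration
    = lambda / partition volume. Saturated plates (all positive) are
    flagged with infinite estimates rather than raising.
    """
    if not (0 <= positives <= total_partitions):
        raise ValueError("positives must lie in [0, total_partitions]")
    if partition_volume_ul <= 0:
        raise ValueError("partition volume must be positive")
    n, k = total_partitions, positives
    if k == n:
        return DpcrResult(n, k, partition_volume_ul, math.inf, math.inf,
                          float(-math.log(1 - stats.beta.ppf(0.025, k, 1)) / partition_volume_ul)
                          if k else 0.0,
                          math.inf, saturated=True)
    lam = -math.log((n - k) / n)
    p_lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    p_hi = float(stats.beta.ppf(0.975, k + 1, n - k))
    lam_lo = -math.log1p(-p_lo)
    lam_hi = -math.log1p(-p_hi) if p_hi < 1 else math.inf
    v = partition_volume_ul
    return DpcrResult(n, k, v, lam, lam / v, lam_lo / v, lam_hi / v)


def pool_fraction(target: DpcrResult, pool: DpcrResult) -> FractionEstimate:
    """Fraction of a target species within a total RNA pool (copies/uL ratio)."""
    if pool.copies_per_ul <= 0:
        raise ValueError("pool concentration must be positive")
    return FractionEstimate(
        target.copies_per_ul, pool.copies_per_ul, target.copies_per_ul / pool.copies_per_ul
    )


def replicate_consistency(fractions: Sequence[float]) -> dict:
    """Spread of pool-fraction estimates across template-input replicates."""
    f = np.asarray(fractions, dtype=float)
    return {
        "n": int(f.size),
        "mean": float(f.mean()),
        "sd": float(f.std(ddof=1)) if f.size > 1 else 0.0,
        "range": float(f.max() - f.min()),
    }


def mmp_fold_change(
    red_treated: float, green_treated: float, red_untreated: float, green_untreated: float
) -> float:
    """Membrane-potential fold change: ratio of red/green dye ratios."""
    for v in (red_treated, green_treated, red_untreated, green_untreated):
        if v <= 0:
            raise ValueError("fluorescence intensities must be positive")
    return (red_treated / green_treated) / (red_untreated / green_untreated)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "student",
) -> TTestResult:
    """Two-sided independent-samples t-test (student default, welch available)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue),
                       float(a.mean()), float(b.mean()), variant)
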