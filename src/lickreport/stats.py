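"""Inferential layer: normality screening and rank-based comparisons.

Session-level rates are bounded and typically non-normal, so the
pipeline screens with a one-sample Kolmogorov-Smirnov test (informational
only) and then compares conditions nonparametrically: two-sided Wilcoxon
signed-rank tests at alpha = 0.025 for paired lick-vs-reflex contrasts,
Bonferroni-corrected when a family of intensities is tested, and a
one-sided Mann-Whitney U test at alpha = 0.05 for the unpaired
test-vs-control (595 nm) session comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "normality_screen",
    "paired_rank_compare",
    "control_session_compare",
]

#: Paired lick-vs-reflex contrasts use this two-sided significance level.
PAIRED_ALPHA = 0.025
#: The unpaired control-session comparison uses this one-sided level.
CONTROL_ALPHA = 0.05
#: Exact signed-rank null below this n (no ties/zeros); else normal approx.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class ComparisonResult:
    comparison_id: str
    statistic: float
    p_value: float
    alpha: float
    n_comparisons: int
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.n_comparisons < 1:
            raise ValueError("Bonferroni family size must be >= 1")

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.n_comparisons

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha


def normality_screen(sample: Sequence[float], alpha: float = 0.05) -> bool:
    """One-sample KS screen against a fitted normal; True = rejected.

    The sample is standardized by its own mean and SD before testing,
    mirroring the usual use of the one-sample KS test as a pre-check.
    The pipeline proceeds nonparametrically regardless; the flag is
    informational.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality screen needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return True  # a point mass is maximally non-normal
    z = (x - x.mean()) / sd
    return bool(sps.kstest(z, "norm").pvalue < alpha)


def paired_rank_compare(
    a: Sequence[float],
    b: Sequence[float],
    comparison_id: str = "paired",
    alpha: float = PAIRED_ALPHA,
    family: int = 1,
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test with Bonferroni correction.

    The exact null distribution is used for n <= 25 when differences
    carry no zeros or tied magnitudes; otherwise the normal
    approximation with continuity correction.  All-zero differences are
    reported as p = 1 with a note (the test is undefined there).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        return ComparisonResult(
            comparison_id, 0.0, 1.0, alpha, family, note="all differences zero"
        )
    nz = d[d != 0]
    exact = len(nz) <= EXACT_N_MAX and len(np.unique(np.abs(nz))) == len(nz)
    res = sps.wilcoxon(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=not exact,
        zero_method="wilcox",
    )
    return ComparisonResult(
        comparison_id, float(res.statistic), float(res.pvalue), alpha, family
    )


def control_session_compare(
    control_hit_rates: Sequence[float],
    test_hit_rates: Sequence[float],
    comparison_id: str = "control_vs_test",
    alpha: float = CONTROL_ALPHA,
) -> ComparisonResult:
    """One-sided Mann-Whitney U: are test-session hit rates larger than
    control (595 nm) session hit rates?"""
    control = np.asarray(control_hit_rates, dtype=float)
    test = np.asarray(test_hit_rates, dtype=float)
    if control.size == 0 or test.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(test, control, alternative="greater")
    return ComparisonResult(
        comparison_id, float(res.statistic), float(res.pvalue), alpha, 1
    )
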