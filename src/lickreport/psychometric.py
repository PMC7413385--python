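"""Cumulative-Gaussian psychometric fitting with guess and lapse rates.

Detection probability as a function of irradiance I is modeled as

    p(I) = gamma + (1 - gamma - lambda) * Phi((log10 I - mu) / sigma)

with location ``mu`` (log10 mW/mm^2), spread ``sigma`` (log10 units),
guess rate ``gamma`` (lower asymptote, bounded [0, 0.5]) and lapse rate
``lambda`` (upper-asymptote deficit, bounded [0, 0.1]).  Parameters are
estimated by maximum binomial likelihood with multi-start bounded
L-BFGS-B, which is deterministic for fixed starting points.  Fitting
uses optogenetic (target) trials only; the catch-trial false-alarm rate
is carried along as a fixed reference line, not as a constraint on the
asymptote.

The detection threshold is defined as the intensity at the midpoint of
the curve's range, which for this parameterization is simply 10**mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychFit",
    "NearThresholdBand",
    "DegenerateFitError",
    "fit_psychometric",
    "extract_threshold",
    "near_threshold_band",
    "psychometric_curve",
]


class DegenerateFitError(ValueError):
    """Raised when a threshold is requested from a flat/degenerate fit."""


def psychometric_curve(
    intensities: np.ndarray, mu: float, sigma: float, gamma: float, lam: float
) -> np.ndarray:
    """Evaluate p(I) on an irradiance grid (mW/mm^2)."""
    x = np.log10(np.asarray(intensities, dtype=float))
    return gamma + (1.0 - gamma - lam) * norm.cdf((x - mu) / sigma)


@dataclass
class PsychFit:
    location_mu: float
    spread_sigma: float
    guess_gamma: float
    lapse_lambda: float
    neg_log_likelihood: float
    intensities: np.ndarray
    fitted_probabilities: np.ndarray
    fa_reference: Optional[float] = None
    degenerate: bool = False

    @property
    def threshold_mw_mm2(self) -> float:
        if self.degenerate:
            raise DegenerateFitError("flat data: threshold undefined")
        return 10.0 ** self.location_mu

    @property
    def fitted_curve(self) -> dict[float, float]:
        return dict(zip(self.intensities.tolist(), self.fitted_probabilities.tolist()))


@dataclass(frozen=True)
class NearThresholdBand:
    """Contiguous intensities whose normalized detection probability
    Phi((log10 I - mu)/sigma) falls inside [low, high]."""

    member_intensities: tuple[float, ...]
    low: float
    high: float

    def __contains__(self, intensity: float) -> bool:
        return any(math.isclose(intensity, m) for m in self.member_intensities)


def _nll(
    theta: np.ndarray, x: np.ndarray, n: np.ndarray, k: np.ndarray
) -> float:
    mu, sigma, gamma, lam = theta
    p = gamma + (1.0 - gamma - lam) * norm.cdf((x - mu) / sigma)
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_psychometric(
    counts: Sequence[tuple[float, int, int]],
    fa_rate: Optional[float] = None,
    gamma_max: float = 0.5,
    lapse_max: float = 0.1,
) -> PsychFit:
    """Fit the four-parameter cumulative Gaussian to per-intensity counts.

    Parameters
    ----------
    counts
        Iterable of ``(intensity_mw_mm2, n_trials, n_hits)`` rows; at
        least 4 distinct intensities with trials are required.
    fa_rate
        Catch-trial false-alarm rate, stored on the fit as the fixed
        reference line (never used in the likelihood).

    Returns a :class:`PsychFit`; flat data (all-zero or all-one counts,
    or an observed-rate range below 1%) are flagged ``degenerate`` and
    carry no threshold.
    """
    rows = [(float(i), int(n), int(k)) for i, n, k in counts if n > 0]
    if len({r[0] for r in rows}) < 4:
        raise ValueError("need >= 4 distinct intensities with trials")
    intensities = np.array([r[0] for r in rows])
    n = np.array([r[1] for r in rows], dtype=float)
    k = np.array([r[2] for r in rows], dtype=float)
    if np.any(k > n):
        raise ValueError("n_hits cannot exceed n_trials")
    order = np.argsort(intensities)
    intensities, n, k = intensities[order], n[order], k[order]
    x = np.log10(intensities)
    obs = k / n

    degenerate = bool(obs.max() - obs.min() < 0.01)

    lo, hi = x.min(), x.max()
    bounds = [
        (lo - 1.0, hi + 1.0),
        (0.01, 5.0),
        (0.0, gamma_max),
        (0.0, lapse_max),
    ]
    # deterministic multi-start grid over location and spread
    starts = [
        np.array([mu0, s0, g0, 0.02])
        for mu0 in np.linspace(lo, hi, 5)
        for s0 in (0.1, 0.3, 0.8)
        for g0 in (0.05, min(0.3, gamma_max))
    ]
    best = None
    for theta0 in starts:
        res = minimize(
            _nll, theta0, args=(x, n, k), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    mu, sigma, gamma, lam = (float(v) for v in best.x)
    return PsychFit(
        location_mu=mu,
        spread_sigma=sigma,
        guess_gamma=gamma,
        lapse_lambda=lam,
        neg_log_likelihood=float(best.fun),
        intensities=intensities,
        fitted_probabilities=psychometric_curve(intensities, mu, sigma, gamma, lam),
        fa_reference=fa_rate,
        degenerate=degenerate,
    )


def extract_threshold(fit: PsychFit) -> float:
    """Intensity at the midpoint of the fitted curve's range: 10**mu.

    The midpoint probability is gamma + (1 - gamma - lambda)/2, and the
    cumulative Gaussian crosses it exactly where its argument is zero.
    """
    return fit.threshold_mw_mm2


def near_threshold_band(
    fit: PsychFit,
    low: float = 0.25,
    high: float = 0.75,
    intensities: Optional[Sequence[float]] = None,
) -> NearThresholdBand:
    """Intensities whose normalized detection term lies in [low, high].

    The band is contiguous in intensity rank because the normalized term
    Phi((log10 I - mu)/sigma) is monotone in I.  An empty band is
    returned (not an error) when the tested grid skips the transition.
    """
    if not 0.0 <= low <= high <= 1.0:
        raise ValueError("need 0 <= low <= high <= 1")
    if fit.degenerate:
        raise DegenerateFitError("flat data: no threshold region")
    grid = np.asarray(
        fit.intensities if intensities is None else list(intensities), dtype=float
    )
    z = (np.log10(grid) - fit.location_mu) / fit.spread_sigma
    member = (norm.cdf(z) >= low) & (norm.cdf(z) <= high)
    return NearThresholdBand(
        member_intensities=tuple(float(v) for v in np.sort(grid[member])),
        low=low,
        high=high,
    )
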