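"""Uncertainty for inferred admixture dates.

Chromosome bootstrap: resample the Z chromosome identities with replacement
(the same resampled multiset applied to every individual), rebuild curves and
refit the date; the 95% CI is the 2.5/97.5 percentile interval.  A fit is
declared *no admixture* when any bootstrap date hits the search floor
(floor(min) = 1) or the 400-generation ceiling.

Weighted jackknife: drop one chromosome at a time and combine the Z leave-one
-out dates with SNP-count weights (Busing-style delete-one formulas), which
works even for a single target individual where the bootstrap cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "JackknifeResult",
    "bootstrap_dates",
    "no_admixture_rule",
    "jackknife_se",
    "jackknife_dates",
    "generations_to_year",
]

NO_ADMIXTURE_MAX_DATE = 400.0
GENERATION_YEARS = 28.0
REFERENCE_BIRTH_YEAR = 1960.0


class ResampleError(RuntimeError):
    """Raised by a refit callable when a resample yields no usable pairs."""


@dataclass
class BootstrapResult:
    """Dates refitted on R chromosome resamples and their percentile CI."""

    dates: np.ndarray
    ci: tuple[float, float]
    n_resamples: int

    @property
    def no_admixture(self) -> bool:
        return no_admixture_rule(self.dates)

    @property
    def sd(self) -> float:
        return float(np.std(self.dates, ddof=1)) if len(self.dates) > 1 else 0.0


@dataclass
class JackknifeResult:
    """Leave-one-chromosome-out dates and the weighted jackknife SE."""

    lam: float
    lam_i: np.ndarray
    weights: np.ndarray  # SNP count per chromosome
    se: float

    @property
    def h(self) -> np.ndarray:
        return self.weights.sum() / self.weights

    @property
    def ci(self) -> tuple[float, float]:
        return (self.lam - 1.96 * self.se, self.lam + 1.96 * self.se)


def bootstrap_dates(
    refit: Callable[[np.ndarray], float],
    n_chromosomes: int,
    n_resamples: int,
    rng: np.random.Generator,
    *,
    max_retries: int = 5,
) -> BootstrapResult:
    """Chromosome bootstrap of the date estimate.

    ``refit`` maps a vector of chromosome multiplicities (how many times each
    chromosome appears in the resample) to a refitted date; it raises
    :class:`ResampleError` for unusable resamples, which are redrawn up to
    ``max_retries`` times.
    """
    if n_resamples < 1:
        raise ValueError("need at least one bootstrap resample")
    dates = np.empty(n_resamples)
    for r in range(n_resamples):
        for attempt in range(max_retries + 1):
            weights = np.bincount(
                rng.integers(0, n_chromosomes, n_chromosomes), minlength=n_chromosomes
            ).astype(float)
            try:
                dates[r] = refit(weights)
                break
            except ResampleError:
                logger.warning("bootstrap resample %d unusable (attempt %d); redrawing", r, attempt + 1)
        else:
            raise ResampleError(f"bootstrap resample {r} failed after {max_retries} retries")
    ci = (float(np.percentile(dates, 2.5)), float(np.percentile(dates, 97.5)))
    return BootstrapResult(dates, ci, n_resamples)


def no_admixture_rule(dates: Sequence[float]) -> bool:
    """True when the bootstrap dates are consistent with no admixture signal:
    the floor of the minimum date is one, or the maximum is 400 or greater."""
    dates = np.asarray(dates, float)
    if dates.size < 1:
        raise ValueError("need at least one bootstrap date")
    return bool(np.floor(dates.min()) <= 1.0 or dates.max() >= NO_ADMIXTURE_MAX_DATE)


def jackknife_se(lam: float, lam_i: Sequence[float], w: Sequence[float]) -> float:
    """Weighted delete-one-chromosome jackknife standard error.

    With h_i = (sum_j w_j)/w_i the estimator is

        sigma_JK^2 = (1/Z) sum_i 1/(h_i - 1)
                     [ h_i*lam - (h_i-1)*lam_i - Z*lam + sum_j (1 - w_j/W) lam_j ]^2

    where W = sum_j w_j; with equal weights this reduces to the standard
    unweighted delete-one jackknife SE.
    """
    lam_i = np.asarray(lam_i, float)
    w = np.asarray(w, float)
    z = lam_i.size
    if z < 2:
        raise ValueError("jackknife needs at least 2 chromosomes")
    if w.size != z:
        raise ValueError("one weight per leave-one-out date required")
    if np.any(w < 1):
        raise ValueError("chromosome weights (SNP counts) must be >= 1")
    W = w.sum()
    h = W / w
    pseudo_sum = np.sum((1.0 - w / W) * lam_i)
    term = h * lam - (h - 1.0) * lam_i - z * lam + pseudo_sum
    var = np.mean(term**2 / (h - 1.0))
    return float(np.sqrt(max(var, 0.0)))


def jackknife_dates(
    refit: Callable[[np.ndarray], float],
    lam: float,
    weights: Sequence[float],
) -> JackknifeResult:
    """Leave-one-chromosome-out dates via the same refit callable as the
    bootstrap (a multiplicity vector with one chromosome zeroed)."""
    w = np.asarray(weights, float)
    z = w.size
    lam_i = np.empty(z)
    for i in range(z):
        mult = np.ones(z)
        mult[i] = 0.0
        lam_i[i] = refit(mult)
    return JackknifeResult(lam, lam_i, w, jackknife_se(lam, lam_i, w))


def generations_to_year(g: float) -> float:
    """Convert a date in generations ago to a calendar year (CE; negative
    values are BCE), assuming 28-year generations and an average sampled
    birth year of 1960:  y = 1960 - 28 * (g + 1)."""
    if g < 0:
        raise ValueError("generations must be >= 0")
    return REFERENCE_BIRTH_YEAR - GENERATION_YEARS * (g + 1.0)
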