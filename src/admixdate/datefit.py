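"""Exponential decay fits of admixture probability curves.

All curves share the decay rate: the one-date model is

    P_hat_{UV}(g) ~ tau_{uv} + delta_{uv} * exp(-g * lambda)

with ``g`` in Morgans and ``lambda`` the admixture date in generations; the
two-date model adds a second exponential with its own per-curve amplitude.
The per-curve intercepts and amplitudes are profiled out in closed form
(simple linear regression on the exponential regressors), leaving a 1-D or
2-D search over the date(s).  Bins enter the sum of squared errors with equal
weight; bins without sampled pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .curves import CurveSet

__all__ = ["FitResult", "fit_one_date", "fit_two_dates", "regrid_if_old"]

LAMBDA_BOUNDS = (1.0, 400.0)
REGRID_THRESHOLD = 55.0  # generations; older dates refit on the 1-5 cM grid
_GRID_POINTS = 200
_FLAT_TOL = 1e-4  # |delta| below this fraction of the curve scale => no decay


@dataclass
class FitResult:
    """Joint decay fit over all surrogate-pair curves.

    ``tau`` and ``delta`` are (n_surrogate, n_surrogate) symmetric matrices;
    the two-date fit stores the second amplitude in ``delta2`` and the two
    dates in ``(lam, lam2)`` with ``lam < lam2``.
    """

    surrogates: list[str]
    lam: float
    tau: np.ndarray
    delta: np.ndarray
    sse: float
    r2: float
    lam2: float | None = None
    delta2: np.ndarray | None = None
    r2_improvement: float | None = None
    flags: list[str] = field(default_factory=list)
    n_bins: int = 0

    @property
    def n_dates(self) -> int:
        return 1 if self.lam2 is None else 2

    @property
    def dates(self) -> tuple[float, ...]:
        return (self.lam,) if self.lam2 is None else (self.lam, self.lam2)

    def to_dict(self) -> dict:
        """JSON-ready fit report: dates, per-curve intercepts/amplitudes,
        SSE and the fit statistics."""
        def curve_table(mat):
            s = self.surrogates
            return {
                f"{s[i]}|{s[j]}": float(mat[i, j])
                for i in range(len(s))
                for j in range(i, len(s))
                if np.isfinite(mat[i, j])
            }

        out = {
            "dates_generations": list(self.dates),
            "tau": curve_table(self.tau),
            "delta": curve_table(self.delta),
            "sse": self.sse,
            "r2": self.r2,
            "r2_improvement": self.r2_improvement,
            "n_bins": self.n_bins,
            "flags": self.flags,
        }
        if self.delta2 is not None:
            out["delta2"] = curve_table(self.delta2)
        return out


def _curve_stack(curves: CurveSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unique (u <= v) curves over unmasked bins, dropping all-NaN curves."""
    idx, y = curves.pair_matrix()
    m = curves.mask
    y = y[:, m]
    keep = ~np.isnan(y).any(axis=1)
    g = curves.grid.centers_M[m]
    return idx[keep], y[keep], g, m


def _profile_sse_one(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Per-curve OLS of y on [1, x]; returns (total SSE, tau, delta)."""
    n = x.size
    sx = x.sum()
    sxx = float(x @ x)
    den = n * sxx - sx * sx
    sy = y.sum(axis=1)
    sxy = y @ x
    syy = np.einsum("ij,ij->i", y, y)
    if den <= 1e-30:
        delta = np.zeros_like(sy)
        tau = sy / n
    else:
        delta = (n * sxy - sx * sy) / den
        tau = (sy - delta * sx) / n
    sse = (
        syy
        - 2 * delta * sxy
        - 2 * tau * sy
        + delta**2 * sxx
        + 2 * tau * delta * sx
        + n * tau**2
    )
    return float(np.clip(sse, 0, None).sum()), tau, delta


def _profile_sse_two(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Per-curve OLS of y on [1, x1, x2] via shared normal equations."""
    n = x1.size
    X = np.column_stack([np.ones(n), x1, x2])
    G = X.T @ X
    B = X.T @ y.T  # (3, n_curves)
    try:
        coef = np.linalg.solve(G, B)
    except np.linalg.LinAlgError:
        coef = np.linalg.pinv(G) @ B
    syy = np.einsum("ij,ij->i", y, y)
    # SSE = y.y - 2 c.B + c.G.c ; with G c = B this reduces to y.y - c.B
    sse = syy - np.einsum("ki,ki->i", coef, B)
    return float(np.clip(sse, 0, None).sum()), coef[0], coef[1], coef[2]


def _scatter(y: np.ndarray) -> float:
    """Total squared deviation of each curve around its own mean."""
    return float(((y - y.mean(axis=1, keepdims=True)) ** 2).sum())


def _expand(idx: np.ndarray, vec: np.ndarray, ns: int) -> np.ndarray:
    mat = np.full((ns, ns), np.nan)
    mat[idx[:, 0], idx[:, 1]] = vec
    mat[idx[:, 1], idx[:, 0]] = vec
    return mat


def fit_one_date(
    curves: CurveSet, lam_bounds: tuple[float, float] = LAMBDA_BOUNDS
) -> FitResult:
    """Profile least-squares fit of the shared one-date decay model.

    The date is found by a log-spaced grid scan refined by bounded 1-D
    minimisation; intercepts/amplitudes come from the closed-form regression
    at the optimum.  Flags: ``no_decay`` when every amplitude is negligible,
    ``at_bound`` when the date sticks to a search bound.
    """
    idx, y, g, m = _curve_stack(curves)
    if y.shape[0] < 1 or y.shape[1] < 3:
        raise ValueError("need at least one curve with >= 3 non-missing bins")

    def sse_of(lam: float) -> float:
        return _profile_sse_one(y, np.exp(-g * lam))[0]

    grid = np.geomspace(lam_bounds[0], lam_bounds[1], _GRID_POINTS)
    sses = np.array([sse_of(l) for l in grid])
    b = int(np.argmin(sses))
    lo = grid[max(b - 1, 0)]
    hi = grid[min(b + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse_of, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3})
    lam = float(res.x) if res.fun <= sses[b] else float(grid[b])
    sse, tau, delta = _profile_sse_one(y, np.exp(-g * lam))
    scatter = _scatter(y)
    r2 = 1.0 - sse / scatter if scatter > 0 else 0.0
    flags = []
    scale = max(np.abs(y).mean(), 1e-12)
    if np.all(np.abs(delta) <= _FLAT_TOL * scale):
        flags.append("no_decay")
    if lam <= lam_bounds[0] * (1 + 1e-6) or lam >= lam_bounds[1] * (1 - 1e-6):
        flags.append("at_bound")
    ns = curves.n_surrogates
    return FitResult(
        list(curves.surrogates),
        lam,
        _expand(idx, tau, ns),
        _expand(idx, delta, ns),
        sse,
        float(r2),
        flags=flags,
        n_bins=int(y.shape[1]),
    )


def fit_two_dates(
    curves: CurveSet,
    one_date: FitResult | None = None,
    lam_bounds: tuple[float, float] = LAMBDA_BOUNDS,
) -> FitResult:
    """Two-pulse decay fit with shared dates across curves.

    A coarse log grid over ordered date pairs seeds Nelder-Mead refinement in
    log-date space.  ``r2_improvement`` is the proportional SSE improvement
    over the one-date fit, ``1 - SSE_2 / SSE_1`` — near zero when a single
    pulse suffices, larger when two distinct pulses are present.  Dates that
    collapse onto each other return the one-date result with improvement 0.
    """
    if one_date is None:
        one_date = fit_one_date(curves, lam_bounds)
    idx, y, g, m = _curve_stack(curves)

    def sse_of(loglams: np.ndarray) -> float:
        l1, l2 = np.exp(np.sort(loglams))
        l1 = float(np.clip(l1, *lam_bounds))
        l2 = float(np.clip(l2, *lam_bounds))
        return _profile_sse_two(y, np.exp(-g * l1), np.exp(-g * l2))[0]

    coarse = np.geomspace(lam_bounds[0], lam_bounds[1], 30)
    best: list[tuple[float, float, float]] = []
    for i, l1 in enumerate(coarse):
        for l2 in coarse[i + 1 :]:
            best.append((sse_of(np.log([l1, l2])), l1, l2))
    best.sort(key=lambda t: t[0])
    starts = [np.log([l1, l2]) for _, l1, l2 in best[:4]]
    starts.append(np.log([max(one_date.lam / 3, lam_bounds[0]), min(one_date.lam * 3, lam_bounds[1])]))
    sol = min(
        (
            optimize.minimize(sse_of, s, method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-12})
            for s in starts
        ),
        key=lambda r: r.fun,
    )
    l1, l2 = np.exp(np.sort(sol.x))
    l1 = float(np.clip(l1, *lam_bounds))
    l2 = float(np.clip(l2, *lam_bounds))
    collapsed = l2 / l1 < 1.01
    sse2 = sse_of(np.log([l1, l2]))
    if collapsed or sse2 >= one_date.sse:
        return FitResult(
            one_date.surrogates,
            one_date.lam,
            one_date.tau,
            one_date.delta,
            one_date.sse,
            one_date.r2,
            lam2=None,
            delta2=None,
            r2_improvement=0.0,
            flags=one_date.flags + ["two_date_collapsed"],
            n_bins=one_date.n_bins,
        )
    sse2, tau, d1, d2 = _profile_sse_two(y, np.exp(-g * l1), np.exp(-g * l2))
    r2imp = 1.0 - sse2 / one_date.sse if one_date.sse > 0 else 0.0
    scatter = _scatter(y)
    ns = curves.n_surrogates
    return FitResult(
        list(curves.surrogates),
        l1,
        _expand(idx, tau, ns),
        _expand(idx, d1, ns),
        sse2,
        1.0 - sse2 / scatter if scatter > 0 else 0.0,
        lam2=l2,
        delta2=_expand(idx, d2, ns),
        r2_improvement=float(np.clip(r2imp, 0.0, 1.0)),
        n_bins=int(y.shape[1]),
    )


def regrid_if_old(fit: FitResult, threshold: float = REGRID_THRESHOLD) -> bool:
    """True when the fitted date calls for the short-range fine grid.

    Dates beyond ~55 generations have essentially decayed by 5 cM, so curves
    should be rebuilt for pairs 1-5 cM apart at 0.05 cM resolution and refit.
    """
    return fit.lam > threshold
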