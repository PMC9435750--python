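"""Admixing-source description and event classification.

The fitted curve amplitudes ``delta_{UV}`` of a two-source pulse form (up to
noise) a rank-1 matrix

    delta_{UV} = alpha(1-alpha) * v_U v_V / (f_U f_V),

where ``f`` is the marginal surrogate-probability vector of the target and
``v = beta_A - beta_B`` the difference between the two sources' surrogate
profiles.  The leading eigenpair of the delta matrix therefore recovers
``sqrt(alpha(1-alpha)) * v`` exactly; what it cannot fix is the split of
that product between alpha and ``|v|``.  The split is resolved by requiring
the implied source profiles to be (non-negative) mixtures of the surrogate
populations: alpha is chosen to minimise the joint NNLS residual of the two
profiles on the surrogate panel.  Each source profile is then reported as
its NNLS mixture of surrogates.

"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .painting import CopyingMatrix

__all__ = [
    "SourceProfile",
    "SourceInference",
    "EventReport",
    "mixture_decompose",
    "infer_sources_and_alpha",
    "merge_similar_donors",
    "iterate",
]

PRUNE_THRESHOLD = 0.005  # surrogates contributing <0.5% are dropped per iteration
MULTIWAY_RESIDUAL = 0.2  # rank-1 residual fraction flagging >2 sources
MULTIPLE_DATE_R2 = 0.2  # two-date improvement flagging multiple pulses
MULTIPLE_DATE_RATIO = 1.5  # required separation between the two dates

CLASSIFICATIONS = (
    "no-admixture",
    "one-date",
    "one-date-multiway",
    "multiple-dates",
    "uncertain",
)


@dataclass
class SourceProfile:
    """One admixing source as a non-negative mixture of surrogates."""

    weights: pd.Series  # indexed by surrogate, sums to 1

    def __post_init__(self) -> None:
        w = self.weights
        if (w < -1e-12).any():
            raise ValueError("source profile weights must be non-negative")
        s = float(w.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"source profile sums to {s:.6g}, not 1")

    def top(self, n: int = 10) -> pd.Series:
        return self.weights.sort_values(ascending=False).head(n)


@dataclass
class SourceInference:
    """alpha plus the two source profiles and eigen diagnostics."""

    alpha: float
    beta_minority: np.ndarray  # surrogate-probability profile of the minority source
    beta_majority: np.ndarray
    profile_minority: SourceProfile
    profile_majority: SourceProfile
    leading_eigenvalue: float
    rank1_residual: float
    uncertain: bool = False

    @property
    def contributions(self) -> pd.Series:
        """Total ancestry contribution of each surrogate (pruning statistic)."""
        return (
            self.alpha * self.profile_minority.weights
            + (1.0 - self.alpha) * self.profile_majority.weights
        )


@dataclass
class EventReport:
    """Final description of the admixture signal in a target population."""

    target: str
    classification: str
    dates: tuple[float, ...]
    dates_ci: tuple[tuple[float, float], ...] | None
    alpha: float | None
    sources: tuple[SourceProfile, ...]
    r2: float
    r2_improvement: float | None
    surrogates_retained: list[str]
    grid: str
    left_trim_cM: float
    calendar_years: tuple[float, ...] = ()
    jackknife_se: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "classification": self.classification,
            "dates_generations": list(self.dates),
            "dates_ci": [list(ci) for ci in self.dates_ci] if self.dates_ci else None,
            "calendar_years_CE": list(self.calendar_years),
            "alpha": self.alpha,
            "sources": [s.weights.to_dict() for s in self.sources],
            "r2": self.r2,
            "r2_improvement": self.r2_improvement,
            "surrogates_retained": self.surrogates_retained,
            "grid": self.grid,
            "left_trim_cM": self.left_trim_cM,
            "jackknife_se": self.jackknife_se,
            **self.extra,
        }


def mixture_decompose(
    target_vector: pd.Series | np.ndarray, surrogate_matrix: pd.DataFrame | np.ndarray
) -> SourceProfile:
    """Non-negative least squares of a target profile on surrogate profiles.

    ``surrogate_matrix`` has one row per surrogate; weights are renormalised
    to sum to one.  An all-zero solution (target orthogonal to every
    surrogate) raises.
    """
    if isinstance(surrogate_matrix, pd.DataFrame):
        names = list(surrogate_matrix.index)
        A = surrogate_matrix.to_numpy(float).T
    else:
        A = np.asarray(surrogate_matrix, float).T
        names = [f"S{i}" for i in range(A.shape[1])]
    b = np.asarray(target_vector, float)
    if A.shape[0] != b.size:
        raise ValueError("target and surrogate profiles have different lengths")
    w, _ = optimize.nnls(A, b)
    total = w.sum()
    if total <= 0:
        raise ValueError("target profile is unrepresentable by the surrogates (all-zero NNLS)")
    return SourceProfile(pd.Series(w / total, index=names))


def infer_sources_and_alpha(
    delta: np.ndarray,
    target_vector: pd.Series,
    surrogate_matrix: pd.DataFrame,
    prob_map: pd.DataFrame,
) -> SourceInference:
    """Two-source decomposition of the fitted amplitude matrix.

    Parameters
    ----------
    delta : symmetric (n_surrogate, n_surrogate) amplitude matrix from the
        one-date fit, ordered like ``prob_map.index``.
    target_vector : the target population's copying vector (donor space).
    surrogate_matrix : copying vectors of the retained surrogates.
    prob_map : donor-to-surrogate probability map p(U|d) for the retained
        surrogates (rows U, columns d).
    """
    if isinstance(surrogate_matrix, CopyingMatrix):
        surrogate_matrix = surrogate_matrix.frame
    surrogates = list(prob_map.index)
    P = prob_map.to_numpy(float)
    f = P @ target_vector.reindex(prob_map.columns).to_numpy(float)
    total = f.sum()
    if not total > 0:
        raise ValueError("target surrogate-probability vector is zero")
    f = f / total
    d = np.asarray(delta, float)
    d = np.where(np.isnan(d), 0.0, d)
    d = 0.5 * (d + d.T)
    evals, evecs = np.linalg.eigh(d)
    lead = int(np.argmax(evals))
    mu = float(evals[lead])
    norm = float(np.linalg.norm(evals))
    resid = float(np.sqrt(max(norm**2 - mu**2, 0.0)) / norm) if norm > 0 else 0.0
    if mu <= 0:
        return SourceInference(
            np.nan, f, f,
            _uniform_profile(surrogates), _uniform_profile(surrogates),
            mu, resid, uncertain=True,
        )
    e = evecs[:, lead]
    # sqrt(alpha(1-alpha)) * (beta_A - beta_B), up to sign, from the eigenpair
    u = np.sqrt(mu) * e * f
    if not (u > 1e-12).any() or not (u < -1e-12).any():
        return SourceInference(
            np.nan, f, f,
            _uniform_profile(surrogates), _uniform_profile(surrogates),
            mu, resid, uncertain=True,
        )
    # surrogate-probability profiles of the surrogate populations themselves
    Q = pd.DataFrame(
        P @ surrogate_matrix[prob_map.columns].to_numpy(float).T,
        index=surrogates,
        columns=surrogates,
    ).T  # rows: surrogate populations, columns: surrogate-probability axis
    Qmat = Q.to_numpy(float).T

    # The eigenpair fixes the source difference up to the scale set by alpha:
    # beta_+ = f + sqrt((1-a)/a) u and beta_- = f - sqrt(a/(1-a)) u.  Choose
    # the alpha whose implied profiles are best representable as surrogate
    # mixtures (joint NNLS residual); scanning alpha over (0, 1) covers both
    # orientations of the eigenvector.
    def nnls_resid(a: float) -> float:
        bp = f + np.sqrt((1 - a) / a) * u
        bm = f - np.sqrt(a / (1 - a)) * u
        rp = optimize.nnls(Qmat, bp)[1]
        rm = optimize.nnls(Qmat, bm)[1]
        return rp * rp + rm * rm

    agrid = np.linspace(0.02, 0.98, 97)
    res_grid = np.array([nnls_resid(a) for a in agrid])
    best = int(np.argmin(res_grid))
    lo = agrid[max(best - 1, 0)]
    hi = agrid[min(best + 1, len(agrid) - 1)]
    ref = optimize.minimize_scalar(
        nnls_resid, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
    )
    alpha_plus = float(ref.x) if ref.fun <= res_grid[best] else float(agrid[best])
    beta_plus = np.clip(f + np.sqrt((1 - alpha_plus) / alpha_plus) * u, 0.0, None)
    beta_minus = np.clip(f - np.sqrt(alpha_plus / (1 - alpha_plus)) * u, 0.0, None)
    beta_plus /= beta_plus.sum()
    beta_minus /= beta_minus.sum()
    prof_plus = mixture_decompose(beta_plus, Q)
    prof_minus = mixture_decompose(beta_minus, Q)
    if alpha_plus <= 0.5:
        alpha, b_min, b_maj = alpha_plus, beta_plus, beta_minus
        p_min, p_maj = prof_plus, prof_minus
    else:
        alpha, b_min, b_maj = 1.0 - alpha_plus, beta_minus, beta_plus
        p_min, p_maj = prof_minus, prof_plus
    if abs(alpha - 0.5) < 1e-6:
        # symmetric split: label by lexicographically smallest top surrogate
        tp, tm = prof_plus.top(1).index[0], prof_minus.top(1).index[0]
        if tm < tp:
            b_min, b_maj = beta_minus, beta_plus
            p_min, p_maj = prof_minus, prof_plus
        else:
            b_min, b_maj = beta_plus, beta_minus
            p_min, p_maj = prof_plus, prof_minus
    return SourceInference(float(alpha), b_min, b_maj, p_min, p_maj, mu, resid)


def _uniform_profile(surrogates: list[str]) -> SourceProfile:
    n = len(surrogates)
    return SourceProfile(pd.Series(np.full(n, 1.0 / n), index=surrogates))


def merge_similar_donors(
    copying: CopyingMatrix, r_threshold: float = 0.95
) -> tuple[CopyingMatrix, dict[str, str]]:
    """Merge donor groups whose donor vectors correlate above ``r_threshold``.

    Each donor group is described by the vector of amounts it contributes to
    every surrogate (a column of the copying matrix); columns with Pearson
    correlation above the threshold are merged transitively, the merged
    column being the mean of its members, and rows are renormalised.
    Returns the merged matrix and the donor -> merged-label mapping.
    """
    frame = copying.frame
    donors = list(frame.columns)
    if len(donors) < 2:
        return copying, {d: d for d in donors}
    corr = np.corrcoef(frame.to_numpy(float).T)
    # union-find over donors
    parent = list(range(len(donors)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            if corr[i, j] > r_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(donors)):
        groups.setdefault(find(i), []).append(i)
    cols = {}
    mapping: dict[str, str] = {}
    for members in groups.values():
        label = "+".join(donors[i] for i in sorted(members))
        cols[label] = frame.iloc[:, members].mean(axis=1)
        for i in members:
            mapping[donors[i]] = label
    merged = pd.DataFrame(cols)
    merged = merged.div(merged.sum(axis=1), axis=0)
    return CopyingMatrix(merged), mapping


def classify(
    r2_improvement: float | None,
    dates: tuple[float, ...],
    rank1_residual: float,
    uncertain: bool,
    no_admixture: bool | None,
) -> str:
    """Event classification from the fit diagnostics and the bootstrap rule."""
    if no_admixture:
        return "no-admixture"
    if uncertain:
        return "uncertain"
    if (
        r2_improvement is not None
        and r2_improvement > MULTIPLE_DATE_R2
        and len(dates) == 2
        and dates[1] / dates[0] >= MULTIPLE_DATE_RATIO
    ):
        return "multiple-dates"
    if rank1_residual > MULTIWAY_RESIDUAL:
        return "one-date-multiway"
    return "one-date"


def iterate(paintings, copying, config=None, *, target=None, surrogates=None):
    """Run the full iterative date/source loop and return an EventReport.

    Convenience wrapper around :class:`admixdate.model.AdmixtureModel`; see
    that class for the orchestration details.
    """
    from .model import AdmixtureModel

    model = AdmixtureModel(
        paintings, copying, target=target, surrogates=surrogates, config=config
    )
    return model.fit().report
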