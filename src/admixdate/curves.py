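"""Admixture probability ("coancestry") curves.

For every ordered pair of surrogate populations ``(U, V)`` and every pair
distance ``g`` on the fitting grid, the curve value is the probability that
two sampled segments at distance ``g`` relate most recently to ``U`` and
``V``, divided by the product of the marginal probabilities ``f_U * f_V``.
Under a single admixture pulse the scaled curve behaves as
``tau + delta_{UV} * exp(-g * lambda)`` with ``delta`` positive for
same-source pairs and negative for cross-source pairs.

Pair draws are first reduced to an integer tensor of donor-pair counts per
(chromosome, distance bin); curves for any donor-to-surrogate probability map
are then cheap tensor contractions.  Chromosome bootstrap and delete-one
jackknife refits reweight the chromosome axis without touching the pair
draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .painting import PaintingSet
from .sampler import PairArrays, SamplerConfig

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceGrid",
    "PairCountTensor",
    "CurveSet",
    "TrimResult",
    "accumulate_curves",
    "scale_curves",
    "apply_null",
    "ld_trim",
]

LD_TRIM_WINDOWS = (3, 5, 7, 9, 11, 13)


@dataclass(frozen=True)
class DistanceGrid:
    """Uniform grid of pair distances (bin-centre separations), in cM."""

    bin_width: float
    min_separation: int  # smallest allowed separation, in bins (exclusive bound + 1)
    n: int

    @classmethod
    def from_sampler(cls, cfg: SamplerConfig) -> "DistanceGrid":
        return cls(cfg.bin_width, cfg.min_k + 1, cfg.max_k - cfg.min_k)

    @property
    def separations(self) -> np.ndarray:
        return np.arange(self.min_separation, self.min_separation + self.n)

    @property
    def centers_cM(self) -> np.ndarray:
        return self.separations * self.bin_width

    @property
    def centers_M(self) -> np.ndarray:
        return self.centers_cM / 100.0

    def index(self, separation: np.ndarray) -> np.ndarray:
        return separation - self.min_separation


class PairCountTensor:
    """Integer donor-pair counts per (chromosome, distance bin).

    ``counts[c, k, a, b]`` is the number of drawn pairs on chromosome ``c`` at
    grid index ``k`` whose segments were painted by donor groups ``a`` and
    ``b`` (as drawn; symmetrisation happens in the curve contraction).
    ``seg_counts[c, d]`` counts the segments per donor per chromosome and
    yields the marginal surrogate probabilities.
    """

    def __init__(
        self,
        counts: np.ndarray,
        seg_counts: np.ndarray,
        grid: DistanceGrid,
        donors: list[str],
        chromosomes: list[str],
    ) -> None:
        self.counts = counts
        self.seg_counts = seg_counts
        self.grid = grid
        self.donors = donors
        self.chromosomes = chromosomes

    @classmethod
    def accumulate(
        cls,
        pset: PaintingSet,
        pairs: PairArrays,
        grid: DistanceGrid,
        *,
        order: str = "chromosome",
    ) -> "PairCountTensor":
        """Reduce pair draws to the count tensor.

        ``order`` selects the accumulation grouping — per chromosome across
        individuals, or per individual across all its chromosomes at once.
        Counts are integers, so both orders give bit-identical tensors; the
        flag exists to make that property testable.
        """
        n_chrom = pset.genome_map.n_chromosomes
        n_d = len(pset.donors)
        shape = (n_chrom, grid.n, n_d, n_d)
        counts = np.zeros(shape, dtype=np.int64)
        chrom = pset.chrom_code[pairs.seg_a].astype(np.int64)
        k = grid.index(pairs.separation.astype(np.int64))
        if len(k) and (k.min() < 0 or k.max() >= grid.n):
            raise ValueError("pair separation outside the distance grid")
        da = pset.donor_code[pairs.seg_a].astype(np.int64)
        db = pset.donor_code[pairs.seg_b].astype(np.int64)
        flat = ((chrom * grid.n + k) * n_d + da) * n_d + db
        if order == "chromosome":
            groups = [chrom == c for c in range(n_chrom)]
        elif order == "individual":
            ind = pset.ind_code[pairs.seg_a]
            groups = [ind == i for i in range(pset.n_individuals)]
        else:
            raise ValueError(f"unknown accumulation order {order!r}")
        acc = np.zeros(counts.size, dtype=np.int64)
        for sel in groups:
            if sel.any():
                acc += np.bincount(flat[sel], minlength=counts.size)
        counts = acc.reshape(shape)
        seg_counts = np.zeros((n_chrom, n_d), dtype=np.int64)
        np.add.at(seg_counts, (pset.chrom_code.astype(np.int64), pset.donor_code.astype(np.int64)), 1)
        return cls(counts, seg_counts, grid, list(pset.donors), list(pset.genome_map.chromosomes))

    def raw_curves(
        self, prob_map: np.ndarray, chrom_weights: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Contract the tensor with a donor-to-surrogate probability map.

        prob_map : (n_surrogate, n_donor), columns summing to 1 (or 0 for
        donor groups dropped from the analysis).

        Returns ``(raw, npairs, f)``: the per-pair mean symmetrised
        probability products ``raw[u, v, k]``, the pair counts per grid bin,
        and the marginal surrogate probabilities ``f[u]``.
        """
        w = np.ones(len(self.chromosomes)) if chrom_weights is None else np.asarray(chrom_weights, float)
        cw = np.einsum("c,ckab->kab", w, self.counts)
        npairs = cw.sum(axis=(1, 2))
        e = np.einsum("kab,ua,vb->kuv", cw, prob_map, prob_map, optimize=True)
        sym = 0.5 * (e + e.transpose(0, 2, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(npairs[:, None, None] > 0, sym / npairs[:, None, None], np.nan)
        seg = w @ self.seg_counts
        total = seg.sum()
        if not total > 0:
            raise ValueError("no segments under the given chromosome weights")
        f = prob_map @ (seg / total)
        return raw.transpose(1, 2, 0), npairs, f


@dataclass
class CurveSet:
    """Scaled admixture probability curves for all surrogate pairs.

    values[u, v, k] is the scaled probability for surrogate pair (u, v) at
    grid bin k; the array is symmetric in (u, v).  ``mask`` flags grid bins
    with at least one sampled pair; ``left_trim`` records how many leading
    bins the LD trim removed (those bins are also masked).
    """

    surrogates: list[str]
    grid: DistanceGrid
    values: np.ndarray
    npairs: np.ndarray
    mask: np.ndarray
    left_trim: int = 0

    @property
    def n_surrogates(self) -> int:
        return len(self.surrogates)

    def curve(self, u: str, v: str) -> tuple[np.ndarray, np.ndarray]:
        """(distances_cM, values) of one curve, masked bins dropped."""
        i, j = self.surrogates.index(u), self.surrogates.index(v)
        return self.grid.centers_cM[self.mask], self.values[i, j, self.mask]

    def pair_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack the unique (u <= v) curves: returns (index pairs, (n_curve, n_k) values)."""
        ns = self.n_surrogates
        iu, iv = np.triu_indices(ns)
        return np.stack([iu, iv], axis=1), self.values[iu, iv, :]

    def apply_trim(self, trim_index: int) -> "CurveSet":
        """Mask all grid bins left of ``trim_index``."""
        mask = self.mask.copy()
        mask[:trim_index] = False
        return replace(self, mask=mask, left_trim=int(trim_index))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        g = self.grid.centers_cM
        for i, u in enumerate(self.surrogates):
            for j, v in enumerate(self.surrogates):
                if j < i:
                    continue
                for k in np.nonzero(self.mask)[0]:
                    rows.append((u, v, g[k], self.values[i, j, k], self.npairs[k]))
        return pd.DataFrame(
            rows, columns=["surrogate_U", "surrogate_V", "g_cM", "scaled_prob", "n_pairs"]
        )


def accumulate_curves(
    pset: PaintingSet,
    pairs: PairArrays,
    prob_map: pd.DataFrame,
    grid: DistanceGrid,
    *,
    order: str = "chromosome",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (unscaled) curves from pair draws and a donor-to-surrogate map.

    Bin ``k`` of curve (U, V) is the mean over pairs at that distance of the
    symmetrised probability product
    ``0.5 * (p(U|d_a) p(V|d_b) + p(U|d_b) p(V|d_a))``.
    Returns (raw[u, v, k], npairs[k], f[u]).
    """
    missing = [d for d in pset.donors if d not in prob_map.columns]
    if missing:
        raise ValueError(f"donor group(s) {missing} absent from the donor->surrogate map")
    tensor = PairCountTensor.accumulate(pset, pairs, grid, order=order)
    pm = prob_map[tensor.donors].to_numpy(float)
    return tensor.raw_curves(pm)


def scale_curves(
    raw: np.ndarray,
    npairs: np.ndarray,
    f: np.ndarray,
    surrogates: Sequence[str],
    grid: DistanceGrid,
) -> CurveSet:
    """Scale raw curves by the marginal product ``f_U * f_V``.

    Surrogates with zero marginal probability cannot be scaled; their curves
    are undefined and the caller should drop them (a warning is logged).
    """
    f = np.asarray(f, float)
    dead = f <= 0
    if dead.any():
        logger.warning(
            "surrogate(s) %s have zero marginal probability; their curves are undefined",
            [s for s, d in zip(surrogates, dead) if d],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = raw / np.outer(f, f)[:, :, None]
    values[dead, :, :] = np.nan
    values[:, dead, :] = np.nan
    mask = npairs > 0
    return CurveSet(list(surrogates), grid, values, npairs.copy(), mask)


def apply_null(curves: CurveSet, null_curves: CurveSet) -> CurveSet:
    """Divide each curve bin-wise by the null (cross-individual) curve."""
    if curves.grid != null_curves.grid:
        raise ValueError("curve sets live on different distance grids")
    if curves.surrogates != null_curves.surrogates:
        raise ValueError("curve sets cover different surrogates")
    zero = null_curves.mask & ~(np.nanmin(np.abs(null_curves.values), axis=(0, 1)) > 0)
    if zero.any():
        logger.warning("%d null bins are zero; marking those bins missing", int(zero.sum()))
    mask = curves.mask & null_curves.mask & ~zero
    with np.errstate(invalid="ignore", divide="ignore"):
        values = curves.values / null_curves.values
    return CurveSet(curves.surrogates, curves.grid, values, curves.npairs.copy(), mask, curves.left_trim)


# ---------------------------------------------------------------------------
# automatic LD left-trim
# ---------------------------------------------------------------------------


@dataclass
class TrimResult:
    """Outcome of the automatic left-trim scan."""

    trim_index: int  # grid index: bins < trim_index are removed
    per_window: dict[int, int]
    cap: int


def _window_slope(y: np.ndarray, x: np.ndarray, valid: np.ndarray) -> float | None:
    """OLS slope over the valid points of one window; None if degenerate."""
    if valid.sum() < 2:
        return None
    xv, yv = x[valid], y[valid]
    xm = xv.mean()
    den = np.sum((xv - xm) ** 2)
    if den <= 0:
        return None
    return float(np.sum((xv - xm) * (yv - yv.mean())) / den)


def ld_trim(
    values: np.ndarray,
    mask: np.ndarray,
    grid: DistanceGrid,
    *,
    start_index: int = 0,
    windows: Sequence[int] = LD_TRIM_WINDOWS,
) -> TrimResult:
    """Find the left endpoint to remove from all curves before fitting.

    Operates on the same-surrogate curve of the maximally contributing
    surrogate, which should be monotonically decreasing in the absence of
    within-population LD.  For each window length ``W`` the window slides
    right from ``start_index`` until its regression slope is negative; the
    first such left endpoint ``x_l`` records ``x_w = x_l + ceil(W/2)``.  The
    returned trim is the maximum ``x_w`` over windows, capped at half of the
    fitted distance range; windows that never find a negative slope
    contribute the cap.
    """
    n = grid.n
    cap = start_index + (n - start_index) // 2
    x = grid.centers_cM
    per_window: dict[int, int] = {}
    for w in windows:
        xw = cap
        for x_l in range(start_index, n - w + 1):
            sl = slice(x_l, x_l + w)
            slope = _window_slope(values[sl], x[sl], mask[sl])
            if slope is not None and slope < 0:
                xw = min(x_l + int(np.ceil(w / 2)), cap)
                break
        per_window[w] = xw
    trim = max(per_window.values()) if per_window else start_index
    return TrimResult(int(trim), per_window, int(cap))
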