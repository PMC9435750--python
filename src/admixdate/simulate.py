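"""Generative simulator of admixed chromosome paintings.

Each admixed haploid genome is a mosaic of ancestry tracts whose sizes (in
Morgans) are exponential with rate equal to the admixture date in
generations, each tract drawn from the minority source with probability
``alpha``.  Within a tract, painted segments of mean length ``1/rho``
Morgans carry donor-group labels drawn from that source's copying profile;
``s`` independent painting samples per haploid share the same underlying
tracts, mimicking stochastic repaints of one genome.  A surrogate panel is
generated by perturbing the true source profiles, emulating the realistic
case where the admixing sources themselves are unsampled.

Defaults mirror the standard single-pulse study design: 20 diploids, 22
chromosomes of 150 cM, s = 10 samples, date 30 generations, minority
fraction 0.2, near-disjoint source profiles over 12 donor groups, and a
12-surrogate perturbed panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .painting import (
    CopyingMatrix,
    GenomeMap,
    PaintingSet,
    compute_copying_vector,
)

__all__ = [
    "SimScenario",
    "SimData",
    "default_source_profiles",
    "simulate_tracts",
    "simulate_paintings",
    "simulate_surrogate_panel",
    "simulate_dataset",
]

TARGET_NAME = "TARGET"


def default_source_profiles(n_donors: int = 12, leak: float = 0.05) -> pd.DataFrame:
    """Near-disjoint copying profiles of the two admixing sources.

    Source A concentrates on the first half of the donor groups and source B
    on the second half; ``leak`` spreads a small amount of probability over
    all donors so supports overlap slightly, as real populations do.
    """
    if n_donors % 2:
        raise ValueError("n_donors must be even")
    half = n_donors // 2
    base = np.linspace(1.5, 0.5, half)
    base /= base.sum()
    donors = [f"d{i:02d}" for i in range(1, n_donors + 1)]
    a = np.concatenate([base * (1 - leak), np.zeros(half)]) + leak / n_donors
    b = np.concatenate([np.zeros(half), base[::-1] * (1 - leak)]) + leak / n_donors
    return pd.DataFrame([a / a.sum(), b / b.sum()], index=["A", "B"], columns=donors)


@dataclass
class SimScenario:
    """Known-truth admixture scenario.

    lam / alpha
        date (generations ago) and minority ancestry fraction of the pulse.
    lam_recent / alpha_recent / recent_profile
        optional second, more recent pulse: the genome first fragments at
        rate ``lam_recent`` and each outer tract comes from the recent source
        with probability ``alpha_recent``, otherwise from the older admixed
        mosaic (which fragments at rate ``lam``).
    rho
        painting granularity: painted segments per Morgan (default 100, i.e.
        mean 1 cM segments, enough to populate every 0.1 cM distance bin).
    shared_block_rate / shared_block_sigma
        optional bottleneck-like inflation: a donor-bias field shared by all
        individuals, piecewise constant on blocks of mean ``1/rate`` Morgans,
        multiplies the copying profiles.  This distorts the main and the
        cross-individual null curves identically, which is exactly the
        artefact the null division is designed to cancel.
    """

    lam: float = 30.0
    alpha: float = 0.2
    n_individuals: int = 20
    n_samples: int = 10
    rho: float = 100.0
    genome: GenomeMap = field(default_factory=GenomeMap.uniform)
    source_profiles: pd.DataFrame = field(default_factory=default_source_profiles)
    lam_recent: float | None = None
    alpha_recent: float | None = None
    recent_profile: pd.Series | None = None
    shared_block_rate: float | None = None
    shared_block_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if (self.lam_recent is None) != (self.alpha_recent is None):
            raise ValueError("two-pulse scenarios need both lam_recent and alpha_recent")

    @property
    def two_pulse(self) -> bool:
        return self.lam_recent is not None and self.alpha_recent > 0

    @property
    def donors(self) -> list[str]:
        return list(self.source_profiles.columns)

    def profiles_matrix(self) -> pd.DataFrame:
        """Profiles of all simulated sources (A, B and the recent source R)."""
        prof = self.source_profiles.copy()
        if self.lam_recent is not None:
            if self.recent_profile is not None:
                r = self.recent_profile.reindex(prof.columns).to_numpy(float)
            else:
                # a distinct but B-related population: same donor support as
                # B with the weights mirrored, so the recent source shares
                # B's broad ancestry yet has its own recognisable signature
                b = prof.loc["B"].to_numpy(float)
                half = len(b) // 2
                r = np.concatenate([b[:half], b[half:][::-1]])
            prof.loc["R"] = r / r.sum()
        return prof


@dataclass
class SimData:
    """Simulated inputs plus the ground truth."""

    paintings: PaintingSet
    copying: CopyingMatrix
    truth: pd.DataFrame
    scenario: SimScenario
    target: str = TARGET_NAME

    @property
    def surrogates(self) -> list[str]:
        return [p for p in self.copying.populations if p != self.target]


def simulate_tracts(
    scenario: SimScenario, length_cM: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestry tracts of one haploid chromosome.

    Returns (boundaries_cM, source_index): boundaries has one more entry than
    sources and spans [0, length]; source_index is 0 for the minority source
    A, 1 for B, 2 for the recent source of a two-pulse scenario.
    """
    if scenario.two_pulse:
        if scenario.lam_recent >= scenario.lam:
            raise ValueError("the recent pulse must be younger than the old one")
        bounds, outer = _pulse(length_cM, scenario.lam_recent, scenario.alpha_recent, rng)
        # outer == 1 (prob alpha_recent) -> recent source; else older mosaic.
        # Old-mosaic tracts subdivide at rate lam - lam_recent: the outer
        # process already contributes lam_recent generations of breakpoints,
        # so the net correlation of the old ancestry decays at rate lam.
        sub_rate = scenario.lam - scenario.lam_recent
        all_bounds = [0.0]
        labels: list[int] = []
        for lo, hi, is_old in zip(bounds[:-1], bounds[1:], outer == 0):
            if not is_old:
                all_bounds.append(hi)
                labels.append(2)
                continue
            sub_b, sub_l = _pulse(hi - lo, sub_rate, scenario.alpha, rng)
            for b, lab in zip(sub_b[1:], np.where(sub_l == 1, 0, 1)):
                all_bounds.append(lo + b)
                labels.append(int(lab))
        return np.asarray(all_bounds), np.asarray(labels, dtype=np.int64)
    bounds, lab = _pulse(length_cM, scenario.lam, scenario.alpha, rng)
    return bounds, np.where(lab == 1, 0, 1)  # 1 == "hit minority" -> source A


def _pulse(
    length_cM: float, lam: float, alpha: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential(rate=lam per Morgan) tract lengths; label 1 w.p. alpha."""
    mean_cM = 100.0 / lam
    n_guess = max(int(length_cM / mean_cM * 1.5) + 8, 8)
    lengths = rng.exponential(mean_cM, n_guess)
    while lengths.sum() < length_cM:
        lengths = np.concatenate([lengths, rng.exponential(mean_cM, n_guess)])
    ends = np.minimum(np.cumsum(lengths), length_cM)
    stop = int(np.searchsorted(ends, length_cM)) + 1
    bounds = np.concatenate([[0.0], ends[:stop]])
    labels = (rng.random(stop) < alpha).astype(np.int64)
    return bounds, labels


def simulate_paintings(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[PaintingSet, pd.DataFrame]:
    """Painting samples plus true-tract annotations for a whole cohort."""
    prof = scenario.profiles_matrix()
    donors = list(prof.columns)
    n_d = len(donors)
    profiles = prof.to_numpy(float)
    gm = scenario.genome
    width = len(str(scenario.n_individuals))
    inds = [f"ind{i + 1:0{width}d}" for i in range(scenario.n_individuals)]
    mean_seg_cM = 100.0 / scenario.rho

    rec_i: list[np.ndarray] = []
    rec_h: list[np.ndarray] = []
    rec_s: list[np.ndarray] = []
    rec_c: list[np.ndarray] = []
    rec_start: list[np.ndarray] = []
    rec_end: list[np.ndarray] = []
    rec_d: list[np.ndarray] = []
    truth_rows = []

    for ci, chrom in enumerate(gm.chromosomes):
        length = float(gm.lengths_cM[ci])
        # optional shared donor-bias field (same for every individual)
        if scenario.shared_block_rate:
            blk_bounds, _ = _pulse(length, scenario.shared_block_rate, 0.0, rng)
            n_blk = len(blk_bounds) - 1
            bias = np.exp(
                scenario.shared_block_sigma * rng.standard_normal((len(profiles), n_blk, n_d))
            )
            blk_prof = profiles[:, None, :] * bias
            blk_prof /= blk_prof.sum(axis=2, keepdims=True)
        else:
            blk_bounds = np.array([0.0, length])
            blk_prof = profiles[:, None, :]
        cdf = np.cumsum(blk_prof, axis=2)
        for ii, ind in enumerate(inds):
            for hap in (1, 2):
                tb, tsrc = simulate_tracts(scenario, length, rng)
                for lo, hi, src in zip(tb[:-1], tb[1:], tsrc):
                    truth_rows.append((ind, hap, chrom, lo, hi, "ABR"[src]))
                for samp in range(1, scenario.n_samples + 1):
                    breaks, _ = _pulse(length, scenario.rho, 0.0, rng)
                    cuts = np.unique(np.concatenate([breaks, tb, blk_bounds]))
                    starts, ends = cuts[:-1], cuts[1:]
                    keep = ends - starts > 1e-12
                    starts, ends = starts[keep], ends[keep]
                    mids = 0.5 * (starts + ends)
                    src = tsrc[np.searchsorted(tb, mids) - 1]
                    blk = np.searchsorted(blk_bounds, mids) - 1
                    u = rng.random(len(mids))
                    dcode = (cdf[src, blk, :] < u[:, None]).sum(axis=1)
                    n = len(mids)
                    rec_i.append(np.full(n, ii, np.int32))
                    rec_h.append(np.full(n, hap, np.int8))
                    rec_s.append(np.full(n, samp, np.int16))
                    rec_c.append(np.full(n, ci, np.int32))
                    rec_start.append(starts)
                    rec_end.append(ends)
                    rec_d.append(dcode.astype(np.int32))

    pset = PaintingSet.from_arrays(
        gm, inds, donors,
        np.concatenate(rec_i), np.concatenate(rec_h), np.concatenate(rec_s),
        np.concatenate(rec_c), np.concatenate(rec_start), np.concatenate(rec_end),
        np.concatenate(rec_d), validate=False,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["individual", "haploid", "chromosome", "start_cM", "end_cM", "source"],
    )
    return pset, truth


def simulate_surrogate_panel(
    source_profiles: pd.DataFrame,
    n_surrogates: int = 12,
    jitter: float = 0.15,
    rng: np.random.Generator | None = None,
) -> CopyingMatrix:
    """Surrogate copying vectors as perturbations of the true source profiles.

    Surrogate ``i`` starts from source ``i mod n_sources`` and is mixed with
    a flat Dirichlet draw in proportion ``jitter`` (0 reproduces the sources
    exactly); the panel therefore contains close but imperfect matches to
    each source, none identical to it when ``jitter > 0``.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    rng = np.random.default_rng() if rng is None else rng
    bases = source_profiles.to_numpy(float)
    n_d = bases.shape[1]
    rows = []
    names = []
    for i in range(n_surrogates):
        base = bases[i % len(bases)]
        noise = rng.dirichlet(np.ones(n_d))
        row = (1.0 - jitter) * base + jitter * noise
        rows.append(row / row.sum())
        names.append(f"surr{i + 1:02d}")
    return CopyingMatrix(pd.DataFrame(rows, index=names, columns=source_profiles.columns))


def simulate_dataset(
    scenario: SimScenario | None = None,
    seed: int | np.random.Generator = 0,
    *,
    n_surrogates: int = 12,
    jitter: float = 0.15,
) -> SimData:
    """Simulate paintings, a perturbed surrogate panel, and the target's
    copying vector — a complete, self-consistent pipeline input."""
    scenario = SimScenario() if scenario is None else scenario
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel = simulate_surrogate_panel(
        scenario.profiles_matrix(), n_surrogates, jitter, rng
    )
    paintings, truth = simulate_paintings(scenario, rng)
    target_vec = compute_copying_vector(paintings).reindex(panel.donors).fillna(0.0)
    copying = CopyingMatrix(
        pd.concat([pd.DataFrame([target_vec.rename(TARGET_NAME)]), panel.frame])
    )
    return SimData(paintings, copying, truth, scenario)
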