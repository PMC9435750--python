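"""Domain types for chromosome paintings and copying vectors.

A *painting* decomposes a phased haploid genome into contiguous DNA segments,
each labelled with the donor group it shares its most recent ancestor with.
For every target haploid the painting software emits ``s`` stochastic samples
of this mosaic; those samples, together with genome-wide *copying vectors*
(the average fraction of DNA each population matches to each donor group),
are the inputs of the admixture-dating pipeline.

Coordinates are genetic-map positions in centimorgans, 0-based and half-open
``[start_cM, end_cM)``, so that the segments of one sample tile a chromosome
exactly.

Integration with painting software: :func:`read_paintings` is the adapter
point.  Upstream per-haploid "samples" output (per-SNP donor assignments at
whatever dialect the painter emits) should be aggregated to donor *groups*
and converted once to the painting TSV documented there — segment-native,
one row per contiguous same-donor stretch; parsing painter-specific dialects
is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "PaintingSample",
    "GenomeMap",
    "PaintingSet",
    "CopyingMatrix",
    "read_paintings",
    "write_paintings",
    "compute_copying_vector",
    "donor_to_surrogate_probs",
    "read_copying_matrix",
    "write_copying_matrix",
]

#: column order of the painting TSV interchange format
PAINTING_COLUMNS = [
    "individual",
    "haploid",
    "sample",
    "chromosome",
    "start_cM",
    "end_cM",
    "donor",
]

_TILE_TOL = 1e-9


class PaintingFormatError(ValueError):
    """Raised when a painting file or frame violates the tiling invariants."""


@dataclass(frozen=True)
class Segment:
    """One painted DNA segment with cM coordinates and a donor-group label."""

    chromosome: str
    start_cM: float
    end_cM: float
    donor: str

    def __post_init__(self) -> None:
        if not self.end_cM > self.start_cM:
            raise ValueError(
                f"segment end ({self.end_cM}) must exceed start ({self.start_cM})"
            )

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM

    @property
    def midpoint_cM(self) -> float:
        return 0.5 * (self.start_cM + self.end_cM)


@dataclass
class PaintingSample:
    """One stochastic mosaic of one haploid genome.

    ``segments`` maps chromosome name to the ordered list of segments tiling
    that chromosome.
    """

    individual: str
    haploid: int
    sample_index: int
    segments: dict[str, list[Segment]] = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())


@dataclass
class GenomeMap:
    """Per-chromosome genetic lengths (cM) and SNP counts.

    SNP counts are the weights of the delete-one-chromosome jackknife; when
    not known they default to a typical array density of ~145 SNPs per cM.
    """

    chromosomes: list[str]
    lengths_cM: np.ndarray
    snp_counts: np.ndarray

    SNPS_PER_CM = 145.0

    def __post_init__(self) -> None:
        self.lengths_cM = np.asarray(self.lengths_cM, dtype=float)
        self.snp_counts = np.asarray(self.snp_counts, dtype=float)
        if len(self.chromosomes) < 1:
            raise ValueError("genome map needs at least one chromosome")
        if np.any(self.lengths_cM <= 0):
            raise ValueError("chromosome lengths must be positive")
        if np.any(self.snp_counts < 1):
            raise ValueError("SNP counts must be >= 1")

    @classmethod
    def uniform(cls, n_chrom: int = 22, length_cM: float = 150.0) -> "GenomeMap":
        names = [f"chr{i}" for i in range(1, n_chrom + 1)]
        lengths = np.full(n_chrom, float(length_cM))
        snps = np.round(lengths * cls.SNPS_PER_CM)
        return cls(names, lengths, snps)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def index_of(self, chrom: str) -> int:
        try:
            return self.chromosomes.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


class PaintingSet:
    """Columnar container for a collection of painting samples.

    Segments are stored as parallel numpy arrays sorted by
    ``(individual, haploid, sample, chromosome, start_cM)``; this is the
    in-memory form every downstream stage (binning, pair sampling, curve
    accumulation) operates on.  ``samples()`` yields :class:`PaintingSample`
    views for small-scale inspection.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        genome_map: GenomeMap,
        *,
        validate: bool = True,
        source: str = "<frame>",
    ) -> None:
        frame = frame[PAINTING_COLUMNS].copy()
        frame.sort_values(
            ["individual", "haploid", "sample", "chromosome", "start_cM"],
            inplace=True,
            kind="mergesort",
        )
        frame.reset_index(drop=True, inplace=True)
        self.genome_map = genome_map
        self.individuals = sorted(frame["individual"].unique().tolist())
        self.donors = sorted(frame["donor"].unique().tolist())
        self._ind_code = frame["individual"].map(
            {v: i for i, v in enumerate(self.individuals)}
        ).to_numpy(np.int32)
        self._donor_code = frame["donor"].map(
            {v: i for i, v in enumerate(self.donors)}
        ).to_numpy(np.int32)
        chrom_lookup = {c: i for i, c in enumerate(genome_map.chromosomes)}
        chrom_codes = frame["chromosome"].map(chrom_lookup)
        if chrom_codes.isna().any():
            bad = frame.loc[chrom_codes.isna(), "chromosome"].iloc[0]
            raise PaintingFormatError(f"{source}: unknown chromosome {bad!r}")
        self._chrom_code = chrom_codes.to_numpy(np.int32)
        self._hap = frame["haploid"].to_numpy(np.int8)
        self._samp = frame["sample"].to_numpy(np.int16)
        self.start = frame["start_cM"].to_numpy(float)
        self.end = frame["end_cM"].to_numpy(float)
        self.n_samples = int(frame["sample"].max()) if len(frame) else 0
        if validate:
            self._validate(source)

    @classmethod
    def from_arrays(
        cls,
        genome_map: GenomeMap,
        individuals: list[str],
        donors: list[str],
        ind_code: np.ndarray,
        haploid: np.ndarray,
        sample_index: np.ndarray,
        chrom_code: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        donor_code: np.ndarray,
        *,
        validate: bool = True,
    ) -> "PaintingSet":
        """Fast columnar constructor (used by the simulator and subsetting);
        the label frame is materialised lazily on demand."""
        self = object.__new__(cls)
        order = np.lexsort((start, chrom_code, sample_index, haploid, ind_code))
        self.genome_map = genome_map
        self.individuals = list(individuals)
        self.donors = list(donors)
        self._ind_code = np.asarray(ind_code, np.int32)[order]
        self._donor_code = np.asarray(donor_code, np.int32)[order]
        self._chrom_code = np.asarray(chrom_code, np.int32)[order]
        self._hap = np.asarray(haploid, np.int8)[order]
        self._samp = np.asarray(sample_index, np.int16)[order]
        self.start = np.asarray(start, float)[order]
        self.end = np.asarray(end, float)[order]
        self.n_samples = int(self._samp.max()) if len(self._samp) else 0
        if validate:
            self._validate("<arrays>")
        return self

    # -- invariants ---------------------------------------------------------

    def _validate(self, source: str) -> None:
        if len(self.start) == 0:
            raise PaintingFormatError(f"{source}: no segments")
        if np.any(self.end <= self.start):
            line = int(np.nonzero(self.end <= self.start)[0][0])
            raise PaintingFormatError(
                f"{source}: segment end <= start at row {line + 1}"
            )
        # group key changes whenever (ind, hap, sample, chrom) changes
        key = (
            ((self._ind_code.astype(np.int64) * 4 + self._hap) * 4096 + self._samp)
            * 1024
            + self._chrom_code
        )
        new_group = np.empty(len(key), dtype=bool)
        new_group[0] = True
        np.not_equal(key[1:], key[:-1], out=new_group[1:])
        # within a group, each segment must start where the previous ended
        gap = np.abs(self.start[1:] - self.end[:-1]) > _TILE_TOL
        bad = gap & ~new_group[1:]
        if bad.any():
            line = int(np.nonzero(bad)[0][0]) + 1
            raise PaintingFormatError(
                f"{source}: gap or overlap between segments at row {line + 1}"
            )
        # each group must start at 0 and end at the chromosome length
        starts = self.start[new_group]
        if np.any(np.abs(starts) > _TILE_TOL):
            raise PaintingFormatError(f"{source}: chromosome not tiled from 0 cM")
        group_end_mask = np.roll(new_group, -1)
        group_end_mask[-1] = True
        ends = self.end[group_end_mask]
        exp = self.genome_map.lengths_cM[self._chrom_code[group_end_mask]]
        if np.any(np.abs(ends - exp) > 1e-6):
            raise PaintingFormatError(
                f"{source}: chromosome not tiled to its full genetic length"
            )

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_segments(self) -> int:
        return len(self.start)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def ind_code(self) -> np.ndarray:
        return self._ind_code

    @property
    def donor_code(self) -> np.ndarray:
        return self._donor_code

    @property
    def chrom_code(self) -> np.ndarray:
        return self._chrom_code

    @property
    def haploid(self) -> np.ndarray:
        return self._hap

    @property
    def sample_index(self) -> np.ndarray:
        return self._samp

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def lengths_cM(self) -> np.ndarray:
        return self.end - self.start

    def to_frame(self) -> pd.DataFrame:
        """Label frame in canonical order (lexicographic on the label columns)."""
        frame = pd.DataFrame(
            {
                "individual": np.asarray(self.individuals, dtype=object)[self._ind_code],
                "haploid": self._hap.astype(int),
                "sample": self._samp.astype(int),
                "chromosome": np.asarray(self.genome_map.chromosomes, dtype=object)[
                    self._chrom_code
                ],
                "start_cM": self.start,
                "end_cM": self.end,
                "donor": np.asarray(self.donors, dtype=object)[self._donor_code],
            }
        )
        frame.sort_values(
            ["individual", "haploid", "sample", "chromosome", "start_cM"],
            inplace=True,
            kind="mergesort",
        )
        frame.reset_index(drop=True, inplace=True)
        return frame

    def samples(self) -> Iterator[PaintingSample]:
        """Yield :class:`PaintingSample` views (one per individual/haploid/sample)."""
        for (ind, hap, samp), grp in self.to_frame().groupby(
            ["individual", "haploid", "sample"], sort=True
        ):
            segs: dict[str, list[Segment]] = {}
            for chrom, cgrp in grp.groupby("chromosome", sort=True):
                segs[str(chrom)] = [
                    Segment(str(chrom), s, e, str(d))
                    for s, e, d in zip(
                        cgrp["start_cM"], cgrp["end_cM"], cgrp["donor"]
                    )
                ]
            yield PaintingSample(str(ind), int(hap), int(samp), segs)

    def subset_individuals(self, individuals: Sequence[str]) -> "PaintingSet":
        chosen = sorted(set(individuals))
        codes = np.array([self.individuals.index(i) for i in chosen])
        keep = np.isin(self._ind_code, codes)
        remap = np.full(len(self.individuals), -1, np.int32)
        remap[codes] = np.arange(len(chosen), dtype=np.int32)
        return PaintingSet.from_arrays(
            self.genome_map, chosen, self.donors,
            remap[self._ind_code[keep]], self._hap[keep], self._samp[keep],
            self._chrom_code[keep], self.start[keep], self.end[keep],
            self._donor_code[keep], validate=False,
        )

    def with_donor_relabel(self, mapping: dict[str, str]) -> "PaintingSet":
        """Return a copy whose donor labels are replaced via ``mapping``."""
        new_labels = [mapping.get(d, d) for d in self.donors]
        merged = sorted(set(new_labels))
        remap = np.array([merged.index(l) for l in new_labels], np.int32)
        return PaintingSet.from_arrays(
            self.genome_map, self.individuals, merged,
            self._ind_code, self._hap, self._samp, self._chrom_code,
            self.start, self.end, remap[self._donor_code], validate=False,
        )


# -- file I/O ---------------------------------------------------------------


def write_paintings(pset: PaintingSet, path) -> None:
    """Write the painting TSV (header + one row per segment).

    Coordinates are printed with 17 significant digits so a write/read
    round-trip reproduces every float bit-exactly.
    """
    frame = pset.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_paintings(path, genome_map: GenomeMap) -> PaintingSet:
    """Read and validate a painting TSV.

    The format is tab-separated with header columns
    ``individual haploid sample chromosome start_cM end_cM donor`` sorted by
    (individual, haploid, sample, chromosome, start_cM).  Violations of the
    tiling invariants raise :class:`PaintingFormatError` naming the file and
    offending row.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"individual": str, "donor": str, "chromosome": str},
        float_precision="round_trip",
    )
    missing = [c for c in PAINTING_COLUMNS if c not in frame.columns]
    if missing:
        raise PaintingFormatError(f"{path}: missing columns {missing}")
    return PaintingSet(frame, genome_map, validate=True, source=str(path))


# -- copying vectors --------------------------------------------------------


class CopyingMatrix:
    """Population x donor-group matrix of genome-wide matching fractions.

    Rows are populations (the admixture target and its candidate surrogates),
    columns are donor groups; every row sums to one.  Backed by a pandas
    DataFrame, accessible via :attr:`frame`.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.astype(float)
        if (frame.to_numpy() < -1e-12).any():
            raise ValueError("copying matrix entries must be non-negative")
        sums = frame.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums.index[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(f"copying-matrix row {bad!r} sums to {sums[bad]:.6g}, not 1")
        self.frame = frame.clip(lower=0.0)
        self.frame.index.name = "population"

    @property
    def populations(self) -> list[str]:
        return list(self.frame.index)

    @property
    def donors(self) -> list[str]:
        return list(self.frame.columns)

    def row(self, population: str) -> pd.Series:
        return self.frame.loc[population]

    def restrict(self, populations: Sequence[str]) -> "CopyingMatrix":
        return CopyingMatrix(self.frame.loc[list(populations)])

    def __contains__(self, population: str) -> bool:
        return population in self.frame.index


def compute_copying_vector(pset: PaintingSet, individuals: Sequence[str] | None = None) -> pd.Series:
    """Genome-wide copying vector of a population from its painting samples.

    The fraction of total painted cM assigned to each donor group, pooled over
    samples and haploids.  Because each sample tiles the same genome this
    equals the average of per-sample fractions, and it is invariant to
    subdividing a segment into same-donor pieces.
    """
    if individuals is not None:
        pset = pset.subset_individuals(individuals)
    lengths = pset.lengths_cM
    total = lengths.sum()
    if not total > 0:
        raise ValueError("zero total painted length")
    sums = np.bincount(pset.donor_code, weights=lengths, minlength=len(pset.donors))
    return pd.Series(sums / total, index=pset.donors, name="copying")


def donor_to_surrogate_probs(copying: CopyingMatrix | pd.DataFrame) -> pd.DataFrame:
    """Probability p(U | d) that a segment painted by donor group ``d`` is most
    recently related to surrogate population ``U``.

    Columns (donors) are normalised:  p(U|d) = f_{U,d} / sum_U' f_{U',d}.
    A donor group matched by no surrogate leaves p(U|d) undefined and raises.
    """
    frame = copying.frame if isinstance(copying, CopyingMatrix) else copying.astype(float)
    col_sums = frame.sum(axis=0)
    dead = col_sums[col_sums <= 0]
    if len(dead):
        raise ValueError(
            f"donor group(s) {list(dead.index)} are never copied by any surrogate; "
            "p(U|d) is undefined"
        )
    return frame / col_sums


def write_copying_matrix(copying: CopyingMatrix, path) -> None:
    copying.frame.to_csv(path, sep="\t", index_label="population", float_format="%.17g")


def read_copying_matrix(path) -> CopyingMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="population", float_precision="round_trip")
    return CopyingMatrix(frame)
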