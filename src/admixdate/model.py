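"""Model/Results interface wiring the whole admixture-dating pipeline.

``AdmixtureModel`` holds the data (painting samples plus the copying-vector
matrix) and the run configuration; ``fit()`` executes

    pair subsampling -> curve accumulation -> (null division, LD trim)
    -> iterative date/source loop with surrogate pruning
    -> optional fine-grid refit for old dates
    -> two-date fit and classification
    -> chromosome bootstrap / weighted jackknife

and returns an ``AdmixtureResults`` carrying the estimates, their
uncertainty, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import curves as curves_mod
from . import datefit, sources, uncertainty
from .curves import CurveSet, DistanceGrid, PairCountTensor
from .painting import (
    CopyingMatrix,
    GenomeMap,
    PaintingSet,
    compute_copying_vector,
    donor_to_surrogate_probs,
    read_copying_matrix,
    read_paintings,
)
from .sampler import PairArrays, SamplerConfig, draw_pairs_arrays
from .sources import EventReport, SourceInference
from .uncertainty import BootstrapResult, JackknifeResult, ResampleError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AdmixtureModel", "AdmixtureResults"]

REGRID_SAMPLER = dict(bin_width=0.05, max_dist=5.0, min_dist=1.0)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full inference run (defaults follow standard use)."""

    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    iterations: int = 5  # date/source loop count Q
    prune_threshold: float = 0.005  # drop surrogates contributing < 0.5%
    null_individual: bool = True
    max_null_individuals: int = 100
    null_scale: float | str = "auto"
    bootstraps: int = 100
    jackknife: bool = False
    regrid: bool = True
    ld_trim: bool = True
    trim_start_cM: float = 1.0
    merge_donors: bool = False
    merge_threshold: float = 0.95
    two_date: bool = True
    lam_bounds: tuple[float, float] = datefit.LAMBDA_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("need at least one iteration")
        if not 0 <= self.prune_threshold < 1:
            raise ValueError("prune threshold must lie in [0, 1)")

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.md5(payload).hexdigest()[:12]


@dataclass
class _Engine:
    """Pair-count tensors for one distance grid; curves are reweighted
    tensor contractions, so bootstrap/jackknife refits are cheap."""

    sampler: SamplerConfig
    grid: DistanceGrid
    tensor: PairCountTensor
    tensor_null: PairCountTensor | None
    pairs_drawn: int
    pairs_eligible: int
    label: str


class AdmixtureModel:
    """Dates and describes admixture in one target population.

    Parameters
    ----------
    paintings : PaintingSet
        stochastic painting samples of the target individuals.
    copying : CopyingMatrix
        copying vectors of the candidate surrogate populations (and
        optionally of the target itself; otherwise the target vector is
        computed from the paintings).
    target : name of the target row in ``copying`` (default "TARGET").
    surrogates : surrogate population names (default: all non-target rows).
    """

    def __init__(
        self,
        paintings: PaintingSet,
        copying: CopyingMatrix,
        target: str | None = None,
        surrogates: list[str] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.config = config or RunConfig()
        self.target = target or "TARGET"
        if self.config.merge_donors:
            copying, mapping = sources.merge_similar_donors(
                copying, self.config.merge_threshold
            )
            paintings = paintings.with_donor_relabel(mapping)
        self.paintings = paintings
        self.copying = copying
        if surrogates is None:
            surrogates = [p for p in copying.populations if p != self.target]
        if len(surrogates) < 2:
            raise ValueError("need at least 2 surrogate populations")
        self.surrogates = list(surrogates)
        unknown = set(paintings.donors) - set(copying.donors)
        if unknown:
            raise ValueError(
                f"painting donor group(s) {sorted(unknown)} absent from the copying matrix"
            )
        if self.target in copying:
            self.target_vector = copying.row(self.target)
        else:
            self.target_vector = (
                compute_copying_vector(paintings).reindex(copying.donors).fillna(0.0)
            )
        surr_matrix = copying.restrict(self.surrogates)
        self.prob_map = donor_to_surrogate_probs(surr_matrix)  # (U x d), cols sum 1

    @classmethod
    def from_files(
        cls,
        painting_path,
        copying_path,
        genome_map: GenomeMap,
        target: str | None = None,
        surrogates: list[str] | None = None,
        config: RunConfig | None = None,
    ) -> "AdmixtureModel":
        return cls(
            read_paintings(painting_path, genome_map),
            read_copying_matrix(copying_path),
            target=target,
            surrogates=surrogates,
            config=config,
        )

    # ------------------------------------------------------------------

    def _build_engine(
        self, sampler_cfg: SamplerConfig, rng_main, rng_null, label: str
    ) -> _Engine:
        grid = DistanceGrid.from_sampler(sampler_cfg)
        pairs = draw_pairs_arrays(self.paintings, sampler_cfg, rng_main, mode="within")
        tensor = PairCountTensor.accumulate(self.paintings, pairs, grid)
        tensor_null = None
        if self.config.null_individual and self.paintings.n_individuals >= 2:
            null_pairs = draw_pairs_arrays(
                self.paintings,
                sampler_cfg,
                rng_null,
                mode="null",
                max_null_individuals=self.config.max_null_individuals,
                null_scale=self.config.null_scale,
            )
            tensor_null = PairCountTensor.accumulate(self.paintings, null_pairs, grid)
        logger.info(
            "%s: drew %d of %d eligible pairs (%.2f%%)",
            label, pairs.n_drawn, pairs.n_eligible, 100 * pairs.sampling_fraction,
        )
        return _Engine(
            sampler_cfg, grid, tensor, tensor_null,
            pairs.n_drawn, pairs.n_eligible, label,
        )

    def _renormalised_map(self, retained: list[str]) -> pd.DataFrame:
        """p(U|d) over the retained surrogates, columns renormalised; donor
        columns no retained surrogate copies become all-zero."""
        sub = self.copying.restrict(retained).frame
        sums = sub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pm = sub.div(sums, axis=1)
        return pm.fillna(0.0)

    def _curves_for(
        self,
        engine: _Engine,
        prob_map: pd.DataFrame,
        retained: list[str],
        chrom_weights: np.ndarray | None,
        trim_index: int | None,
        top_surrogate: str | None,
    ) -> CurveSet:
        pm = prob_map[engine.tensor.donors].to_numpy(float)
        raw, npairs, f = engine.tensor.raw_curves(pm, chrom_weights)
        cs = curves_mod.scale_curves(raw, npairs, f, retained, engine.grid)
        if engine.tensor_null is not None:
            raw_n, npairs_n, f_n = engine.tensor_null.raw_curves(pm, chrom_weights)
            cs_null = curves_mod.scale_curves(raw_n, npairs_n, f_n, retained, engine.grid)
            cs = curves_mod.apply_null(cs, cs_null)
        if trim_index is not None:
            cs = cs.apply_trim(trim_index)
        elif self.config.ld_trim and top_surrogate is not None:
            ti = retained.index(top_surrogate)
            start = int(
                np.searchsorted(engine.grid.centers_cM, self.config.trim_start_cM)
            )
            trim = curves_mod.ld_trim(
                cs.values[ti, ti], cs.mask, engine.grid, start_index=start
            )
            cs = cs.apply_trim(trim.trim_index)
        return cs

    def _run_loop(self, engine: _Engine) -> dict:
        cfg = self.config
        retained = list(self.surrogates)
        top: str | None = None
        src_inf: SourceInference | None = None
        history = []
        fit1 = None
        cs = None
        for it in range(cfg.iterations):
            pm = self._renormalised_map(retained)
            if top is None:
                pmx = pm[engine.tensor.donors].to_numpy(float)
                _, _, f0 = engine.tensor.raw_curves(pmx)
                top = retained[int(np.argmax(f0))]
            cs = self._curves_for(engine, pm, retained, None, None, top if cfg.ld_trim else None)
            fit1 = datefit.fit_one_date(cs, cfg.lam_bounds)
            src_inf = sources.infer_sources_and_alpha(
                fit1.delta, self.target_vector, self.copying.restrict(retained), pm
            )
            history.append(
                {
                    "iteration": it + 1,
                    "lam": fit1.lam,
                    "alpha": src_inf.alpha,
                    "retained": list(retained),
                    "left_trim": cs.left_trim,
                }
            )
            if src_inf.uncertain:
                break
            contrib = src_inf.contributions
            top = contrib.idxmax()
            keep = contrib[contrib >= cfg.prune_threshold].index.tolist()
            if len(keep) < 2:  # never prune below a fittable curve set
                keep = contrib.sort_values(ascending=False).head(2).index.tolist()
            keep = [s for s in retained if s in set(keep)]
            if not keep:
                raise RuntimeError("all surrogates pruned")
            retained = keep
        return {
            "retained": retained,
            "curves": cs,
            "fit_one": fit1,
            "sources": src_inf,
            "prob_map": self._renormalised_map(retained),
            "top": top,
            "history": history,
        }

    def fit(self) -> "AdmixtureResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        keys = ss.spawn(5)
        rngs = [np.random.default_rng(k) for k in keys]
        engine = self._build_engine(cfg.sampler, rngs[0], rngs[1], "default-grid")
        state = self._run_loop(engine)
        grid_label = (
            f"{cfg.sampler.min_dist:g}-{cfg.sampler.max_dist:g}cM@{cfg.sampler.bin_width:g}"
        )
        regridded = False
        if (
            cfg.regrid
            and not state["sources"].uncertain
            and datefit.regrid_if_old(state["fit_one"])
        ):
            fine = replace(cfg.sampler, **REGRID_SAMPLER)
            engine = self._build_engine(fine, rngs[2], rngs[3], "fine-grid")
            state = self._run_loop(engine)
            grid_label = f"{fine.min_dist:g}-{fine.max_dist:g}cM@{fine.bin_width:g}"
            regridded = True

        fit1 = state["fit_one"]
        cs = state["curves"]
        fit2 = None
        if cfg.two_date and not state["sources"].uncertain:
            fit2 = datefit.fit_two_dates(cs, fit1, cfg.lam_bounds)

        # --- uncertainty: refits reweight the chromosome axis only -------
        final_pm = state["prob_map"]
        retained = state["retained"]
        trim_index = cs.left_trim if cs is not None else 0

        def refit(weights: np.ndarray) -> float:
            try:
                cs_w = self._curves_for(engine, final_pm, retained, weights, trim_index, None)
                return datefit.fit_one_date(cs_w, cfg.lam_bounds).lam
            except (ValueError, np.linalg.LinAlgError) as exc:
                raise ResampleError(str(exc)) from exc

        boot: BootstrapResult | None = None
        if cfg.bootstraps > 0 and not state["sources"].uncertain:
            boot = uncertainty.bootstrap_dates(
                refit, self.paintings.genome_map.n_chromosomes, cfg.bootstraps, rngs[4]
            )
        jack: JackknifeResult | None = None
        if cfg.jackknife and not state["sources"].uncertain:
            jack = uncertainty.jackknife_dates(
                refit, fit1.lam, self.paintings.genome_map.snp_counts
            )

        # --- classification and report -----------------------------------
        src = state["sources"]
        no_adm = boot.no_admixture if boot is not None else None
        r2imp = fit2.r2_improvement if fit2 is not None else None
        two_dates = fit2.dates if (fit2 is not None and fit2.n_dates == 2) else (fit1.lam,)
        classification = sources.classify(
            r2imp, two_dates, src.rank1_residual, src.uncertain, no_adm
        )
        if classification == "multiple-dates":
            dates = fit2.dates
            dates_ci = None
        else:
            dates = (fit1.lam,)
            dates_ci = (boot.ci,) if boot is not None else None
        years = tuple(uncertainty.generations_to_year(d) for d in dates)
        report = EventReport(
            target=self.target,
            classification=classification,
            dates=dates,
            dates_ci=dates_ci,
            alpha=None if np.isnan(src.alpha) else float(src.alpha),
            sources=(src.profile_minority, src.profile_majority),
            r2=fit1.r2,
            r2_improvement=r2imp,
            surrogates_retained=retained,
            grid=grid_label,
            left_trim_cM=float(trim_index * engine.grid.bin_width),
            calendar_years=years,
            jackknife_se=jack.se if jack is not None else None,
            extra={
                "one_date": fit1.lam,
                "one_date_ci": list(boot.ci) if boot is not None else None,
                "config_hash": cfg.config_hash(),
                "regridded": regridded,
                "sampling_fraction": engine.pairs_drawn / max(engine.pairs_eligible, 1),
                "fit_flags": fit1.flags,
            },
        )
        return AdmixtureResults(
            model=self,
            report=report,
            curves=cs,
            fit_one=fit1,
            fit_two=fit2,
            source_inference=src,
            bootstrap=boot,
            jackknife=jack,
            engine=engine,
            history=state["history"],
        )


@dataclass
class AdmixtureResults:
    """Fitted admixture event: estimates, uncertainty and diagnostics."""

    model: AdmixtureModel
    report: EventReport
    curves: CurveSet
    fit_one: datefit.FitResult
    fit_two: datefit.FitResult | None
    source_inference: SourceInference
    bootstrap: BootstrapResult | None
    jackknife: JackknifeResult | None
    engine: _Engine
    history: list[dict]

    # -- convenience accessors -----------------------------------------
    @property
    def date(self) -> float:
        """Point estimate of the (primary) admixture date, in generations."""
        return self.fit_one.lam

    @property
    def date_ci(self) -> tuple[float, float] | None:
        return self.bootstrap.ci if self.bootstrap is not None else None

    @property
    def alpha(self) -> float | None:
        return self.report.alpha

    @property
    def classification(self) -> str:
        return self.report.classification

    @property
    def r2_improvement(self) -> float | None:
        return self.report.r2_improvement

    def refit_dates(self, chrom_weights: np.ndarray) -> float:
        """Refit the one-date model under chromosome multiplicities (the
        bootstrap/jackknife primitive, exposed for diagnostics)."""
        cs = self.model._curves_for(
            self.engine,
            self.model._renormalised_map(self.report.surrogates_retained),
            self.report.surrogates_retained,
            chrom_weights,
            self.curves.left_trim,
            None,
        )
        return datefit.fit_one_date(cs, self.model.config.lam_bounds).lam

    def summary(self) -> str:
        r = self.report
        lines = []
        add = lines.append
        add("Admixture event report".center(62))
        add("=" * 62)
        add(f"{'Target population:':<28}{r.target}")
        add(f"{'Classification:':<28}{r.classification}")
        for i, d in enumerate(r.dates):
            ci = ""
            if r.dates_ci is not None:
                lo, hi = r.dates_ci[i]
                ci = f"   95% CI [{lo:.1f}, {hi:.1f}]"
            add(f"{'Date (generations ago):':<28}{d:.1f}{ci}")
            add(f"{'Date (calendar year CE):':<28}{r.calendar_years[i]:.0f}")
        if r.jackknife_se is not None:
            add(f"{'Jackknife SE (gen):':<28}{r.jackknife_se:.2f}")
        if r.alpha is not None:
            add(f"{'Minority fraction alpha:':<28}{r.alpha:.3f}")
        add(f"{'Fit R2:':<28}{r.r2:.3f}")
        if r.r2_improvement is not None:
            add(f"{'Two-date improvement R2*:':<28}{r.r2_improvement:.3f}")
        add(f"{'Distance grid:':<28}{r.grid}")
        add(f"{'Left trim (cM):':<28}{r.left_trim_cM:.2f}")
        add(f"{'Surrogates retained:':<28}{len(r.surrogates_retained)}")
        add("-" * 62)
        add("Source profiles (top surrogate weights)")
        for name, prof in zip(("minority", "majority"), r.sources):
            top = prof.top(10)
            add(f"  {name}:")
            for s, w in top.items():
                if w > 1e-4:
                    add(f"    {s:<20}{w:.3f}")
        add("=" * 62)
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.report.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def plot_curves(self, pairs=None, path=None):
        """Plot scaled curves (and fitted decay) for surrogate pairs."""
        from .plotting import plot_curve_set

        return plot_curve_set(self.curves, self.fit_one, pairs=pairs, path=path)
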