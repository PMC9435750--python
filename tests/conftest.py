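"""Shared fixtures: tiny hand-built paintings and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import admixdate as ad
from admixdate.model import AdmixtureModel, RunConfig
from admixdate.painting import GenomeMap, PaintingSet


def make_painting_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "individual", "haploid", "sample", "chromosome", "start_cM", "end_cM", "donor",
        ],
    )


@pytest.fixture(scope="session")
def toy_map() -> GenomeMap:
    return GenomeMap(["chr1", "chr2"], np.array([100.0, 80.0]), np.array([1000.0, 800.0]))


@pytest.fixture
def toy_paintings(toy_map) -> PaintingSet:
    """Two individuals, one sample each, hand-placed segments."""
    rows = []
    rng = np.random.default_rng(42)
    for ind in ["i1", "i2"]:
        for hap in (1, 2):
            for chrom, length in [("chr1", 100.0), ("chr2", 80.0)]:
                cuts = np.sort(rng.uniform(0, length, 39))
                bounds = np.concatenate([[0.0], cuts, [length]])
                donors = rng.choice(["dA", "dB", "dC"], size=len(bounds) - 1)
                for s, e, d in zip(bounds[:-1], bounds[1:], donors):
                    rows.append((ind, hap, 1, chrom, s, e, d))
    return PaintingSet(make_painting_frame(rows), toy_map)


@pytest.fixture(scope="session")
def small_scenario() -> ad.SimScenario:
    """Reduced cohort for fast end-to-end tests."""
    return ad.SimScenario(n_individuals=6, genome=GenomeMap.uniform(6, 150.0), n_samples=4)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return ad.simulate_dataset(small_scenario, 11)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """One fitted pipeline run on the small dataset, reused across tests."""
    cfg = RunConfig(seed=11, bootstraps=25, jackknife=True)
    model = AdmixtureModel(
        small_dataset.paintings, small_dataset.copying,
        target=small_dataset.target, config=cfg,
    )
    return model.fit()
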