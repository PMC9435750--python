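"""Small shared helpers for constructing synthetic curve sets in tests."""

import numpy as np

from admixdate.curves import CurveSet, DistanceGrid
from admixdate.sampler import SamplerConfig


def make_noiseless_curves(components, tau=1.0, grid=None):
    """CurveSet of model-generated curves tau + sum_i d_i exp(-g*lam_i).

    ``components`` is a list of one (delta, lam) pair per surrogate; the
    (u, v) curve carries the mean of the u and v diagonal curves so the
    matrix is symmetric.
    """
    grid = grid or DistanceGrid.from_sampler(SamplerConfig())
    g = grid.centers_M
    n = len(components)
    diag = [tau + d * np.exp(-g * lam) for d, lam in components]
    values = np.empty((n, n, grid.n))
    for i in range(n):
        for j in range(n):
            values[i, j] = 0.5 * (diag[i] + diag[j])
    npairs = np.full(grid.n, 100.0)
    return CurveSet([f"S{k}" for k in range(n)], grid, values, npairs, npairs > 0)
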