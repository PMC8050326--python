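import numpy as np
import pandas as pd
import pytest

import soilgeo as sg


@pytest.fixture
def rng():
    return np.random.default_rng(20130924)


@pytest.fixture
def small_dataset(rng):
    """25 random points with random values, for estimator oracles."""
    coords = rng.uniform(0, 50, size=(25, 2))
    return sg.PointDataset(
        pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "z": rng.normal(5, 2, 25)})
    )


@pytest.fixture
def grid_dataset(rng):
    """A 100-point survey grid with one simulated spherical field."""
    coords = sg.regular_grid_coords(90, 10)
    model = sg.VariogramModel("spherical", 0.15, 0.10, 27.0)
    z = sg.simulate_grf(coords, model, mean=2.91, rng=rng)
    return sg.PointDataset(
        pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "FCO2": z}),
        grid_spacing=10.0,
    )


def brute_force_variogram(coords, values, bin_width, max_lag):
    """Independent pair-enumeration Matheron estimator (test oracle)."""
    sums, counts, dsums = {}, {}, {}
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d >= max_lag:
                continue
            b = int(d // bin_width)
            sums[b] = sums.get(b, 0.0) + (values[i] - values[j]) ** 2
            counts[b] = counts.get(b, 0) + 1
            dsums[b] = dsums.get(b, 0.0) + d
    bins = sorted(counts)
    lags = np.array([dsums[b] / counts[b] for b in bins])
    gammas = np.array([sums[b] / (2.0 * counts[b]) for b in bins])
    npairs = np.array([counts[b] for b in bins])
    return lags, gammas, npairs
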