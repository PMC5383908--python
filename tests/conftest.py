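import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from rmcorr.data import PairedRepeatedData

# Frozen 3-participant x 5-trial fixture.  Expected values were computed
# with an independent oracle (within-participant centering + Pearson on
# the centered values, p from the t distribution with df = L - N - 1,
# slope from a dummy-coded least-squares solve) and frozen here.
FIXTURE_PARTICIPANTS = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
FIXTURE_X = [1.0, 2.0, 3.0, 4.0, 5.0,
             2.0, 3.5, 4.0, 5.5, 7.0,
             0.5, 1.0, 2.5, 3.0, 4.5]
FIXTURE_Y = [10.2, 11.1, 11.9, 13.2, 13.8,
             5.1, 6.3, 6.2, 7.9, 8.4,
             20.0, 20.7, 21.3, 22.1, 23.5]
FIXTURE_R = 0.9793480178765671
FIXTURE_P = 5.523281033474582e-09
FIXTURE_DF = 11
FIXTURE_SLOPE = 0.7988571428571438


@pytest.fixture
def fixed_dataset() -> PairedRepeatedData:
    return PairedRepeatedData(FIXTURE_PARTICIPANTS, FIXTURE_Y, FIXTURE_X)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_unbalanced_dataset(rng, n_min=2, n_max=20, k_min=2, k_max=8):
    """A random messy dataset: unbalanced sizes, arbitrary scales."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        sizes = rng.integers(k_min, k_max + 1, n)
        if sizes.sum() - n - 1 >= 1 and sizes.sum() >= 4:
            break
    parts, xs, ys = [], [], []
    for j, size in enumerate(sizes):
        cx = rng.normal(0, 3)
        cy = rng.normal(0, 3)
        parts += [f"s{j}"] * int(size)
        xs.append(cx + rng.normal(0, 1.5, size))
        ys.append(cy + rng.normal(0, 1.5, size))
    return PairedRepeatedData(parts, np.concatenate(ys), np.concatenate(xs))


def write_csv(path, participants, measure1, measure2, header=("participant", "measure1", "measure2")):
    lines = [",".join(header)]
    for p, m1, m2 in zip(participants, measure1, measure2):
        lines.append(f"{p},{m1},{m2}")
    path.write_text("\n".join(lines) + "\n")
    return path
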