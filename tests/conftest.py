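import numpy as np
import pandas as pd
import pytest

from colonyphylo import synthetic
from colonyphylo.signatures import default_reference_signatures


@pytest.fixture(scope="session")
def reference_set():
    return default_reference_signatures()


@pytest.fixture(scope="session")
def small_truth():
    """A 20-colony noise-light cohort with spectra assigned (seed fixed)."""
    cfg = synthetic.CohortConfig(n_colonies=20, donor_age=40.0, seed=11,
                                 germline_count=50, inculture_rate=1.0,
                                 artifact_count=5)
    truth = synthetic.simulate_genealogy(cfg)
    synthetic.simulate_spectra(truth)
    return truth


@pytest.fixture(scope="session")
def small_table(small_truth):
    return synthetic.simulate_read_counts(small_truth)


def four_gamete_violations(gm: pd.DataFrame, max_pairs: int = 20000) -> int:
    """Count site pairs exhibiting all four gametes (perfect-phylogeny breaker)."""
    M = gm.to_numpy(dtype=float)
    m = M.shape[1]
    rng = np.random.default_rng(0)
    pairs = []
    if m * (m - 1) // 2 <= max_pairs:
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    else:
        while len(pairs) < max_pairs:
            i, j = rng.integers(m, size=2)
            if i != j:
                pairs.append((min(i, j), max(i, j)))
    bad = 0
    for i, j in pairs:
        a, b = M[:, i], M[:, j]
        ok = ~(np.isnan(a) | np.isnan(b))
        gam = {(x, y) for x, y in zip(a[ok], b[ok])}
        if {(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)} <= gam:
            bad += 1
    return bad
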