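import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polyhybrid import SimConfig, simulate_counts
from polyhybrid.quant import CountMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_counts(values, lengths=None, groups=None) -> CountMatrix:
    """Build a CountMatrix from a plain dict/array for hand-sized fixtures."""
    df = pd.DataFrame(values)
    if lengths is None:
        lengths = pd.Series(1000.0, index=df.index)
    else:
        lengths = pd.Series(lengths, index=df.index, dtype=float)
    if groups is None:
        groups = pd.Series({c: c.rsplit("_", 1)[0] for c in df.columns})
    else:
        groups = pd.Series(groups)
    return CountMatrix(df, lengths, groups)


@pytest.fixture(scope="session")
def four_group_counts() -> CountMatrix:
    """Small deterministic 4-group matrix (2 reps each, 8 genes)."""
    rng = np.random.default_rng(99)
    cols = [f"{g}_{r}" for g in ("BSB", "YB", "2nBY", "3nBY") for r in (1, 2)]
    vals = rng.poisson(100, size=(8, len(cols)))
    df = pd.DataFrame(vals, index=[f"g{i}" for i in range(8)], columns=cols)
    return small_counts(df, lengths=rng.integers(500, 2000, size=8))


@pytest.fixture(scope="session")
def mix_sim():
    """The reference recovery simulation: 2000 genes, 3 reps, |log2FC|=3,
    dispersion 0.05, seed 3 — the study-sized mixture used for parameter
    recovery checks."""
    cfg = SimConfig(n_genes=2000, seed=3, nb_dispersion=0.05, effect_log2fc=3.0)
    counts, truth = simulate_counts(cfg)
    return cfg, counts, truth
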