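import logging

import numpy as np
import pandas as pd
import pytest

import ifnsynergy as ifs
from ifnsynergy.interaction import FactorialDesign

logging.getLogger("ifnsynergy").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_factorial():
    """A 300-gene factorial simulation with all planted classes."""
    cfg = ifs.SimFactorialConfig(n_genes=300, seed=11)
    counts, design, truth = ifs.generate_factorial(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def small_fits(small_factorial):
    _, counts, design, truth = small_factorial
    s = ifs.estimate_size_factors(counts)
    alpha = ifs.estimate_dispersion(counts, design, s)
    fits = ifs.fit_interaction(counts, design, s, alpha)
    return fits, truth


@pytest.fixture(scope="session")
def cohort_default():
    """The default 45-line paired cohort simulation."""
    cfg = ifs.SimCohortConfig(seed=5)
    untreated, treated, metadata, latent = ifs.generate_cohort(cfg)
    return cfg, untreated, treated, metadata, latent


def make_design(n_reps: int = 3) -> FactorialDesign:
    rows = []
    for a, b in ((0, 0), (1, 0), (0, 1), (1, 1)):
        for r in range(1, n_reps + 1):
            rows.append((f"A{a}B{b}r{r}", a, b, r))
    df = pd.DataFrame(rows, columns=["sample", "knockdown", "cytokine", "replicate"])
    return FactorialDesign(df.set_index("sample"))


def saturated_counts(means, n_reps: int = 3, genes=("g1",)) -> pd.DataFrame:
    """Counts equal to the given condition means exactly, replicated."""
    design = make_design(n_reps)
    cond = {(0, 0): means[0], (1, 0): means[1], (0, 1): means[2], (1, 1): means[3]}
    data = {
        s: [cond[(design.table.loc[s, "knockdown"], design.table.loc[s, "cytokine"])]] * len(genes)
        for s in design.table.index
    }
    return pd.DataFrame(data, index=list(genes)), design


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
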