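import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrscreen.gwas_data import HarmonizedSet, SummaryDataset

settings.register_profile("mrscreen", database=None, deadline=None)
settings.load_profile("mrscreen")


def make_harmonized(bx, by, sy, sx=None, exposure="exp", outcome="out"):
    """HarmonizedSet from raw arrays (sx defaults to sy's scale)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape).copy()
    sx = sy.copy() if sx is None else \
        np.broadcast_to(np.asarray(sx, dtype=float), bx.shape).copy()
    df = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(len(bx))],
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
        "eaf_exp": 0.5,
    })
    return HarmonizedSet(exposure, outcome, df)


def make_dataset(name="trait", **cols):
    """SummaryDataset from keyword columns, with sensible defaults."""
    n = len(next(iter(cols.values())))
    base = {
        "snp_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": ["1"] * n,
        "pos": list(range(1_000_000, 1_000_000 + 100_000 * n, 100_000)),
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [0.5] * n,
        "beta": [0.1] * n,
        "se": [0.01] * n,
        "pval": [1e-10] * n,
        "n": [100_000.0] * n,
    }
    base.update(cols)
    return SummaryDataset(name, pd.DataFrame(base))


@pytest.fixture
def toy_harmonized():
    rng = np.random.default_rng(7)
    bx = rng.normal(0.1, 0.03, 10)
    by = 0.4 * bx + rng.normal(0, 0.005, 10)
    return make_harmonized(bx, by, 0.005, sx=0.004)
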