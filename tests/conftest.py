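import numpy as np
import pandas as pd
import pytest

import rppashift as rs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix(rng):
    """20 probes x 6 samples, two groups of three, log2 scale."""
    vals = rng.normal(0.0, 0.3, size=(20, 6)) + rng.uniform(-2, 2, 20)[:, None]
    df = pd.DataFrame(
        vals,
        index=[f"p{i:02d}" for i in range(20)],
        columns=[f"s{i}" for i in range(6)],
    )
    return rs.ExpressionMatrix(df)


@pytest.fixture()
def two_group_samples():
    return rs.SampleTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "group": ["a"] * 3 + ["b"] * 3,
        "batch": ["run1"] * 6,
        "replicate": [1, 2, 3, 1, 2, 3],
        "cf1": 1.0,
        "cf2": 1.0,
    }))


def make_contrast_result(probe_ids, lfc, fdr, contrast_id="c", **extra):
    """Assemble a ContrastResult table directly from arrays (for modules
    that consume DE results rather than produce them)."""
    n = len(probe_ids)
    lfc = np.asarray(lfc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    table = pd.DataFrame({
        "lfc": lfc,
        "se": extra.get("se", np.full(n, 0.1)),
        "t": lfc / extra.get("se", np.full(n, 0.1)),
        "p": fdr,
        "fdr": fdr,
        "ci_low": extra.get("ci_low", lfc - 0.2),
        "ci_high": extra.get("ci_high", lfc + 0.2),
        "avg_expr": extra.get("avg_expr", np.zeros(n)),
    }, index=pd.Index(probe_ids, name="probe_id"))
    return rs.ContrastResult(contrast_id=contrast_id, coeffs={}, table=table)


@pytest.fixture()
def null_sim_config():
    """Null generator settings: no effects, no offsets, flat trend, the
    scaled-inverse-chi-square variance hierarchy exactly as moderated."""
    return rs.SimulationConfig(
        n_probes=500,
        n_phospho=100,
        scenario_fractions={},
        batch_offsets={},
        loading_offset_sd=0.0,
        trend_slope=0.0,
        var_s0_2=0.02,
        var_d0=4.0,
    )
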