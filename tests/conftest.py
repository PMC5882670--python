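"""Shared fixtures: synthetic datasets at two scales.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vitalrates as vr


@pytest.fixture(scope="session")
def default_sim():
    """Full study-scale simulated dataset (23 occasions, default rates)."""
    cfg = vr.SimConfig(seed=123)
    enc, truth = vr.simulate_population(cfg)
    return cfg, enc, truth


@pytest.fixture(scope="session")
def small_sim():
    """Small 9-occasion dataset for fast structural tests."""
    cfg = vr.SimConfig(
        occasions=vr.biannual_occasions("2004-09-15", 9),
        recruitment_mean=60,
        immigration_rate=8,
        seed=5,
    )
    enc, truth = vr.simulate_population(cfg)
    return cfg, enc, truth


@pytest.fixture(scope="session")
def growth_panel():
    """Longitudinal growth data from known parameters with cohort effects.

    120 fish, 4 September measurements each, individual random effects on
    both log k and log Linf; returns (data, truth_params, true_u, true_v).
    """
    rng = np.random.default_rng(21)
    cohorts = [2004, 2005, 2006]
    truth = vr.GrowthParams(
        log_k=np.log(0.3), log_linf=np.log(330.0), t0=-0.2,
        sigma_u=0.12, sigma_v=0.12, sigma_eps=3.0,
        k_group={2004: 0.0, 2005: 0.2, 2006: -0.15},
        linf_group={2004: 0.0, 2005: -0.1, 2006: 0.15},
    )
    rows, us, vs = [], {}, {}
    for i in range(120):
        c = cohorts[i % 3]
        u, v = rng.standard_normal(2)
        fid = f"F{i:03d}"
        us[fid], vs[fid] = u, v
        ages = np.array([1.25, 2.25, 3.25, 4.25])
        lengths = vr.vbgf_length(truth, ages, u=u, v=v, group=c) + rng.normal(0, 3.0, 4)
        for a, l in zip(ages, lengths):
            rows.append({"fish_id": fid, "age": a, "length_mm": l, "cohort": c})
    data = pd.DataFrame(rows)
    return data, truth, pd.Series(us), pd.Series(vs)


@pytest.fixture(scope="session")
def cjs_sim():
    """Study-scale dataset with tagged-fish detection ~0.84 per occasion
    (per-pass capture probability 0.6), the regime of the survival models."""
    q = 1 - np.sqrt(1 - 0.84)
    cfg = vr.SimConfig(capture_prob=q, seed=321)
    enc, truth = vr.simulate_population(cfg)
    return cfg, enc, truth
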