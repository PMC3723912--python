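import numpy as np
import pytest

from circaphos.synthdata import PhosphoSimParams, TraceParams, simulate_phospho_table


@pytest.fixture
def clean_cosine():
    """Noiseless 24 h cosine peaking at t=0, hourly samples over 120 h."""
    t = np.arange(0.0, 120.5, 1.0)
    return t, 1000.0 + 300.0 * np.cos(2.0 * np.pi * t / 24.0)


@pytest.fixture
def phospho_fixture():
    """Small phospho occurrence table with known truth (seeded)."""
    params = PhosphoSimParams(n_proteins=40, spike_fraction=0.15)
    table, truth = simulate_phospho_table(params, seed=11)
    return params, table, truth


@pytest.fixture
def group_columns():
    ga = [f"control_{i}" for i in range(1, 6)]
    gb = [f"case_{i}" for i in range(1, 6)]
    return ga, gb
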