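"""Shared fixtures: small simulated cohorts and oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hapmeth.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-architecture cohort shared across read-only tests."""
    cfg = SimulationConfig(
        n_samples=60,
        scenarios={"null": 60, "genetic_cis": 25, "genetic_distal": 15,
                   "imprinted_like": 15},
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_phased(rows, sample_prefix="S"):
    """Build a phased-counts frame from (pos, snp, sample, mA, uA, mB, uB)."""
    recs = [
        {"chrom": "chr1", "pos": pos, "strand": "+", "context": "CpG",
         "sample": f"{sample_prefix}{s}", "snp_id": snp,
         "methA": ma, "unmethA": ua, "methB": mb, "unmethB": ub}
        for pos, snp, s, ma, ua, mb, ub in rows
    ]
    return pd.DataFrame(recs)
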