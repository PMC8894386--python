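"""Shared fixtures: small synthetic cohorts analyzed once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from ctclsc.pipeline import analyze_sample
from ctclsc.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort1():
    """One-patient cohort with planted truth (seed 0)."""
    cfg = SimulationConfig(n_patients=1, seed=0)
    matrix, contigs, coords, variants, survival, truth = simulate_cohort(cfg)
    return {
        "config": cfg, "matrix": matrix, "contigs": contigs, "coords": coords,
        "variants": variants, "survival": survival, "truth": truth,
    }


@pytest.fixture(scope="session")
def analyzed1(cohort1):
    """The one-patient cohort run through the full per-sample chain."""
    return analyze_sample(
        cohort1["matrix"], cohort1["contigs"], cohort1["coords"],
        sample="P01-L1", seed=0,
    )


@pytest.fixture(scope="session")
def cohort3():
    """Three-patient cohort plus per-sample analysis results (seed 1)."""
    cfg = SimulationConfig(n_patients=3, seed=1)
    matrix, contigs, coords, variants, survival, truth = simulate_cohort(cfg)
    results = {
        sid: analyze_sample(matrix, contigs, coords, sample=sid, seed=0)
        for sid in sorted(set(matrix.sample_of_cell))
    }
    return {
        "matrix": matrix, "contigs": contigs, "coords": coords,
        "variants": variants, "truth": truth, "results": results,
    }


def truth_status(truth_cell_type: pd.Series) -> pd.Series:
    """Planted per-cell status at malignant/reactive granularity."""
    return truth_cell_type.map(
        lambda t: t if t.startswith("malignant") else "reactive"
    )
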