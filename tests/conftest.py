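from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proteoid.cohort_io import IntensityMatrix, SampleKey
from proteoid.synthetic_cohort import CohortConfig, simulate_cohort


def make_matrix(values, proteins, sample_keys) -> IntensityMatrix:
    """Build an IntensityMatrix from a 2-D array-like and (individual, tp) pairs."""
    samples = [k if isinstance(k, SampleKey) else SampleKey(*k) for k in sample_keys]
    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=list(proteins),
        columns=[s.label for s in samples],
    )
    return IntensityMatrix(values=frame, samples=samples)


def cohort_samples(n_individuals: int, n_timepoints: int) -> list[SampleKey]:
    return [
        SampleKey(f"I{i + 1:02d}", t + 1)
        for i in range(n_individuals)
        for t in range(n_timepoints)
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """The default 42 x 7 synthetic cohort (shared; treat as read-only)."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for faster integration-style tests."""
    return simulate_cohort(
        CohortConfig(
            n_individuals=8,
            n_timepoints=4,
            n_proteins=60,
            n_loci=12,
            erratic_gene_fraction=0.0,
            seed=7,
        )
    )
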