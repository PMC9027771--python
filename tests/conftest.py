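"""Shared fixtures: one default synthetic reference + cohort per session.

The expensive objects (single-cell reference, marker catalog, bulk cohort)
are generated once and reused; tests that need different parameters build
their own small instances.
"""

import numpy as np
import pytest
from hypothesis import settings

from bloodshift import de, markers, normalize, simulate
from bloodshift.datatypes import ExpressionMatrix, SampleRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sc_reference():
    """Default 12-type labeled single-cell reference (counts, labels, truth)."""
    return simulate.simulate_sc_reference(seed=1)


@pytest.fixture(scope="session")
def catalog(sc_reference):
    sc, labels, _ = sc_reference
    return markers.derive_markers(sc, labels)


@pytest.fixture(scope="session")
def bulk_cohort(sc_reference):
    """Default 7-donor paired cohort with the altitude shift pattern."""
    _, _, ref = sc_reference
    return simulate.simulate_bulk_cohort(ref, seed=100)


@pytest.fixture(scope="session")
def corrected_bulk(bulk_cohort):
    counts, meta, _ = bulk_cohort
    norm = normalize.normalize_counts(counts)
    return normalize.donor_center(norm.transformed, meta), meta


@pytest.fixture(scope="session")
def de_results(bulk_cohort):
    counts, meta, _ = bulk_cohort
    return de.paired_de(counts, meta)


def make_paired_meta(n_donors: int) -> list[SampleRecord]:
    meta = []
    for d in range(n_donors):
        donor = f"D{d + 1}"
        meta.append(SampleRecord(f"{donor}_before", donor, "before"))
        meta.append(SampleRecord(f"{donor}_after", donor, "after"))
    return meta


def make_counts(values, gene_ids=None, sample_ids=None, lengths=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"G{i}" for i in range(n_g)],
        sample_ids=sample_ids or [f"S{i}" for i in range(n_s)],
        values=values,
        unit="counts",
        gene_lengths_bp=lengths,
    )
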