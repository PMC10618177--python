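import dataclasses

import pandas as pd
import pytest

from progsplice.io_formats import SampleSheet
from progsplice.synthetic_data import CATEGORIES, SimConfig, make_sample_sheet


@pytest.fixture
def small_config() -> SimConfig:
    """Down-sized cohort for fast unit tests (full defaults stay for the
    acceptance suite)."""
    return SimConfig(
        n_features_per_category={c: 25 for c in CATEGORIES},
        n_splice_events=12,
        seed=101,
    )


@pytest.fixture
def sheet(small_config) -> SampleSheet:
    return make_sample_sheet(small_config)


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": ["A1", "A2", "A3", "B1", "B2", "B3"],
        "group": ["RD"] * 3 + ["HCC"] * 3,
    }))


def psi_frame(rows):
    """Build a PSI-record table from (event, gene, sample, inc, exc) tuples."""
    from progsplice.splicing import compute_psi
    out = []
    for ev, gene, sample, inc, exc in rows:
        psi, tier = compute_psi(inc, exc)
        out.append((ev, gene, sample, inc, exc, psi, tier))
    return pd.DataFrame(out, columns=["event_id", "gene_id", "sample_id",
                                      "inc_reads", "exc_reads", "psi", "coverage"])
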