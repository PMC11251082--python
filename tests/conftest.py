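"""Shared fixtures: committed toy files and session-scoped heavy analyses."""

from pathlib import Path

import pandas as pd
import pytest

from alveofate import SimConfig, generate_timecourse
from alveofate.containers import AnnotatedCounts
from alveofate.pipeline import branching_fate_analysis

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture(scope="session")
def wt_timecourse() -> AnnotatedCounts:
    """Small WT four-time-point dataset (600 cells)."""
    return generate_timecourse(SimConfig(n_cells_per_timepoint=150, seed=123))


@pytest.fixture(scope="session")
def kras_timecourse() -> AnnotatedCounts:
    return generate_timecourse(
        SimConfig(n_cells_per_timepoint=150, genotype="KRAS", seed=124)
    )


@pytest.fixture(scope="session")
def symmetric_branching_result() -> dict:
    """Full fate analysis of a symmetric Y-trajectory (~2000 cells)."""
    return branching_fate_analysis(seed=1, branch_asymmetry=0.5)


@pytest.fixture(scope="session")
def asymmetric_branching_result() -> dict:
    """Full fate analysis at branch_asymmetry 0.7 (~2000 cells)."""
    return branching_fate_analysis(seed=1, branch_asymmetry=0.7)


@pytest.fixture()
def qc_toy() -> AnnotatedCounts:
    """10-cell toy with mito fractions {0.05 x6, 0.25 x4}."""
    df = pd.read_csv(FIXTURES / "qc_toy" / "counts.tsv", sep="\t", index_col=0)
    return AnnotatedCounts(
        counts=df.to_numpy(),
        gene_symbols=list(df.columns),
        cell_meta=pd.DataFrame(index=df.index),
    )
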