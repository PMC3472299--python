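import numpy as np
import pandas as pd
import pytest

from uprflow import (
    ProbeIntensityMatrix,
    default_design,
    generate_probe_data,
    median_polish_summarize,
    quantile_normalize,
)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_expression(design):
    """Summarized expression from a small synthetic probe dataset."""
    probes, truth = generate_probe_data(
        design, n_genes=120, probes_per_gene=5, de_fraction=0.1, seed=7
    )
    normalized = ProbeIntensityMatrix(
        quantile_normalize(probes.values), probes.probe_to_probeset
    )
    return median_polish_summarize(normalized), truth


def summarize_pipeline(probes):
    normalized = ProbeIntensityMatrix(
        quantile_normalize(probes.values), probes.probe_to_probeset
    )
    return median_polish_summarize(normalized)
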