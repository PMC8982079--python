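"""Shared fixtures: synthetic sections at the default study scale.

The heavyweight simulations (200 x 200-spot chip, ~200k read pairs) are
session-scoped so the end-to-end checks share one run.
"""

import numpy as np
import pytest

from stereopipe import demux, quantify, synthetic


@pytest.fixture(scope="session")
def default_truth_section():
    """Default synthetic section, truth only (no read channel)."""
    return synthetic.simulate_section(seed=21, with_reads=False)


@pytest.fixture(scope="session")
def working_matrix(default_truth_section):
    """Truth counts aggregated to the desk-scale working resolution (bin 10)."""
    return default_truth_section.truth.binned_counts(10)


@pytest.fixture(scope="session")
def clean_run():
    """Error-free 200x200 channel: simulate -> demux -> count."""
    sec = synthetic.simulate_section(seed=11, error_model=synthetic.ErrorModel.clean())
    res = demux.demux_stream(sec.reads.read1, sec.reads.read2, sec.layout)
    mat, ratios = quantify.count_pipeline(
        res.records, sec.gene_panel, sec.layout.width, sec.layout.height
    )
    return {"section": sec, "demux": res, "matrix": mat, "ratios": ratios}


@pytest.fixture(scope="session")
def noisy_run():
    """Noisy 200x200 channel (1% invalid CID, 1% ambiguous, 2% low-quality
    UMI plus N/unmappable/multimap injections): simulate -> demux."""
    sec = synthetic.simulate_section(seed=11, error_model=synthetic.ErrorModel.noisy())
    res = demux.demux_stream(sec.reads.read1, sec.reads.read2, sec.layout)
    return {"section": sec, "demux": res}


@pytest.fixture(scope="session")
def small_chip():
    return synthetic.generate_chip(8, 8, seed=1)


@pytest.fixture(scope="session")
def gene_panel():
    return synthetic.make_gene_panel(seed=5)


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def region_module_truth():
    """Planted spatial co-expression groups: one per region, since types
    sharing a region share a spatial pattern (AT2 + fibroblast both live
    in the alveolar background)."""
    m = synthetic.TYPE_MARKERS
    return {
        "bronchiole": frozenset(m["Clara"]),
        "alveolar": frozenset(m["AT2"]) | frozenset(m["AlveolarFibroblast"]),
        "vessel": frozenset(m["SmoothMuscle"]),
        "immune": frozenset(m["Neutrophil"]),
    }
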