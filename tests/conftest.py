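import numpy as np
import pytest

from assocmod.module_builder import AnalysisContext
from assocmod.segmentation import assign_genes_to_segments, build_segments
from assocmod.synthetic_data import benchmark_suite


def make_context(ds):
    """Segment the CNV track and assemble an analysis context."""
    segments, g2s = [], {}
    if "cnv_probe" in ds.tracks:
        segments = build_segments(ds.tracks["cnv_probe"], ds.annotations)
        g2s = assign_genes_to_segments(
            ds.annotations, segments,
            [f for f, t in ds.annotations.items() if t.data_type != "cnv_probe"])
    return AnalysisContext(ds, segments, g2s)


@pytest.fixture(scope="session")
def bench():
    """One benchmark panel (seed 1) with all six planted module types."""
    (ds, truth), = benchmark_suite(1)
    return ds, truth


@pytest.fixture(scope="session")
def bench_ctx(bench):
    ds, truth = bench
    return make_context(ds), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
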