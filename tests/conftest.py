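import numpy as np
import pandas as pd
import pytest

from chdsig.datatypes import ExpressionMatrix, GeneAnnotation, SampleSheet


def make_matrix(values, probes=None, samples=None, detection=None):
    """Build an ExpressionMatrix from plain arrays with generated labels."""
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j:02d}" for j in range(values.shape[1])]
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, dtype=float), index=probes, columns=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), det)


def make_sheet(assignments):
    """sample -> group dict to SampleSheet."""
    return SampleSheet(
        pd.DataFrame({"group": pd.Series(assignments)}).rename_axis("sample_id")
    )


def make_annotation(rows):
    """rows: (probe_id, gene, chromosome, start) tuples; end = start + 100."""
    tab = pd.DataFrame(
        [(p, g, c, s, s + 100) for p, g, c, s in rows],
        columns=["probe_id", "gene", "chromosome", "start", "end"],
    ).set_index("probe_id")
    return GeneAnnotation(tab)


@pytest.fixture
def two_group_sheet():
    return make_sheet(
        {f"A{i}": "A" for i in range(3)} | {f"B{i}": "B" for i in range(3)}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
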