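import numpy as np
import pandas as pd
import pytest

from xtissue.core import ExpressionMatrix, SampleDesign, TissueProfile
from xtissue.pipeline import run_simulated


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_profile():
    """5 genes x 4 tissues with unambiguous argmax structure."""
    data = pd.DataFrame(
        {
            "gut": [1.0, 0.5, 9.0, 2.0, 0.0],
            "kidney": [2.0, 7.0, 1.0, 2.0, 0.0],
            "liver": [8.0, 7.0, 2.0, 2.0, 0.0],
            "lung": [0.5, 1.0, 0.5, 3.0, 0.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return TissueProfile(data)


@pytest.fixture
def random_expression(rng):
    """Random 12-gene x 9-sample matrix over 3 tissues."""
    samples = [f"s{i}" for i in range(9)]
    tissues = ["liver"] * 3 + ["kidney"] * 3 + ["gut"] * 3
    data = pd.DataFrame(
        rng.gamma(2.0, 5.0, size=(12, 9)),
        index=[f"g{i:02d}" for i in range(12)],
        columns=samples,
    )
    design = SampleDesign(
        raw_tissue=pd.Series(tissues, index=samples), tissue_group_map={}
    )
    return ExpressionMatrix(data), design


@pytest.fixture(scope="session")
def glk_run(tmp_path_factory):
    """One full pipeline run on the glk_default benchmark (default seed)."""
    outdir = tmp_path_factory.mktemp("glk_run")
    return run_simulated(seed=0, outdir=outdir), outdir
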