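import numpy as np
import pytest

from pcombine import CountTable, validate_pvalues

# the five published per-study p-values of the depression GWAS meta-analysis
FIVE_PVALUES = [0.94, 0.0015, 0.97, 0.79, 0.81]


@pytest.fixture
def five_pvalues():
    return validate_pvalues(FIVE_PVALUES)


@pytest.fixture
def table1():
    """The five-study case/control count table of the depression GWAS."""
    return CountTable(
        labels=["1", "2", "3", "4", "5"],
        case_event=np.array([11, 244, 49, 79, 71]),
        case_total=np.array([270, 1016, 234, 600, 290]),
        control_event=np.array([25, 282, 35, 76, 86]),
        control_total=np.array([630, 926, 166, 600, 340]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
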