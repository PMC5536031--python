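import numpy as np
import pytest

from hotspot_rp import SyntheticSpec, generate_corpus, worked_fixture


@pytest.fixture(scope="session")
def worked_corpus():
    """Tiny deterministic corpus: 2 x 15 residues, 3 properties."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_corpus():
    """Small random corpus with enough positives for split-based tests."""
    spec = SyntheticSpec(
        n_sequences=4, length_range=(25, 40), prevalence=0.15,
        n_properties=5, seed=7,
    )
    return generate_corpus(spec)


AAINDEX_3RECORDS = """\
H TESTA00101
D ramp of integers one to twenty
R PMID:0000000
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
       1.       2.       3.       4.       5.       6.       7.       8.       9.      10.
      11.      12.      13.      14.      15.      16.      17.      18.      19.      20.
//
H TESTB00101
D all cells missing
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      NA      NA      NA      NA      NA      NA      NA      NA      NA      NA
      NA      NA      NA      NA      NA      1.0     NA      NA      NA      NA
//
H TESTC00101
D halves
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.5      0.5      0.5      0.5      0.5      0.5      0.5      0.5      0.5      0.5
     0.5      0.5      0.5      0.5      0.5      0.5      0.5      0.5      0.5      0.5
//
"""


@pytest.fixture
def aaindex_path(tmp_path):
    path = tmp_path / "aaindex1.txt"
    path.write_text(AAINDEX_3RECORDS)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
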