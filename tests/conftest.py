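"""Shared fixtures: a small hand-written table and its expected structure."""

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# 2 complexes (3 + 2 subunits) x 4 taxa, annotation row in use.
SMALL_CSV = """\
,,Excavata,Excavata,Opisthokonta,Opisthokonta
,,Discoba,Discoba,Metazoa,Fungi
,,Tbrucei,Lmajor,Hsapiens,Scerevisiae
,,strainA,strainB,ref,lab
CplxA,a1,+,+,+,+
,a2,+,-,+,-
,a3,-,-,+,+
CplxB,b1,1,0,1,1
,b2,0,0,1,1
"""

SMALL_OCCUPANCY = [
    [True, True, True, True],
    [True, False, True, False],
    [False, False, True, True],
    [True, False, True, True],
    [False, False, True, True],
]


@pytest.fixture
def small_csv() -> str:
    return SMALL_CSV


@pytest.fixture
def small_dataset(small_csv):
    from coulson import io_format

    ds, report = io_format.build_dataset(io_format.parse_table(small_csv))
    assert ds is not None and not report.errors
    return ds
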