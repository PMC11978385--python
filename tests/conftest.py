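import io

import pytest

from mafscan.maf_io import parse_maf


def parse_text(maf_text):
    """Parse MAF text given as a string (tests convenience)."""
    return list(parse_maf(io.StringIO(maf_text)))


@pytest.fixture
def two_block_maf():
    return (
        "##maf version=1\n"
        "a score=5.0\n"
        "s hg.chr1 10 4 + 100 AC-GT\n"
        "s mm.chr1  3 5 + 50  ACAGT\n"
        "\n"
        "a score=1.0\n"
        "s hg.chr1 14 6 + 100 GATTAC\n"
        "s mm.chr1  8 6 + 50  GATTAC\n"
        "s rn.chr2  0 6 - 40  GAGTAC\n"
        "\n"
    )


@pytest.fixture
def two_blocks(two_block_maf):
    return parse_text(two_block_maf)
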