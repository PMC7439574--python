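import pytest

from methamp import Amplicon

# 60 bp toy target with 5 CpGs, used across the amplicon-level tests
TOY_SEQUENCE = "ATGGACGTTACGGATTCGAATCCGTTAGGACCTTAGCAATTCGTTAAGGTCATGCATGCA"


@pytest.fixture(scope="session")
def toy_amplicon() -> Amplicon:
    return Amplicon.from_sequence("toy", TOY_SEQUENCE)
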