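import numpy as np
import pytest

from phagepan import (
    BarcodeTable,
    DEFAULT_BARCODES,
    DegenerateCodonScheme,
    QualityPolicy,
    ReadPair,
)
from phagepan.codons import revcomp
from phagepan.fastq import PHRED_OFFSET

Q40 = chr(PHRED_OFFSET + 40)


@pytest.fixture(scope="session")
def scheme() -> DegenerateCodonScheme:
    return DegenerateCodonScheme()


@pytest.fixture(scope="session")
def barcode_table() -> BarcodeTable:
    return BarcodeTable(entries=dict(DEFAULT_BARCODES), max_mismatch=1)


@pytest.fixture(scope="session")
def policy() -> QualityPolicy:
    return QualityPolicy()


def planted_pair(
    scheme: DegenerateCodonScheme,
    insert: str,
    barcode: str = DEFAULT_BARCODES["vh4_r0"],
    read_id: str = "pair1",
) -> ReadPair:
    """Noiseless read pair carrying ``insert`` between the scheme anchors."""
    amplicon = barcode + scheme.flank_upstream + insert + scheme.flank_downstream
    qual = Q40 * len(amplicon)
    return ReadPair(read_id, amplicon, qual, revcomp(amplicon), qual)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)
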