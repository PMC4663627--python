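from pathlib import Path

import pytest

from srnaduplex.sra_io import load_reads

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def ds0_strands() -> dict[str, str]:
    """The reference perfect-duplex strands from the shipped fixture file."""
    from Bio import SeqIO

    records = {r.id: str(r.seq) for r in SeqIO.parse(DATA_DIR / "ds_srna0.fasta", "fasta")}
    return {
        "positive": records["ds_srna0_positive"],
        "negative": records["ds_srna0_negative"],
        "negative_as_printed": records["ds_srna0_negative_as_printed"],
    }
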