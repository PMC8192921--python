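import numpy as np
import pytest

from seqmoments.sequence_io import ALPHABET, NucleotideSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, seq_id="s"):
    bases = "".join(rng.choice(list(ALPHABET), size=length))
    return NucleotideSequence(id=seq_id, bases=bases)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with path.open("w") as fh:
            for seq_id, bases in records:
                fh.write(f">{seq_id}\n{bases}\n")
        return path

    return _write
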