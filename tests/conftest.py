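import numpy as np
import pytest

from snptree.seqio import Read


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_reads(sequences, sample="s", prefix="r"):
    """Wrap plain sequence strings as labelled reads."""
    return [Read(f"{prefix}{i}", seq, sample) for i, seq in enumerate(sequences)]


def tile_reads(source, read_length=40, step=5, sample="s", prefix="r"):
    """Error-free reads tiling *source* at fixed step (plus one flush at the end)."""
    seqs = [source[i : i + read_length] for i in range(0, len(source) - read_length + 1, step)]
    if (len(source) - read_length) % step:
        seqs.append(source[-read_length:])
    return make_reads(seqs, sample=sample, prefix=f"{prefix}_{sample}")


def random_sequence(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
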