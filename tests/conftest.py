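import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from rsnpscan.io import Genome, read_genome
from rsnpscan.types import Pwm


def write_fasta(path, seqs, width=60):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return str(path)


@pytest.fixture
def make_genome(tmp_path):
    """Factory: dict of sequences -> Genome over a temp FASTA."""

    def _make(seqs, name="genome.fa"):
        return read_genome(write_fasta(tmp_path / name, seqs))

    return _make


@pytest.fixture
def tata_pwm():
    """Sharp 6-mer matrix with consensus TATAAA and default-like cutoffs."""
    counts = np.zeros((6, 4))
    for i, b in enumerate("TATAAA"):
        counts[i, "ACGT".index(b)] = 10
    return Pwm("P$TATA_01", counts, core_cutoff=0.75, matrix_cutoff=0.85)


def random_counts(rng, width, max_count=20):
    """Random nonnegative integer count matrix of the given width."""
    return rng.integers(0, max_count + 1, size=(width, 4)).astype(float)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
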