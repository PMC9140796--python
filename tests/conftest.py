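import numpy as np
import pytest

from mhc2popkit import make_alignment


@pytest.fixture
def tiny_alignment():
    """Three 9-nt in-frame haplotypes with two segregating sites."""
    return make_alignment(
        [("h1", "ATGAAATTT"), ("h2", "ATGAAATTC"), ("h3", "ATGACATTT")]
    )


@pytest.fixture
def random_alignment_factory():
    """Factory for random in-frame alignments (mutation rate per site ~ 0.08)."""

    stops = {"TAA", "TAG", "TGA"}

    def has_stop(seq):
        return any(seq[k : k + 3] in stops for k in range(0, len(seq), 3))

    def make(n=6, n_codons=10, seed=0, coding=False):
        rng = np.random.default_rng(seed)
        L = 3 * n_codons
        base = "".join(rng.choice(list("ACGT"), L))
        while coding and has_stop(base):
            base = "".join(rng.choice(list("ACGT"), L))
        recs = []
        for i in range(n):
            while True:
                s = list(base)
                for j in range(L):
                    if rng.random() < 0.08:
                        s[j] = str(rng.choice(list("ACGT")))
                seq = "".join(s)
                if not coding or not has_stop(seq):
                    break
            recs.append((f"t{i}", seq))
        return make_alignment(recs, expected_length=None)

    return make
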