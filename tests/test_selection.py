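import math
from itertools import permutations, product

import numpy as np
import pytest

from mhc2popkit import (
    make_alignment,
    translate,
    ng_dn_ds,
    z_test_selection,
    wu_kabat_profile,
    codon_pair_counts,
    potential_sites,
)
from mhc2popkit.seqio import PeptideSequence

BASES = "TCAG"
CODON_TABLE = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for idx, (a, b, c) in enumerate(product(BASES, repeat=3)):
    CODON_TABLE[a + b + c] = _AA[idx]
SENSE = [c for c, aa in CODON_TABLE.items() if aa != "*"]


def oracle_pair_counts(a, b):
    """Independent pathway enumeration for one codon pair."""
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(diff):
        cur, syn, non, hit = a, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*" or CODON_TABLE[cur] == "*":
                hit = True
                non += 1
            elif CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        (blocked if hit else clean).append((syn, non))
    paths = clean or blocked
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


class TestPathwayCounting:
    def test_matches_exhaustive_enumeration_all_sense_pairs(self):
        for a in SENSE:
            for b in SENSE:
                got = codon_pair_counts(a, b)
                want = oracle_pair_counts(a, b)
                assert got == pytest.approx(want), (a, b)

    def test_changes_conserved(self):
        # syn + nonsyn equals the number of differing positions
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.choice(SENSE, 2)
            s, n = codon_pair_counts(a, b)
            ndiff = sum(x != y for x, y in zip(a, b))
            assert s + n == pytest.approx(ndiff)

    def test_sites_conserved(self):
        for codon in SENSE:
            s, n = potential_sites(codon)
            assert s + n == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "codon,expected_s",
        [("TTT", 1 / 3), ("GGG", 1.0), ("AAA", 1 / 3), ("ATG", 0.0)],
    )
    def test_potential_sites_hand_values(self, codon, expected_s):
        assert potential_sites(codon)[0] == pytest.approx(expected_s)


class TestNGDistance:
    def test_identical_sequences_zero(self):
        aln = make_alignment([("a", "ATGAAACCC"), ("b", "ATGAAACCC")])
        res = ng_dn_ds(aln, bootstrap_reps=50, seed=0)
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.Z == 0.0 and res.p_neq == 1.0

    def test_single_synonymous_difference_closed_form(self):
        # TTT->TTC synonymous; S_sites = (1/3 + 1 + 1/3) = 5/3 per sequence
        aln = make_alignment([("a", "TTTGGGAAA"), ("b", "TTCGGGAAA")])
        res = ng_dn_ds(aln, bootstrap_reps=0)
        pS = 1.0 / (5 / 3)
        assert res.dS == pytest.approx(-0.75 * math.log(1 - 4 / 3 * pS))
        assert res.dN == 0.0
        assert res.omega == 0.0

    def test_no_correction_reduces_to_p(self):
        aln = make_alignment([("a", "TTTGGGAAA"), ("b", "TTCGGGAAA")])
        res = ng_dn_ds(aln, correction="none", bootstrap_reps=0)
        assert res.dS == pytest.approx(0.6)
        assert res.dN == 0.0

    def test_omega_undefined_when_ds_zero(self):
        aln = make_alignment([("a", "ATGAAACCC"), ("b", "ATGAGACCC")])
        res = ng_dn_ds(aln, bootstrap_reps=0)
        assert res.dS == 0.0 and res.dN > 0.0
        assert res.omega is None

    def test_stop_codons_rejected(self):
        aln = make_alignment([("a", "ATGTAACCC"), ("b", "ATGTAACCC")])
        with pytest.raises(ValueError, match="stop"):
            ng_dn_ds(aln, bootstrap_reps=0)

    def test_bootstrap_reproducible(self, random_alignment_factory):
        aln = random_alignment_factory(n=5, n_codons=8, seed=12, coding=True)
        r1 = ng_dn_ds(aln, bootstrap_reps=100, seed=5)
        r2 = ng_dn_ds(aln, bootstrap_reps=100, seed=5)
        assert r1 == r2


class TestZTest:
    def test_equal_rates_give_z_zero(self):
        Z, p = z_test_selection(0.1, 0.01, 0.1, 0.01, "neq")
        assert Z == 0.0 and p == 1.0
        _, p_pos = z_test_selection(0.1, 0.01, 0.1, 0.01, "pos")
        assert p_pos == 0.5

    def test_normal_quantile(self):
        # Z = 1.96 two-tailed -> p ~ 0.05
        Z, p = z_test_selection(1.96, 0.5, 0.0, 0.5, "neq")
        assert Z == pytest.approx(1.96)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            z_test_selection(0.1, 0.0, 0.2, 0.0)


def _peps(rows):
    return [PeptideSequence(id=f"p{i}", aa=r, stop_positions=()) for i, r in enumerate(rows)]


class TestWuKabat:
    def test_invariant_site_scores_one(self):
        prof = wu_kabat_profile(_peps(["AA", "AA", "AA", "AA"]))
        assert prof.W[0] == 1.0

    def test_all_distinct_residues(self):
        prof = wu_kabat_profile(_peps(["AK", "SK", "TK", "VK"]))
        assert prof.W[0] == 16.0  # 4 * 4 / 1

    def test_direct_formula(self):
        rows = ["A"] * 5 + ["S"] * 3 + ["T"] * 2
        prof = wu_kabat_profile(_peps(rows))
        assert prof.W[0] == pytest.approx(10 * 3 / 5)

    def test_polymorphic_sites_threshold(self):
        # site 1 hypervariable, sites 2-4 invariant
        rows = ["AKLM", "SKLM", "TKLM", "VKLM", "GKLM"]
        prof = wu_kabat_profile(_peps(rows))
        assert prof.polymorphic_sites == (1,)

    def test_conserved_runs(self):
        rows = ["AKLMNPQR", "SKLMNPQR"]
        prof = wu_kabat_profile(_peps(rows), min_run=6)
        assert prof.conserved_runs == ((2, 8),)

    def test_permutation_invariance_and_monotonicity(self):
        rows = ["AKL", "AKL", "SKL"]
        p1 = wu_kabat_profile(_peps(rows))
        p2 = wu_kabat_profile(_peps(rows[::-1]))
        assert np.allclose(p1.W, p2.W)
        # adding a new residue at site 1 cannot decrease k there
        p3 = wu_kabat_profile(_peps(rows + ["TKL"]))
        assert p3.W[0] >= p1.W[0]
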