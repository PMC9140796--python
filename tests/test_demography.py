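import math

import numpy as np
import pytest

from mhc2popkit import (
    make_alignment,
    tajima_d,
    fu_fs,
    r2_statistic,
    coalescent_null,
    mismatch_observed,
    mismatch_expected,
    fit_sudden_expansion,
    raggedness,
    expansion_time,
    pairwise_diversity,
    segregating_sites,
    simulate_coalescent_sample,
)
from mhc2popkit.demography import (
    ewens_log_pmf,
    simulate_null_statistics,
    neutrality_summary,
)


def oracle_tajima_d(n, S, K):
    """From-scratch constant evaluation, independent of the implementation."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (K - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimaD:
    def test_zero_when_estimators_agree(self):
        n = 10
        a1 = sum(1 / i for i in range(1, n))
        S = 5
        assert tajima_d(n, S, S / a1) == pytest.approx(0.0)

    def test_matches_constant_oracle(self):
        assert tajima_d(4, 3, 1.5) == pytest.approx(oracle_tajima_d(4, 3, 1.5), abs=1e-12)

    def test_oracle_parity_on_random_alignments(self, random_alignment_factory):
        for seed in range(20):
            aln = random_alignment_factory(n=6, n_codons=12, seed=seed)
            S = segregating_sites(aln)
            if S == 0:
                continue
            K, _ = pairwise_diversity(aln)
            assert tajima_d(aln.n, S, K) == pytest.approx(
                oracle_tajima_d(aln.n, S, K), abs=1e-12
            )

    def test_matches_dendropy(self, random_alignment_factory):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import popgenstat

        aln = random_alignment_factory(n=8, n_codons=15, seed=42)
        mat = dendropy.DnaCharacterMatrix.from_dict(dict(aln.records))
        S = segregating_sites(aln)
        K, _ = pairwise_diversity(aln)
        assert tajima_d(aln.n, S, K) == pytest.approx(
            popgenstat.tajimas_d(mat), abs=1e-10
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajima_d(3, 2, 1.0)


class TestFuFs:
    def test_pair_analytic(self):
        # n=2: P(K>=2) = theta/(1+theta); theta=1 -> 0.5 -> Fs = 0
        assert fu_fs(2, 1.0, 2) == pytest.approx(0.0, abs=1e-12)

    def test_boundary_undefined(self):
        assert math.isnan(fu_fs(2, 1.0, 1))  # S' = 1
        assert math.isnan(fu_fs(5, 0.0, 3))  # K = 0

    def test_ewens_normalizes(self):
        for n in (5, 20, 100):
            for theta in (0.1, 1.0, 10.0):
                total = np.exp(ewens_log_pmf(n, theta)).sum()
                assert total == pytest.approx(1.0, abs=1e-10)

    def test_exhaustive_ewens_oracle_n5(self):
        # direct enumeration of |s(n,k)| for n=5: 24, 50, 35, 10, 1
        theta = 2.0
        stirling = {1: 24, 2: 50, 3: 35, 4: 10, 5: 1}
        denom = theta * (theta + 1) * (theta + 2) * (theta + 3) * (theta + 4)
        pmf = {k: stirling[k] * theta**k / denom for k in stirling}
        assert sum(pmf.values()) == pytest.approx(1.0)
        s_prime = pmf[4] + pmf[5]
        expected = math.log(s_prime / (1 - s_prime))
        assert fu_fs(5, theta, 4) == pytest.approx(expected, abs=1e-10)


class TestR2:
    def test_direct_enumeration(self):
        # n=4, one singleton site carried by the first sequence
        aln = make_alignment(
            [("a", "TAAAAA"), ("b", "AAAAAA"), ("c", "AAAAAA"), ("d", "AAAAAA")]
        )
        # S=1, K=0.5, U=(1,0,0,0)
        expected = math.sqrt((0.75**2 + 3 * 0.25**2) / 4) / 1
        assert r2_statistic(aln) == pytest.approx(expected, abs=1e-12)

    def test_identical_sample_is_missing(self):
        aln = make_alignment([("a", "AAA")] * 1 + [("b", "AAA"), ("c", "AAA"), ("d", "AAA")])
        assert math.isnan(r2_statistic(aln))

    def test_oracle_parity_on_random_alignments(self, random_alignment_factory):
        for seed in range(20):
            aln = random_alignment_factory(n=5, n_codons=10, seed=seed + 100)
            S = segregating_sites(aln)
            if S == 0:
                continue
            K, _ = pairwise_diversity(aln)
            # independent from-scratch evaluation
            mat = np.array([list(s) for s in aln.seqs])
            U = np.zeros(aln.n)
            for j in range(mat.shape[1]):
                vals, counts = np.unique(mat[:, j], return_counts=True)
                if len(vals) < 2:
                    continue
                for v, c in zip(vals, counts):
                    if c == 1:
                        U[np.where(mat[:, j] == v)[0][0]] += 1
            expected = math.sqrt(np.mean((U - K / 2) ** 2)) / S
            assert r2_statistic(aln) == pytest.approx(expected, abs=1e-12)


class TestCoalescentNull:
    def test_null_median_gives_half(self):
        null = simulate_null_statistics(n=20, S=10, reps=2000, seed=3)["D"]
        med = float(np.nanmedian(null))
        p = coalescent_null("D", med, n=20, S_obs=10, reps=2000, seed=3)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_extreme_value_has_tiny_p(self):
        p = coalescent_null("D", -5.0, n=20, S_obs=10, reps=1000, seed=4)
        assert p < 0.001

    def test_null_d_mean_near_zero(self):
        null = simulate_null_statistics(n=30, S=20, reps=3000, seed=5)
        assert abs(np.nanmean(null["D"])) < 0.15
        assert abs(np.nanmean(null["Fs"])) < 0.3

    def test_seed_reproducibility(self):
        a = simulate_null_statistics(n=10, S=5, reps=50, seed=9)
        b = simulate_null_statistics(n=10, S=5, reps=50, seed=9)
        assert np.array_equal(a["D"], b["D"], equal_nan=True)


class TestMismatch:
    def test_observed_two_sequences(self):
        aln = make_alignment([("a", "AAATTT"), ("b", "AATTTA")])
        F = mismatch_observed(aln)
        assert F[2] == 1.0 and F.sum() == 1.0

    def test_observed_enumeration(self):
        aln = make_alignment([("a", "AAAAAA"), ("b", "AATAAA"), ("c", "ATTAAA")])
        F = mismatch_observed(aln)
        assert F[1] == pytest.approx(2 / 3)
        assert F[2] == pytest.approx(1 / 3)

    def test_expected_equilibrium_geometric(self):
        for theta in (0.5, 1.0, 3.0):
            F = mismatch_expected(4.0, theta, theta, 20)
            i = np.arange(21)
            geometric = theta**i / (1 + theta) ** (i + 1)
            assert np.allclose(F, geometric, atol=1e-14)

    def test_expected_large_tau_reaches_equilibrium_at_theta1(self):
        F = mismatch_expected(500.0, 1.0, 5.0, 15)
        i = np.arange(16)
        geometric = 5.0**i / 6.0 ** (i + 1)
        assert np.allclose(F, geometric, atol=1e-12)

    def test_expected_matches_monte_carlo(self):
        tau, th0, th1 = 5.0, 1.0, 50.0
        rng = np.random.default_rng(11)
        n_mc = 1_000_000
        # piecewise-exponential coalescence time then Poisson mutations
        t = rng.exponential(th1, size=n_mc)
        deep = t >= tau
        t[deep] = tau + rng.exponential(th0, size=deep.sum())
        diffs = rng.poisson(t)
        d_max = 30
        counts = np.bincount(np.clip(diffs, 0, d_max + 1), minlength=d_max + 2)
        mc = counts[: d_max + 1] / n_mc
        F = mismatch_expected(tau, th0, th1, d_max)
        # 3-SE binomial check per class where the normal approximation holds
        # (expected count >= 5); sparse classes compared as one aggregate
        se = np.sqrt(F * (1 - F) / n_mc)
        dense = F * n_mc >= 5
        assert np.all(np.abs(F - mc)[dense] <= 3 * se[dense])
        p_sparse = F[~dense].sum()
        se_sparse = math.sqrt(p_sparse * (1 - p_sparse) / n_mc)
        assert abs(mc[~dense].sum() - p_sparse) <= 3 * se_sparse + 1e-8

    def test_mass_truncated_not_exceeding_one(self):
        F = mismatch_expected(3.0, 1.0, 20.0, 10)
        assert F.sum() <= 1.0 + 1e-12

    def test_raggedness_conventions(self):
        assert raggedness(np.array([0.5, 0.5])) == 0.0
        assert raggedness(np.array([1.0])) == 0.0
        # unimodal smoother than multimodal
        uni = np.array([0.1, 0.3, 0.4, 0.15, 0.05])
        multi = np.array([0.35, 0.05, 0.3, 0.05, 0.25])
        assert raggedness(uni) < raggedness(multi)


class TestSuddenExpansionFit:
    def test_self_fit_recovers_parameters(self):
        F = mismatch_expected(5.0, 1.0, 30.0, 40)
        F = F / F.sum()
        fit = fit_sudden_expansion(F, n=60, reps=0)
        assert fit.tau == pytest.approx(5.0, abs=0.1)
        assert fit.SSD < 1e-6

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            fit_sudden_expansion(np.array([0.5, 0.5]), n=10, reps=0)

    def test_bootstrap_p_values_and_ci(self):
        rng_aln = simulate_coalescent_sample(
            n=40, L=600, theta0=1.0, theta1=20.0, tau=5.0, seed=21
        )
        F = mismatch_observed(rng_aln)
        fit = fit_sudden_expansion(F, n=40, reps=30, seed=2)
        assert 0.0 <= fit.p_SSD <= 1.0
        assert 0.0 <= fit.p_rg <= 1.0
        assert fit.ci_tau[0] <= fit.ci_tau[1]


class TestExpansionTime:
    @pytest.mark.parametrize(
        "tau,u,expected",
        [(19.82, 0.00177, 28), (19.82, 0.00160, 31), (0.0, 0.001, 0)],
    )
    def test_conversion(self, tau, u, expected):
        assert expansion_time(tau, u, 198).t_rounded == expected

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            expansion_time(1.0, 0.0, 198)


class TestNeutralitySummary:
    def test_summary_on_expansion_sample(self):
        aln = simulate_coalescent_sample(
            n=25, L=600, theta0=0.5, theta1=10.0, tau=4.0, seed=33
        )
        res = neutrality_summary(aln, reps=300, seed=7)
        assert res.n == 25 and res.S >= 1
        assert 0.0 <= res.p_D <= 1.0
        # recent expansion should push D and Fs negative
        assert res.tajima_D < 0.5
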