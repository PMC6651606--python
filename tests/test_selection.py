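"""Ka/Ks estimation, the GY94 likelihood machinery and the neutrality LRT."""

import math
import warnings

import numpy as np
import pytest

from upsdiverge._codon import CODON_INDEX, SENSE_CODONS, UNIFORM_FREQS
from upsdiverge.selection import (
    CodonAlignment,
    age_trend,
    backthread_codons,
    fit_pair,
    gy94_loglik,
    lineage_compare,
    ml_ka_ks,
    neutrality_test,
    ng86_counts,
    spearman_trend,
    SelectionResult,
)
from upsdiverge.selection import _ng86_site_fractions
from upsdiverge.synthetic_data import evolve_codon_pair


def _aln(t=0.3, omega=0.4, length=300, seed=1, kappa=2.0):
    a, b = evolve_codon_pair(length, t, kappa, omega, seed=seed)
    return CodonAlignment(a, b)


class TestCodonAlignment:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CodonAlignment("ATGAAA", "ATG")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment("ATGTAAAAA", "ATGAAAAAA")


class TestNG86:
    def test_identical_sequences_have_zero_rates(self):
        r = ng86_counts(CodonAlignment("ATGAAACGT", "ATGAAACGT"))
        assert r.s_diffs == r.n_diffs == 0
        assert r.ka == 0 and r.ks == 0

    def test_phe_to_leu_counts_one_nonsynonymous_difference(self):
        r = ng86_counts(CodonAlignment("TTT", "TTA"))
        assert r.n_diffs == 1 and r.s_diffs == 0

    def test_lysine_codon_synonymous_site_fraction(self):
        # AAA: only AAG (Lys) is synonymous at position 3; AAC/AAT are Asn
        fractions = _ng86_site_fractions()
        assert fractions[CODON_INDEX["AAA"]] == pytest.approx(1.0 / 3.0)

    def test_site_counts_sum_to_three_per_codon(self):
        fractions = _ng86_site_fractions()
        assert np.all(fractions >= 0) and np.all(fractions <= 3)
        r = ng86_counts(_aln())
        assert r.s_sites + r.n_sites == pytest.approx(3 * 300)

    def test_saturation_flagged_as_undefined(self):
        # maximal per-site divergence drives the JC argument non-positive
        r = ng86_counts(CodonAlignment("AGA" * 4, "CGC" * 4))  # Arg vs Arg, 2 syn diffs/codon
        assert not r.ks_defined and math.isnan(r.ks)

    def test_agrees_with_independent_biopython_oracle(self):
        pytest.importorskip("Bio.codonalign")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for seed in (1, 2, 3):
            aln = _aln(seed=seed)
            ours = ng86_counts(aln)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(CodonSeq(aln.seq_a), CodonSeq(aln.seq_b), method="NG86")
            assert ours.ka == pytest.approx(dn, rel=0.03, abs=5e-3)
            assert ours.ks == pytest.approx(ds, rel=0.06, abs=5e-3)


class TestGY94Loglik:
    def test_zero_branch_identical_pair_gives_sum_log_pi(self):
        aln = CodonAlignment("ATGAAA", "ATGAAA")
        expected = 2 * math.log(1.0 / 61.0)
        assert gy94_loglik(aln, 0.0, 2.0, 0.5) == pytest.approx(expected)

    def test_time_reversibility_under_sequence_swap(self):
        aln = _aln()
        swapped = CodonAlignment(aln.seq_b, aln.seq_a)
        ll = gy94_loglik(aln, 0.4, 2.0, 0.5)
        assert gy94_loglik(swapped, 0.4, 2.0, 0.5) == pytest.approx(ll, abs=1e-8)

    def test_likelihood_decreases_with_t_for_identical_pair(self):
        aln = CodonAlignment("ATG", "ATG")
        lls = [gy94_loglik(aln, t, 2.0, 1.0) for t in (0.0, 0.01, 0.1, 1.0)]
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestFitPair:
    def test_identical_sequences_fit_to_zero_divergence(self):
        seq = evolve_codon_pair(200, 0.0, 2.0, 1.0, seed=5)[0]
        fit = fit_pair(CodonAlignment(seq, seq))
        assert fit.t <= 1e-4

    def test_fixed_omega_honored(self):
        fit = fit_pair(_aln(), fix_omega=1.0)
        assert fit.omega == 1.0

    def test_fit_deterministic(self):
        aln = _aln(seed=7)
        f1, f2 = fit_pair(aln), fit_pair(aln)
        assert (f1.t, f1.kappa, f1.omega, f1.lnl) == (f2.t, f2.kappa, f2.omega, f2.lnl)

    def test_parameter_recovery_on_moderate_divergence(self):
        estimates = [fit_pair(_aln(t=0.5, omega=0.2, length=500, seed=s)).omega for s in range(8)]
        assert 0.15 <= float(np.median(estimates)) <= 0.25


class TestMlKaKs:
    def test_omega_one_gives_equal_rates(self):
        fit = fit_pair(_aln(omega=1.0, seed=3), fix_omega=1.0)
        ka, ks = ml_ka_ks(fit, _aln(omega=1.0, seed=3))
        assert ka == pytest.approx(ks)

    def test_ratio_equals_fitted_omega(self):
        aln = _aln(seed=9)
        fit = fit_pair(aln)
        ka, ks = ml_ka_ks(fit, aln)
        assert ka / ks == pytest.approx(fit.omega, rel=1e-6)

    def test_concordant_with_ng86_at_low_divergence(self):
        ratios_ka, ratios_ks = [], []
        for seed in range(6):
            aln = _aln(t=0.15, omega=0.3, length=400, seed=seed)
            ng = ng86_counts(aln)
            fit = fit_pair(aln)
            ka, ks = ml_ka_ks(fit, aln)
            if ng.ka > 0 and ng.ks > 0:
                ratios_ka.append(ka / ng.ka)
                ratios_ks.append(ks / ng.ks)
        assert 0.8 <= float(np.median(ratios_ka)) <= 1.2
        assert 0.8 <= float(np.median(ratios_ks)) <= 1.2


class TestNeutralityTest:
    def test_identical_sequences_called_neutral_with_zero_lr(self):
        seq = evolve_codon_pair(150, 0.0, 2.0, 1.0, seed=2)[0]
        res = neutrality_test(CodonAlignment(seq, seq))
        assert res.lr == pytest.approx(0.0, abs=1e-3)
        assert res.neutral

    def test_strong_purifying_selection_rejected_as_neutral(self):
        hits = 0
        for seed in range(5):
            res = neutrality_test(_aln(t=0.5, omega=0.05, length=500, seed=seed))
            hits += not res.neutral
        assert hits == 5

    def test_neutral_simulation_mostly_accepted(self):
        accepted = 0
        for seed in range(10):
            res = neutrality_test(_aln(t=0.5, omega=1.0, length=500, seed=100 + seed))
            accepted += res.neutral
        assert accepted >= 8

    def test_lr_invariant_to_sequence_order(self):
        aln = _aln(seed=4)
        swapped = CodonAlignment(aln.seq_b, aln.seq_a)
        assert neutrality_test(aln).lr == pytest.approx(neutrality_test(swapped).lr, abs=1e-4)


class TestBackthread:
    def test_gapped_columns_dropped(self):
        aln = backthread_codons("M-K", "MQK", "ATGAAA", "ATGCAAAAA")
        assert aln.seq_a == "ATGAAA" and aln.seq_b == "ATGAAA"


def _result(rank, omega=0.5, neutral=False, ka=0.1, ks=0.3):
    return SelectionResult(
        pair_id="p", ka=ka, ks=ks, omega_ml=omega, lnl_fixed=-10.0,
        lnl_free=-9.0, lr=2.0, neutral=neutral, age_rank=rank,
    )


class TestAgeTrend:
    def test_perfect_monotone_decline_gives_rho_minus_one(self):
        results = []
        for i, rank in enumerate(("7", "8", "9", "10")):
            for _ in range(5):
                results.append(_result(rank, neutral=i == 0))
        rho, p = age_trend(
            [_result(r, omega=1.0 - 0.2 * i) for i, r in enumerate(("7", "8", "9", "10"))],
            value="omega",
        )
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2.0 / 24.0)  # exact two-sided, n=4

    def test_neutral_fraction_trend(self):
        results = []
        fractions = {"7": 0.8, "8": 0.5, "9": 0.3, "10": 0.1}
        for rank, frac in fractions.items():
            for i in range(10):
                results.append(_result(rank, neutral=i < frac * 10))
        rho, p = age_trend(results, value="neutral_fraction")
        assert rho == pytest.approx(-1.0)

    def test_constant_values_rejected(self):
        results = [_result(r, omega=0.5) for r in ("7", "8", "9", "10")]
        with pytest.raises(ValueError, match="constant"):
            age_trend(results, value="omega")

    def test_fewer_than_three_ranks_rejected(self):
        results = [_result("7"), _result("8", omega=0.1)]
        with pytest.raises(ValueError):
            age_trend(results, value="omega")

    def test_ancient_rank_excluded_by_default(self):
        results = [_result(r, omega=1.0 - 0.1 * i) for i, r in enumerate(("7", "8", "9"))]
        results.append(_result("A", omega=5.0))  # would break the trend if included
        rho, _ = age_trend(results, value="omega")
        assert rho == pytest.approx(-1.0)


class TestSpearman:
    def test_matches_scipy_for_large_n(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        rho, p = spearman_trend(x, y)
        rho_s, p_s = stats.spearmanr(x, y)
        assert rho == pytest.approx(rho_s) and p == pytest.approx(p_s)

    def test_exact_small_sample_p_value(self):
        rho, p = spearman_trend([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2.0 / 6.0)  # 2 of 3! orderings reach |rho| = 1


class TestLineageCompare:
    def test_separated_samples_match_exact_enumeration(self):
        a = [_result("7", omega=v) for v in (1.0, 2.0, 3.0)]
        b = [_result("7", omega=v) for v in (10.0, 11.0, 12.0)]
        u, p, direction = lineage_compare(a, b, value="omega")
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert direction == "b"

    def test_identical_samples_not_significant(self):
        a = [_result("7", omega=v) for v in (1.0, 2.0, 3.0, 4.0)]
        _, p, _ = lineage_compare(a, list(a), value="omega")
        assert p > 0.6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            lineage_compare([], [_result("7")], value="omega")

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(8)
        a = [_result("7", omega=float(v)) for v in rng.lognormal(-1.2, 0.3, size=30)]
        b = [_result("7", omega=float(v)) for v in rng.lognormal(-0.4, 0.3, size=30)]
        _, p, direction = lineage_compare(a, b, value="omega")
        assert p < 0.05 and direction == "b"
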