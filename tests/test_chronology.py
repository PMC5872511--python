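"""Calibrated dating: masked TN93 divergence, the d/(2r) age rule against
the published family table, extinction profiling and the between-genome
rate comparison."""

import numpy as np
import pytest

from l1trace import chronology as ch
from l1trace import simgenome as sg


def _toy_pair():
    a = "ACGT" * 25
    b = list(a)
    b[8] = "G"   # A->G transition
    b[28] = "G"  # A->G transition
    b[50] = "A"  # G->A transition
    b[70] = "C"  # G->C transversion
    b[90] = "T"  # G->T transversion
    return a, "".join(b)


class TestDistances:
    def test_identical_sequences_have_zero_divergence(self):
        est = ch.masked_divergence(["ACGT" * 50] * 3, "ACGT" * 50)
        assert est.mean == 0.0
        assert est.se == 0.0

    def test_toy_pair_matches_independent_tn93_oracle(self):
        """5 differences in 100 sites: p-distance 0.05 and the TN93
        correction equal the values computed independently with
        ape::dist.dna (frozen)."""
        a, b = _toy_pair()
        assert ch.p_distance(a, b) == pytest.approx(0.05)
        assert ch.tn93_distance(a, b) == pytest.approx(0.0530221696502, abs=1e-10)

    def test_simulated_pair_matches_ape_oracle(self):
        """An 800 bp pair evolved 60 Myr apart reproduces ape::dist.dna's
        TN93 distance to 10 decimals (frozen)."""
        a = sg._random_dna(np.random.default_rng(5), 800, 0.45)
        b = sg.evolve_sequence(a, 60, 0.0013, rng=np.random.default_rng(6))
        assert ch.tn93_distance(a, b) == pytest.approx(0.07351141437, abs=1e-9)

    def test_tn93_matrix_agrees_with_pairwise_function(self):
        from l1trace._align import encode_dna

        base = sg._random_dna(np.random.default_rng(1), 500, 0.45)
        seqs = [
            sg.evolve_sequence(base, t, 0.0013, rng=np.random.default_rng(i))
            for i, t in enumerate((1, 10, 40, 80))
        ]
        mat = np.stack([encode_dna(s) for s in seqs])
        M = ch.tn93_matrix(mat)
        for i in range(4):
            for j in range(i + 1, 4):
                assert M[i, j] == pytest.approx(
                    ch.tn93_from_codes(mat[i], mat[j]), abs=1e-12
                )


class TestMasking:
    def test_differences_at_cpg_columns_are_masked_out(self):
        cons = "TT" + "CG" * 10 + "TTAA" * 20
        other = "TT" + "TA" * 10 + "TTAA" * 20  # differs only inside CpGs
        est = ch.masked_divergence([cons, other], cons, min_sites=20)
        assert est.mean == 0.0

    def test_polypurine_runs_masked_only_in_utr3(self):
        cons = "CT" * 40 + "AGGAAGAGGA" + "CT" * 10
        keep = ch.mask_keep(cons, utr3_span=(80, 110))
        assert not keep[80:90].any()  # purine run masked
        assert keep[:80].all()  # same motif outside the 3'UTR span untouched
        keep_no_span = ch.mask_keep(cons)
        assert keep_no_span.all()

    def test_masking_is_idempotent(self):
        cons = sg._random_dna(np.random.default_rng(2), 400, 0.5)
        k1 = ch.mask_keep(cons, utr3_span=(300, 400))
        masked_consensus = "".join(c if k else "T" for c, k in zip(cons, k1))
        # applying the mask to an already-masked consensus changes nothing:
        # the mask depends only on the consensus
        assert (ch.mask_keep(cons, utr3_span=(300, 400)) == k1).all()

    def test_too_few_unmasked_columns_refused(self):
        with pytest.raises(ch.InsufficientSignalError):
            ch.masked_divergence(["CG" * 30] * 2, "CG" * 30)


class TestAgeConversion:
    @pytest.mark.parametrize(
        "divergence_pct,age_myr",
        [(18.10, 69.6), (0.70, 2.7), (5.2, 20.0), (17.2, 66.2)],
    )
    def test_published_family_table_rows(self, divergence_pct, age_myr):
        """Divergence -> age under the 0.13%/Myr clock reproduces the
        published per-family ages exactly (d / 2r, rounded to 0.1 Myr)."""
        clock = ch.CalibratedClock(rate=0.13)
        est = ch.divergence_to_age(divergence_pct / 100.0, clock)
        assert round(est.age, 1) == age_myr

    def test_zero_divergence_gives_zero_age(self):
        assert ch.divergence_to_age(0.0).age == 0.0

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            ch.divergence_to_age(-0.01)

    def test_clock_from_calibration_round_trips_exactly(self):
        r, t_cal = 0.13, 56.0
        clock = ch.CalibratedClock.from_calibration(2 * (r / 100) * t_cal, t_cal)
        assert clock.rate == pytest.approx(r, abs=0.0)

    def test_age_strictly_increasing_in_divergence(self):
        clock = ch.CalibratedClock(rate=0.13)
        ages = [ch.divergence_to_age(d, clock).age for d in np.linspace(0, 0.3, 20)]
        assert all(b > a for a, b in zip(ages, ages[1:]))

    def test_ci_brackets_age(self):
        est = ch.divergence_to_age(ch.DivergenceEstimate(0.05, 0.004, 100))
        assert est.ci_low <= est.age <= est.ci_high


class TestExtinctionProfile:
    def _divergences(self, t_lo, t_hi, n=60, seed=0, length=800):
        rng = np.random.default_rng(seed)
        cons = sg._random_dna(rng, length, 0.45)
        times = rng.uniform(t_lo, t_hi, n)
        seqs = [sg.evolve_sequence(cons, t, 0.0013, rng=rng) for t in times]
        return ch.divergence_from_consensus(seqs, cons), times

    def test_family_active_to_present_peaks_at_zero(self):
        d, _ = self._divergences(0.0, 3.0)
        prof = ch.extinction_profile(d)
        assert prof.cessation_divergence < 0.005
        assert prof.peak_divergence <= 0.0075

    def test_cessation_tracks_minimum_insertion_time(self):
        """For a family extinct at t_e the cessation estimate approaches
        t_e (truth = minimum insertion time) within sampling error."""
        d, times = self._divergences(20.0, 30.0, n=80, seed=1, length=5000)
        prof = ch.extinction_profile(d)
        t_min = times.min()
        # per-locus binomial noise in Myr governs how far the minimum
        # divergence can stray from the youngest true insertion
        dmin = prof.cessation_divergence
        se_myr = 100 * np.sqrt(dmin * (1 - dmin) / 5000) / 0.13
        assert abs(prof.cessation_myr - t_min) < 3 * se_myr + 1.0
        assert prof.onset_myr > prof.cessation_myr

    def test_two_families_with_equal_extinction_agree(self):
        d1, _ = self._divergences(15.0, 25.0, n=80, seed=2, length=5000)
        d2, _ = self._divergences(15.0, 25.0, n=80, seed=3, length=5000)
        p1, p2 = ch.extinction_profile(d1), ch.extinction_profile(d2)
        assert abs(p1.cessation_myr - p2.cessation_myr) < 4.0

    def test_small_families_refused(self):
        with pytest.raises(ValueError):
            ch.extinction_profile(np.full(10, 0.05))


class TestCompareRates:
    def test_published_means_give_twelve_percent_slowdown(self):
        """The per-family mean divergences (12.49 vs 10.92; 13.07 vs 11.58)
        give an overall slowdown that rounds to 12%."""
        slow = ch.panel_slowdown_from_means([(12.49, 10.92), (13.07, 11.58)])
        assert round(100 * slow) == 12

    def test_identical_panels_give_zero_slowdown_p_one(self):
        x = np.linspace(0.05, 0.15, 50)
        cmp = ch.compare_rates(x, x.copy(), paired=True)
        assert cmp.slowdown == 0.0
        assert cmp.p_value == 1.0

    def test_slower_lineage_detected_in_simulation(self):
        rng = np.random.default_rng(4)
        cons, pairs = sg.simulate_orthologous_loci(
            200, 0.0013, 0.88 * 0.0013, t_start=80.0, t_end=60.0, seed=4
        )
        da = ch.divergence_from_consensus([a for a, _ in pairs], cons)
        db = ch.divergence_from_consensus([b for _, b in pairs], cons)
        cmp = ch.compare_rates(da, db, paired=True)
        assert 0.05 < cmp.slowdown < 0.20
        assert cmp.p_value < 0.001
        assert cmp.p_rank < 0.001

    def test_small_panels_rejected(self):
        with pytest.raises(ValueError):
            ch.compare_rates(np.ones(5), np.ones(5))

    def test_zero_reference_mean_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            ch.compare_rates(np.zeros(20), np.ones(20))
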