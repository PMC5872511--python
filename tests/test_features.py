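"""Copy-number scanning, tandem-repeat detection, LPR motif matrix and the
counting-based dN/dS."""

import numpy as np
import pandas as pd
import pytest

from l1trace import features as ft
from l1trace import simgenome as sg


def _library(bundle):
    return {
        spec.name: ft.ConsensusEntry(spec.source_sequence, spec.feature_spans)
        for spec in bundle.scenario.families
    }


class TestCopyNumbers:
    def test_element_free_genome_gives_all_zeros(self):
        rng = np.random.default_rng(1)
        lib = {"famA": ft.ConsensusEntry(sg._random_dna(rng, 6000, 0.45), {"5UTR": (0, 2000)})}
        for seed in range(3):
            genome = {"c": sg._random_dna(np.random.default_rng(50 + seed), 100_000, 0.42)}
            recs = ft.family_copy_numbers(genome, lib)
            assert [r.n_total for r in recs] == [0]

    def test_simulated_counts_within_five_percent_of_truth(self, demo):
        recs = ft.family_copy_numbers(demo["genome"], _library(demo["bundle"]))
        truth = demo["truth"]
        for r in recs:
            true_n = int((truth.family == r.family).sum())
            assert abs(r.n_total - true_n) <= 0.05 * true_n

    def test_equidistant_fragment_counted_once_deterministically(self):
        rng = np.random.default_rng(2)
        shared = sg._random_dna(rng, 4000, 0.45)
        lib = {
            "famB": ft.ConsensusEntry(shared, {"5UTR": (0, 1000)}),
            "famA": ft.ConsensusEntry(shared, {"5UTR": (0, 1000)}),
        }
        genome = {
            "c": sg._random_dna(rng, 20_000, 0.42) + shared + sg._random_dna(rng, 20_000, 0.42)
        }
        recs = {r.family: r.n_total for r in ft.family_copy_numbers(genome, lib)}
        assert recs == {"famA": 1, "famB": 0}  # tie resolved alphabetically

    def test_full_length_estimates_and_invariant(self, demo, harvested):
        lib = _library(demo["bundle"])
        recs = ft.family_copy_numbers(demo["genome"], lib)
        recs = ft.full_length_estimates(harvested["elements"], recs, lib)
        truth = demo["truth"]
        for r in recs:
            assert r.n_fl_complete <= r.n_fl_utr <= r.n_total
            true_fl = int(truth[truth.family == r.family].full_length.sum())
            assert abs(r.n_fl_utr - true_fl) <= max(1, round(0.2 * true_fl))

    def test_all_full_length_family_has_equal_estimates(self):
        rng = np.random.default_rng(3)
        bundle = sg.demo_scenario(seed=21, n_families=1, n_inserts=25, p_full_length=1.0)
        genome, truth = sg.simulate_history(bundle.scenario)
        lib = _library(bundle)
        recs = ft.family_copy_numbers(genome, lib)
        recs = ft.full_length_estimates([], recs, lib)
        assert recs[0].n_fl_utr == recs[0].n_total == 25


class TestTandemRepeats:
    def test_three_exact_copies_of_42mer(self):
        unit = sg._random_dna(np.random.default_rng(4), 42, 0.6)
        flank = sg._random_dna(np.random.default_rng(5), 150, 0.5)
        arrays = ft.detect_tandem_repeats(flank + unit * 3 + flank[::-1])
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.unit_length == 42
        assert arr.copies == pytest.approx(3.0, abs=0.3)
        assert arr.start >= 140 and arr.end <= 150 + 3 * 42 + 10

    def test_random_promoter_has_no_arrays(self):
        for seed in range(4):
            prom = sg._random_dna(np.random.default_rng(60 + seed), 800, 0.55)
            assert ft.detect_tandem_repeats(prom) == []

    def test_rotation_by_one_unit_preserves_detection(self):
        unit = sg._random_dna(np.random.default_rng(6), 30, 0.6)
        seq = unit * 4
        base = ft.detect_tandem_repeats(seq)
        rotated = ft.detect_tandem_repeats(seq[30:] + seq[:30])
        assert base and rotated
        assert base[0].unit_length == rotated[0].unit_length == 30
        assert base[0].copies == rotated[0].copies

    def test_short_promoter_rejected(self):
        with pytest.raises(ValueError):
            ft.detect_tandem_repeats("ACGTACGT", min_unit=10)


class TestLprMotifMatrix:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(7)
        flank1 = sg._random_dna(rng, 60, 0.45)
        m21 = sg._random_dna(rng, 21, 0.45)
        mid = sg._random_dna(rng, 30, 0.45)
        m33 = sg._random_dna(rng, 33, 0.45)
        tail = sg._random_dna(rng, 60, 0.45)
        anc = flank1 + m21 + mid + m33 + tail
        defs = {"21bp": (m21, 60), "33bp": (m33, 60 + 21 + 30)}
        lost33 = flank1 + m21 + mid + "-" * 33 + tail
        lost21 = flank1 + "-" * 21 + mid + m33 + tail
        allgap = "-" * len(anc)
        cons = {"anc": anc, "no33": lost33, "no21": lost21, "gone": allgap}
        return cons, defs

    def test_ancestral_row_all_present(self, setup):
        cons, defs = setup
        mat = ft.lpr_motif_matrix(cons, defs, ancestral="anc")
        assert (mat.loc["anc"] == "present").all()

    def test_deleted_motifs_scored_absent(self, setup):
        cons, defs = setup
        mat = ft.lpr_motif_matrix(cons, defs, ancestral="anc")
        assert mat.loc["no33", "33bp"] == "absent"
        assert mat.loc["no33", "21bp"] == "present"
        assert mat.loc["no21", "21bp"] == "absent"
        assert mat.loc["no21", "33bp"] == "present"

    def test_all_gap_row_flagged_unknown(self, setup):
        cons, defs = setup
        mat = ft.lpr_motif_matrix(cons, defs, ancestral="anc")
        assert (mat.loc["gone"] == "unknown").all()

    def test_unaligned_input_rejected(self, setup):
        cons, defs = setup
        cons["bad"] = "ACGT"
        with pytest.raises(ValueError):
            ft.lpr_motif_matrix(cons, defs, ancestral="anc")


class TestGlobalDnds:
    def test_identical_sequences_give_zero_and_undefined_omega(self):
        seqs = ["ATGAAAGGG" * 10] * 3
        om = ft.global_dnds(seqs)
        assert om.dn == 0.0
        assert om.ds == 0.0
        assert om.omega is None

    def test_two_codon_toy_matches_hand_computed_counting(self):
        """TTT AAA GGG vs TTC AGA GGG: one synonymous (TTT->TTC) and one
        nonsynonymous (AAA->AGA) difference. Site counts by hand with
        stop-codon changes excluded: S = 1/3 + (3/8 + 3/4)/2 + 1 = 1.8958,
        N = 7.1042, so pS = 0.5275 and pN = 0.1408; Jukes-Cantor correction
        gives ds = 0.9113 and dn = 0.1559."""
        got = ft._pair_dnds("TTTAAAGGG", "TTCAGAGGG")
        assert got is not None
        dn, ds = got
        assert dn == pytest.approx(0.1559, abs=2e-4)
        assert ds == pytest.approx(0.9113, abs=2e-4)

    def test_matches_independent_counting_implementation(self):
        """Cross-check against Bio.codonalign's NG86 on an evolved pair.

        The reference treats mutations to stop codons as nonsynonymous
        whereas this implementation excludes them (the counting method's
        original convention), so the comparison runs on codons that have no
        stop codon among their single-base neighbours and no stop on any
        substitution pathway — there the two conventions coincide exactly.
        """
        import itertools
        import warnings

        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        def touches_stop(c1, c2):
            diff = [i for i in range(3) if c1[i] != c2[i]]
            for order in itertools.permutations(diff):
                cur = c1
                for i in order:
                    cur = cur[:i] + c2[i] + cur[i + 1 :]
                    if cur in ft._STOPS:
                        return True
            return False

        def stop_free(codon):
            for i in range(3):
                for base in "ACGT":
                    if base != codon[i] and codon[:i] + base + codon[i + 1 :] in ft._STOPS:
                        return False
            return True

        rng = np.random.default_rng(8)
        a = sg._random_orf(rng, 200)
        b = sg.evolve_sequence(a, 40, 0.0013, rng=rng)
        a2, b2 = [], []
        for i in range(0, len(a), 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if (
                cb in ft._STOPS
                or not stop_free(ca)
                or not stop_free(cb)
                or touches_stop(ca, cb)
            ):
                a2.append("GGG")
                b2.append("GGG")
            else:
                a2.append(ca)
                b2.append(cb)
        a2, b2 = "".join(a2), "".join(b2)
        got = ft._pair_dnds(a2, b2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn_bio, ds_bio = cal_dn_ds(CodonSeq(a2), CodonSeq(b2), method="NG86")
        assert got[0] == pytest.approx(dn_bio, abs=1e-6)
        assert got[1] == pytest.approx(ds_bio, abs=1e-6)

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(9)
        a = sg._random_orf(rng, 100)
        b = sg.evolve_sequence(a, 30, 0.0013, rng=rng)
        om_ab = ft.global_dnds([a, b], on_stop="mask")
        om_ba = ft.global_dnds([b, a], on_stop="mask")
        assert om_ab.dn == pytest.approx(om_ba.dn, abs=1e-12)
        assert om_ab.ds == pytest.approx(om_ba.ds, abs=1e-12)

    def test_premature_stop_sequence_excluded_with_warning(self, caplog):
        import logging

        good_a = "ATGAAAGGGTTC" * 5
        good_b = "ATGAAGGGGTTC" * 5
        bad = "ATGTAAGGGTTC" * 5  # TAA in frame
        with caplog.at_level(logging.WARNING):
            om = ft.global_dnds({"a": good_a, "b": good_b, "bad": bad})
        assert "premature stop" in caplog.text
        assert om is not None

    def test_purifying_selection_yields_omega_below_one(self):
        """Simulated purifying selection (nonsynonymous substitutions
        accepted at 1/4 the synonymous rate) gives omega < 1."""
        below = 0
        for i in range(10):
            a, b = _selected_pair(seed=70 + i, accept_nonsyn=0.25)
            om = ft.global_dnds([a, b], on_stop="mask")
            if om.omega is not None and om.omega < 1:
                below += 1
        assert below >= 9


def _selected_pair(seed: int, accept_nonsyn: float, n_codons: int = 300,
                   t: float = 60.0, rate: float = 0.0013):
    """A coding pair where proposed nonsynonymous changes are accepted with
    probability `accept_nonsyn` (selection filter on a neutral proposal)."""
    rng = np.random.default_rng(seed)
    a = sg._random_orf(rng, n_codons)
    p = 0.75 * (1 - np.exp(-4 * rate * t / 3))
    b = list(a)
    aa = ft._AA
    for i in range(len(a)):
        if rng.random() >= p:
            continue
        new = "ACGT"[int(rng.integers(0, 4))]
        if new == a[i]:
            continue
        ci = i // 3 * 3
        old_codon = "".join(b[ci : ci + 3])
        cand = list(old_codon)
        cand[i - ci] = new
        cand = "".join(cand)
        if cand in ft._STOPS or old_codon in ft._STOPS:
            continue
        syn = aa.get(cand) == aa.get(old_codon)
        if syn or rng.random() < accept_nonsyn:
            b[i] = new
    return a, "".join(b)
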