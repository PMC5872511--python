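"""Promoter classification, 3'-terminus family clustering, consensus
building and the naming convention."""

import numpy as np
import pytest

from l1trace import families as fm
from l1trace import simgenome as sg


def _elements(seed=3, n_families=3, members=15, promoter_types=None, **kw):
    bundle = sg.demo_scenario(
        seed=seed,
        n_families=n_families,
        n_inserts=members,
        p_full_length=1.0,
        promoter_types=promoter_types,
        **kw,
    )
    return sg.synthesize_fl_elements(bundle.scenario)


class TestClassifyPromoters:
    def test_single_shared_promoter_gives_one_class(self):
        els, _ = _elements(n_families=2, promoter_types=[1, 1])
        classes, unclassified = fm.classify_promoters(els)
        assert len(classes) == 1
        assert unclassified == []
        assert len(classes[0].members) == len(els)

    def test_two_nonhomologous_promoters_split_perfectly(self):
        els, labels = _elements(n_families=3, promoter_types=[1, 2, 2])
        classes, _ = fm.classify_promoters(els)
        assert len(classes) == 2
        for c in classes:
            types = {labels[m][:4] for m in c.members}
            # members of one class come from families sharing a promoter
            fams = {labels[m] for m in c.members}
            assert fams in ({"fam1"}, {"fam2", "fam3"})

    def test_promoter_at_five_percent_divergence_stays_in_class(self):
        els, _ = _elements(n_families=1, members=12)
        # mutate one element's promoter to 5% divergence from its class
        rng = np.random.default_rng(0)
        target = els[0]
        s, e = target.feature_spans["5UTR"]
        utr = target.sequence[s:e]
        mutated = sg.evolve_sequence(utr, t=0.05 / 0.0013, rate=0.0013, rng=rng)
        target.sequence = target.sequence[:s] + mutated + target.sequence[e:]
        classes, _ = fm.classify_promoters(els)
        assert len(classes) == 1
        assert target.element_id in classes[0].members

    def test_empty_utr_routed_to_unclassified(self):
        els, _ = _elements(n_families=1, members=12)
        els[0].feature_spans["5UTR"] = (0, 0)
        classes, unclassified = fm.classify_promoters(els)
        assert unclassified == [els[0].element_id]
        assert len(classes[0].members) == len(els) - 1


class TestClusterFamilies:
    def test_three_families_recovered_with_exact_membership(self):
        els, labels = _elements(
            n_families=3,
            members=14,
            promoter_types=[1, 1, 1],
            age_step_myr=2,
            window_myr=4,
            between_divergence=0.10,
        )
        classes, _ = fm.classify_promoters(els)
        records = fm.cluster_families(classes[0], els, bootstrap_reps=150, seed=1)
        assert len(records) == 3
        for rec in records:
            assert len({labels[m] for m in rec.members}) == 1

    def test_single_homogeneous_family_stays_one_family(self):
        els, _ = _elements(n_families=1, members=15)
        classes, _ = fm.classify_promoters(els)
        records = fm.cluster_families(classes[0], els, bootstrap_reps=100, seed=2)
        assert len(records) == 1
        assert records[0].n_members == 15

    def test_cluster_of_nine_members_is_dropped(self):
        els, labels = _elements(
            n_families=2,
            members=15,
            promoter_types=[1, 1],
            age_step_myr=2,
            window_myr=4,
            between_divergence=0.10,
        )
        keep = [e for e in els if labels[e.element_id] == "fam1"] + [
            e for e in els if labels[e.element_id] == "fam2"
        ][:9]
        classes, _ = fm.classify_promoters(keep)
        records = fm.cluster_families(classes[0], keep, bootstrap_reps=150, seed=3)
        assert len(records) == 1
        assert {labels[m] for m in records[0].members} == {"fam1"}

    def test_consensus_recovers_source_at_99_percent(self):
        els, _ = _elements(n_families=1, members=20, seed=8)
        bundle_src = sg.demo_scenario(seed=8, n_families=1, n_inserts=20, p_full_length=1.0)
        source = bundle_src.scenario.families[0].source_sequence
        classes, _ = fm.classify_promoters(els)
        records = fm.cluster_families(classes[0], els, bootstrap_reps=100, seed=4)
        from l1trace._align import edit_identity

        assert edit_identity(records[0].consensus, source) >= 0.99


class TestBuildConsensus:
    def test_identical_sequences_return_themselves(self):
        assert fm.build_consensus(["ACGTAC"] * 4) == "ACGTAC"

    def test_toy_alignment_matches_manual_column_count(self):
        aligned = [
            "ACGTACGTAC",
            "ACGTACGTAC",
            "ATGTACGAAC",
            "ACGAACGTAC",
            "ACGT-CGTAC",
        ]
        # columns: majority of each column counted by hand
        assert fm.build_consensus(aligned) == "ACGTACGTAC"

    def test_majority_gap_columns_removed(self):
        aligned = ["A-GT", "A-GT", "ACGT"]
        assert fm.build_consensus(aligned) == "AGT"

    def test_fifty_fifty_tie_breaks_alphabetically(self):
        aligned = ["AAAA", "AACA", "CACA", "CCAA"]
        # column counts: {A3 C1}, {A3 C1}, {A2 C2}->A, {A4}
        out1 = fm.build_consensus(aligned)
        out2 = fm.build_consensus(aligned)
        assert out1 == out2 == "AAAA"

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            fm.build_consensus(["ACGT"])


class TestNaming:
    def _fam(self, name, ptype, n):
        return fm.FamilyRecord(
            name=name, promoter_type=ptype, members=[f"{name}_{i}" for i in range(n)],
            consensus="ACGT", n_members=n,
        )

    def test_naming_examples(self):
        fams = [self._fam("a", 1, 20), self._fam("b", 4, 30),
                self._fam("c", 4, 25), self._fam("d", 3, 12)]
        ages = {"a": 2.7, "b": 43.5, "c": 66.2, "d": 22.3}
        labels = {"a": "Ec", "b": "shared", "c": "shared", "d": "Cs"}
        named = {f.members[0].split("_")[0]: f.name
                 for f in fm.name_families(fams, ages, labels)}
        assert named["a"] == "L1_Ec1_I"
        assert named["b"] == "L1_Perissodactyla4_I"
        assert named["c"] == "L1_Perissodactyla4_II"
        assert named["d"] == "L1_Cs3_I"

    def test_names_invariant_under_input_permutation(self):
        fams = [self._fam(nm, 2, 10 + i) for i, nm in enumerate("abcd")]
        ages = {"a": 5.0, "b": 1.0, "c": 9.0, "d": 3.0}
        labels = {nm: "Ec" for nm in "abcd"}
        ref = {f.members[0]: f.name for f in fm.name_families(fams, ages, labels)}
        for perm in ([3, 1, 0, 2], [2, 3, 1, 0]):
            shuffled = [fams[i] for i in perm]
            got = {f.members[0]: f.name for f in fm.name_families(shuffled, ages, labels)}
            assert got == ref

    def test_age_tie_broken_by_copy_number(self):
        fams = [self._fam("a", 1, 10), self._fam("b", 1, 40)]
        ages = {"a": 5.0, "b": 5.0}
        labels = {"a": "Ec", "b": "Ec"}
        named = {f.members[0].split("_")[0]: f.name
                 for f in fm.name_families(fams, ages, labels)}
        assert named["b"] == "L1_Ec1_I"  # more copies ranks younger on a tie
        assert named["a"] == "L1_Ec1_II"

    @pytest.mark.parametrize(
        "n,expected", [(1, "I"), (4, "IV"), (9, "IX"), (14, "XIV"), (40, "XL")]
    )
    def test_roman_numerals(self, n, expected):
        assert fm.roman(n) == expected


class TestNeighborJoining:
    def test_topology_matches_skbio_on_random_distances(self):
        import skbio
        from l1trace._trees import neighbor_joining, splits

        rng = np.random.default_rng(11)
        names = [f"t{i}" for i in range(8)]
        # additive-ish random distances: perturbed patristic distances
        base = rng.uniform(0.05, 0.4, size=(8, 8))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        mine = neighbor_joining(D, names)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
        ref_splits = set()
        all_names = frozenset(names)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(names) - 1:
                anchor = min(all_names)
                ref_splits.add(
                    frozenset(all_names - side) if anchor in side else side
                )
        assert splits(mine) == ref_splits
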