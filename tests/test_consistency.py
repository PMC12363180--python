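"""Cluster purity, Pfam/EC consistency, predictor benchmarking, gates."""

import random
import statistics

import pytest

from scsh import consistency as cons
from scsh.types import AlignmentRecord, Clustering, FunctionalLabels


def lab(pid, pfams=(), ecs=()):
    return FunctionalLabels(
        pid,
        frozenset(pfams),
        tuple(FunctionalLabels.parse_ec(e) for e in ecs),
    )


def rm_aln(rep, member, lddt, tm):
    return AlignmentRecord(rep, member, 0.5, 0.95, 0.95, 1e-10,
                           tm_score=tm, lddt=lddt)


class TestStructuralPurity:
    def test_per_cluster_mean(self):
        c = Clustering({"r": {"r", "a", "b"}})
        rows = [rm_aln("r", "a", 0.8, 0.9), rm_aln("r", "b", 1.0, 0.7)]
        purities, _ml, _mt = cons.structural_purity(c, rows)
        (p,) = purities
        assert p.mean_lddt == pytest.approx(0.9)
        assert p.mean_tm == pytest.approx(0.8)

    def test_singleton_omitted(self):
        c = Clustering({"r": {"r"}})
        purities, ml, mt = cons.structural_purity(c, [rm_aln("r", "r", 1.0, 1.0)])
        assert purities == [] and ml is None and mt is None

    def test_medians_match_direct_computation(self):
        clusters = {f"r{i}": {f"r{i}", f"m{i}"} for i in range(5)}
        c = Clustering(clusters)
        lddts = [0.5, 0.7, 0.9, 0.95, 1.0]
        rows = [rm_aln(f"r{i}", f"m{i}", lddts[i], lddts[i]) for i in range(5)]
        _p, ml, mt = cons.structural_purity(c, rows)
        assert ml == statistics.median(lddts)
        assert mt == statistics.median(lddts)


class TestPfamConsistency:
    def test_identical_singleton_sets_score_one(self):
        s = cons.pfam_consistency("r", [lab("a", {"PF00001"}), lab("b", {"PF00001"})])
        assert s.score == 1.0

    def test_asymmetric_pair_scores_averaged(self):
        # A->B: |{PF1}|/|{PF1,PF2}| = 1/2 ; B->A: 1/1 ; mean 0.75
        s = cons.pfam_consistency("r", [lab("a", {"PF1", "PF2"}), lab("b", {"PF1"})])
        assert s.score == pytest.approx(0.75)

    def test_disjoint_sets_score_zero(self):
        s = cons.pfam_consistency("r", [lab("a", {"PF1"}), lab("b", {"PF2"})])
        assert s.score == 0.0

    def test_fewer_than_two_annotated_not_scored(self):
        assert cons.pfam_consistency("r", [lab("a", {"PF1"}), lab("b")]) is None

    def test_score_one_iff_identical_sets(self):
        rng = random.Random(3)
        for _ in range(200):
            members = [
                lab(f"p{i}", {f"PF{rng.randrange(4)}" for _ in range(rng.randrange(1, 4))})
                for i in range(rng.randrange(2, 6))
            ]
            s = cons.pfam_consistency("r", members)
            identical = len({m.pfam_accessions for m in members}) == 1
            assert (s.score == 1.0) == identical


class TestEcConsistency:
    def test_truncation_by_level(self):
        members = [lab("a", ecs=["1.2.3.4"]), lab("b", ecs=["1.2.3.5"])]
        assert cons.ec_consistency("r", members, 3).score == 1.0
        assert cons.ec_consistency("r", members, 4).score == 0.0

    def test_multi_ec_member_excluded(self):
        members = [
            lab("a", ecs=["1.1.1.1", "2.7.7.7"]),
            lab("b", ecs=["1.1.1.1"]),
        ]
        assert cons.ec_consistency("r", members, 1) is None

    def test_dash_at_level_disregarded(self):
        members = [lab("a", ecs=["1.2.-.-"]), lab("b", ecs=["1.2.3.4"])]
        # at level 3 the first member is disregarded -> <2 eligible -> skipped
        assert cons.ec_consistency("r", members, 3) is None
        assert cons.ec_consistency("r", members, 2).score == 1.0

    def test_level_monotone_nonincreasing(self):
        rng = random.Random(9)
        for _ in range(200):
            members = [
                lab(f"p{i}", ecs=[f"{rng.randrange(1, 3)}.{rng.randrange(1, 3)}."
                                  f"{rng.randrange(1, 3)}.{rng.randrange(1, 3)}"])
                for i in range(rng.randrange(2, 6))
            ]
            prev = 1.0
            for level in (1, 2, 3, 4):
                s = cons.ec_consistency("r", members, level).score
                assert s <= prev + 1e-12
                prev = s


class TestBinning:
    def test_fraction_fully_consistent(self):
        rows = cons.consistency_vs_metric_binning(
            {"r1": 1.0, "r2": 0.5}, {"r1": 0.3, "r2": 0.4}, [0.0, 0.65, 1.0]
        )
        assert rows[0]["fraction_fully_consistent"] == 0.5
        assert rows[0]["n_clusters"] == 2

    def test_empty_bin_reports_absent(self):
        rows = cons.consistency_vs_metric_binning(
            {"r1": 1.0}, {"r1": 0.3}, [0.0, 0.65, 1.0]
        )
        assert rows[1]["fraction_fully_consistent"] is None

    def test_boundary_value_lands_in_lower_bin(self):
        rows = cons.consistency_vs_metric_binning(
            {"r1": 1.0}, {"r1": 0.65}, [0.0, 0.65, 1.0]
        )
        assert rows[0]["n_clusters"] == 1 and rows[1]["n_clusters"] == 0

    def test_metric_outside_bins_is_error(self):
        with pytest.raises(ValueError, match="outside all bins"):
            cons.consistency_vs_metric_binning({"r1": 1.0}, {"r1": 2.0}, [0.0, 1.0])


class TestDeepfriAgreement:
    def test_agreement_by_level(self):
        ec = FunctionalLabels.parse_ec
        predicted = {"p": (ec("3.6.1.1"), 0.9)}
        reference = {"p": ec("3.6.1.5")}
        out = cons.deepfri_ec_agreement(predicted, reference)
        assert out == {1: 1.0, 2: 1.0, 3: 1.0}

    def test_total_disagreement(self):
        ec = FunctionalLabels.parse_ec
        out = cons.deepfri_ec_agreement({"p": (ec("2.7.7.7"), 0.9)},
                                        {"p": ec("3.6.1.5")})
        assert out == {1: 0.0, 2: 0.0, 3: 0.0}

    def test_fractional_agreement(self):
        ec = FunctionalLabels.parse_ec
        predicted = {f"p{i}": (ec("1.1.1.1"), 0.9) for i in range(3)}
        predicted["p3"] = (ec("2.1.1.1"), 0.9)
        reference = {f"p{i}": ec("1.2.2.2") for i in range(4)}
        out = cons.deepfri_ec_agreement(predicted, reference)
        assert out[1] == pytest.approx(0.75)

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="shared"):
            cons.deepfri_ec_agreement({"a": (("1", "1", "1", "1"), 0.5)},
                                      {"b": ("1", "1", "1", "1")})


class TestGates:
    def test_plddt_gate_strict(self):
        kept, n, total = cons.plddt_gate({"a": 90.0, "b": 90.1}, 90.0)
        assert kept == {"b"} and (n, total) == (1, 2)

    def test_confidence_gate_strict(self):
        preds = {"a": (("1", "1", "1", "1"), 0.81), "b": (("1", "1", "1", "1"), 0.8)}
        kept, n, total = cons.confidence_gate(preds, 0.8)
        assert set(kept) == {"a"} and (n, total) == (1, 2)

    def test_empty_inputs(self):
        assert cons.confidence_gate({}, 0.8) == ({}, 0, 0)
        assert cons.plddt_gate({}, 90.0) == (set(), 0, 0)


class TestSemanticConsistency:
    GROUPS = [["Phage tail protein", "Minor tail protein"]]

    def test_synonyms_count_as_consistent(self):
        c = Clustering({"r": {"r"}})
        frac, n_ok, n_all = cons.semantic_consistency(
            c, {"r": "Phage tail protein"}, {"r": "Minor tail protein"}, self.GROUPS
        )
        assert (frac, n_ok, n_all) == (1.0, 1, 1)

    def test_ambiguous_representative_removes_cluster(self):
        c = Clustering({"r": {"r", "m"}, "r2": {"r2"}})
        transferred = {"r": "hypothetical protein", "m": "hypothetical protein",
                       "r2": "Phage tail protein"}
        seqs = {"r2": "Minor tail protein"}
        frac, _ok, n_all = cons.semantic_consistency(c, transferred, seqs, self.GROUPS)
        assert n_all == 1 and frac == 1.0

    def test_identical_strings_consistent_without_config_entry(self):
        c = Clustering({"r": {"r"}})
        frac, *_rest = cons.semantic_consistency(
            c, {"r": "Endolysin"}, {"r": "endolysin"}, []
        )
        assert frac == 1.0

    def test_missing_config_is_error(self):
        c = Clustering({"r": {"r"}})
        with pytest.raises(ValueError, match="synonym"):
            cons.semantic_consistency(c, {"r": "x"}, {"r": "x"}, None)

    def test_unrelated_annotations_inconsistent(self):
        c = Clustering({"r": {"r"}})
        frac, *_rest = cons.semantic_consistency(
            c, {"r": "Endolysin"}, {"r": "portal protein"}, self.GROUPS
        )
        assert frac == 0.0
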