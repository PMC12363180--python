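"""Hit filtering, annotation transfer, and the two annotation rates."""

import pytest

from scsh import annotate as ann
from scsh.types import (
    AlignmentRecord,
    BestHit,
    Clustering,
    PhageMetadata,
    ProductAnnotation,
    StructureModel,
)


def hit(q="q", t="t", tm=0.7, qcov=0.9, tcov=0.9, evalue=1e-10, name=None,
        db="other"):
    return AlignmentRecord(q, t, 0.3, qcov, tcov, evalue, tm_score=tm,
                           target_name=name, target_db=db)


class TestFilterHits:
    def test_passing_hit_kept(self):
        assert ann.filter_structure_hits([hit(tm=0.62, qcov=0.85, tcov=0.83)])

    def test_below_tm_dropped(self):
        assert not ann.filter_structure_hits([hit(tm=0.45, qcov=0.95, tcov=0.95)])

    def test_coverage_mode_semantics(self):
        rec = hit(tm=0.62, qcov=0.75, tcov=0.95)
        assert not ann.filter_structure_hits([rec])
        assert ann.filter_structure_hits([rec], coverage_mode="target")

    def test_thresholds_inclusive(self):
        assert ann.filter_structure_hits([hit(tm=0.5, qcov=0.8, tcov=0.8)])

    def test_record_without_tm_skipped(self):
        rec = AlignmentRecord("q", "t", 0.3, 0.9, 0.9, 1e-5)
        assert ann.filter_structure_hits([rec]) == []


class TestBestHit:
    def test_highest_tm_wins(self):
        best = ann.select_best_hit([hit(t="a", tm=0.7), hit(t="b", tm=0.9)])
        assert best.target_id == "b"

    def test_evalue_breaks_tm_tie(self):
        best = ann.select_best_hit(
            [hit(t="a", tm=0.8, evalue=1e-3), hit(t="b", tm=0.8, evalue=1e-8)]
        )
        assert best.target_id == "b"

    def test_database_precedence_breaks_remaining_tie(self):
        best = ann.select_best_hit([
            hit(t="afdb", tm=0.8, evalue=1e-5, db="AFDB"),
            hit(t="pdb", tm=0.8, evalue=1e-5, db="PDB"),
        ])
        assert best.target_db == "PDB"

    def test_empty_hit_list_gives_none(self):
        assert ann.select_best_hit([]) is None


class TestVoidAndUnannotated:
    @pytest.mark.parametrize("name,expected", [
        ("Putative DNA-binding protein", True),
        ("Major capsid protein", False),
        ("", True),
        (None, True),
        ("Domain of Unknown Function DUF99", True),
        ("Uncharacterized conserved protein", True),
    ])
    def test_void_classification(self, name, expected):
        assert ann.classify_void(name) is expected

    @pytest.mark.parametrize("product,expected", [
        ("hypothetical protein", True),
        ("terminase large subunit", False),
        ("Hypothetical Protein gp42", True),
        ("", True),
    ])
    def test_sequence_unannotated(self, product, expected):
        assert ann.is_sequence_unannotated(product) is expected

    def test_void_terms_configurable(self):
        assert ann.classify_void("probable kinase", void_terms=("probable",))
        assert not ann.classify_void("putative kinase", void_terms=("probable",))


class TestTransfer:
    def test_members_inherit_rep_hit_name(self):
        c = Clustering({"r": {"r", "a", "b"}})
        hits = {"r": BestHit("r", "t", "terminase", "PDB", 0.9, 1e-9)}
        out = ann.transfer_annotations(c, hits)
        assert len(out) == 3
        assert {o.product for o in out} == {"terminase"}
        assert all(o.source == "structure_transfer" for o in out)

    def test_cluster_without_hit_contributes_nothing(self):
        c = Clustering({"r": {"r", "a"}})
        assert ann.transfer_annotations(c, {}) == []

    def test_transfer_conserves_member_counts(self):
        c = Clustering({"r1": {"r1", "a"}, "r2": {"r2", "b", "c"}})
        hits = {
            "r1": BestHit("r1", "t1", "x", "PDB", 0.9, 1e-9),
            "r2": BestHit("r2", "t2", "y", "AFDB", 0.8, 1e-5),
        }
        assert len(ann.transfer_annotations(c, hits)) == 2 + 3

    def test_non_representative_key_is_error(self):
        c = Clustering({"r": {"r", "a"}})
        with pytest.raises(ValueError, match="a"):
            ann.transfer_annotations(c, {"a": BestHit("a", "t", "x", "PDB", 0.9, 1e-9)})


class TestRates:
    def test_sequence_rate_formula(self):
        prods = [ProductAnnotation(f"p{i}", "hypothetical protein") for i in range(4)]
        prods += [ProductAnnotation(f"q{i}", "portal protein") for i in range(6)]
        tally, rate = ann.sequence_annotation_rate(prods)
        assert rate == pytest.approx(0.6)
        assert tally.n_unannotated == 4

    @pytest.mark.parametrize("product,expected", [
        ("hypothetical protein", 0.0), ("endolysin", 1.0),
    ])
    def test_sequence_rate_boundaries(self, product, expected):
        _t, rate = ann.sequence_annotation_rate(
            [ProductAnnotation(f"p{i}", product) for i in range(5)]
        )
        assert rate == expected

    def test_empty_products_error(self):
        with pytest.raises(ValueError, match="undefined"):
            ann.sequence_annotation_rate([])

    def test_structure_rate_formula(self):
        ids = [f"p{i}" for i in range(10)]
        transferred = [
            ProductAnnotation(f"p{i}", "putative x" if i < 3 else "endolysin",
                              source="structure_transfer")
            for i in range(8)
        ]
        tally, rate = ann.structure_annotation_rate(ids, transferred)
        assert (tally.n_match, tally.n_void) == (8, 3)
        assert rate == pytest.approx(0.5)

    def test_structure_rate_boundaries(self):
        ids = ["a", "b"]
        assert ann.structure_annotation_rate(ids, [])[1] == 0.0
        full = [ProductAnnotation(i, "endolysin", source="structure_transfer")
                for i in ids]
        assert ann.structure_annotation_rate(ids, full)[1] == 1.0

    def test_transferred_id_outside_set_is_error(self):
        with pytest.raises(ValueError, match="zz"):
            ann.structure_annotation_rate(
                ["a"], [ProductAnnotation("zz", "x", source="structure_transfer")]
            )

    def test_structure_rate_monotone_in_void_terms(self):
        ids = [f"p{i}" for i in range(6)]
        transferred = [
            ProductAnnotation(p, n, source="structure_transfer")
            for p, n in zip(ids, ["putative x", "probable y", "endolysin",
                                  "holin", "portal", "integrase"])
        ]
        terms = []
        prev = 1.1
        for extra in ("putative", "probable", "endolysin"):
            terms.append(extra)
            _t, rate = ann.structure_annotation_rate(ids, transferred, tuple(terms))
            assert rate <= prev
            prev = rate


class TestPerGroupRates:
    META = [PhageMetadata("ph1", "A", "temperate"), PhageMetadata("ph2", "A", "lytic"),
            PhageMetadata("ph3", "B", "lytic")]

    def _fixture(self):
        # ph1: 5 proteins, 3 annotated (0.6); ph2: 5 proteins, 2 annotated (0.4)
        products, mapping = [], {}
        for i in range(5):
            products.append(ProductAnnotation(
                f"a{i}", "endolysin" if i < 3 else "hypothetical protein"))
            mapping[f"a{i}"] = "ph1"
        for i in range(5):
            products.append(ProductAnnotation(
                f"b{i}", "holin" if i < 2 else "hypothetical protein"))
            mapping[f"b{i}"] = "ph2"
        return products, mapping

    def test_group_average_is_mean_of_phage_rates(self):
        products, mapping = self._fixture()
        out = ann.per_group_rates(products, [], mapping, self.META)
        assert out["per_phage"]["ph1"][0] == pytest.approx(0.6)
        assert out["per_phage"]["ph2"][0] == pytest.approx(0.4)
        assert out["per_group_averaged"]["A"][0] == pytest.approx(0.5)

    def test_single_phage_group_average_is_identity(self):
        products = [ProductAnnotation("c0", "endolysin")]
        out = ann.per_group_rates(products, [], {"c0": "ph3"}, self.META)
        assert out["per_group_averaged"]["B"][0] == out["per_phage"]["ph3"][0] == 1.0

    def test_unmapped_protein_is_error(self):
        with pytest.raises(ValueError, match="zz"):
            ann.per_group_rates([ProductAnnotation("zz", "x")], [], {}, self.META)

    def test_pooled_and_averaged_variants_emitted(self):
        products, mapping = self._fixture()
        out = ann.per_group_rates(products, [], mapping, self.META)
        assert out["overall_pooled"][0] == pytest.approx(0.5)
        assert out["overall_averaged"][0] == pytest.approx(0.5)


class TestPlddt:
    def test_mean_and_classification(self):
        m = StructureModel("x", (70.0, 80.0, 90.0))
        assert ann.mean_plddt(m) == pytest.approx(80.0)
        assert ann.classify_plddt(80.0) == "High_pLDDT"

    def test_boundary_inclusive_at_70(self):
        assert ann.classify_plddt(70.0) == "High_pLDDT"
        assert ann.classify_plddt(69.9) == "Low_pLDDT"


class TestCounterDefenseScreen:
    def test_strictly_above_threshold(self):
        kept = ann.counter_defense_screen([hit(tm=0.61), hit(tm=0.60)])
        assert [k.tm_score for k in kept] == [0.61]

    def test_empty_input_empty_output(self):
        assert ann.counter_defense_screen([]) == []
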