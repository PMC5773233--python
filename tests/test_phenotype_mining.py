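"""Phenotype mining: parsing, term classification, gene linkage, gene sets."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omimgwas.phenotype_mining import (
    GenePhenotypeLink,
    MalformedRecordError,
    PhenotypeRecord,
    RefractiveClassification,
    TermLexicon,
    build_gene_sets,
    classify_refractive,
    link_genes,
    mining_report,
    parse_omim_records,
)
from omimgwas.synthetic import SyntheticConfig, gen_omim_fixture

RECORD_TEXT = """*RECORD*
*FIELD* NO
100001
*FIELD* TI
#100001 FIRST SYNDROME
*FIELD* CS
Eyes:
   Severe myopia;
   Cataract
*RECORD*
*FIELD* NO
100002
*FIELD* TI
#100002 SECOND SYNDROME
*FIELD* TX
No clinical synopsis section in this one.
*RECORD*
*FIELD* NO
100003
*FIELD* CS
Growth:
   Short stature
"""


class TestParsing:
    def test_empty_stream_gives_empty_list(self):
        assert parse_omim_records("") == []

    def test_records_parsed_in_file_order_with_fields(self):
        records = parse_omim_records(RECORD_TEXT)
        assert [r.mim_id for r in records] == ["100001", "100002", "100003"]
        assert records[0].title.startswith("#100001")
        assert "Severe myopia" in records[0].clinical_text
        # missing clinical-synopsis section defaults to empty text
        assert records[1].clinical_text == ""
        # clinical text is always a substring of the raw block
        for r in records:
            assert r.clinical_text in r.raw_block

    def test_missing_id_field_reports_byte_offset(self):
        bad = "*RECORD*\n*FIELD* TI\nOrphan title, no id\n"
        text = RECORD_TEXT + bad
        with pytest.raises(MalformedRecordError, match=str(len(RECORD_TEXT.encode()))):
            parse_omim_records(text)

    def test_generated_fixture_round_trips_ids(self):
        config = SyntheticConfig()
        text, _, _, manifest = gen_omim_fixture(config, seed=1)
        records = parse_omim_records(text)
        assert [r.mim_id for r in records] == list(manifest.planted_classes)


class TestClassification:
    @pytest.mark.parametrize(
        ("text", "expected"),
        [
            ("Severe myopia; cataract", {"myopia"}),
            (
                "myopic astigmatism and hypermetropia",
                {"myopia", "astigmatism", "hyperopia"},
            ),
            ("", set()),
            ("High hyperopia with near-sightedness episodes", {"hyperopia", "myopia"}),
            ("Refractive error of unknown type", {"ametropia_other"}),
            # whole-word rule: no match inside longer or hyphen-joined words
            ("amyopiaX and pre-myopia and myopias", set()),
            ("MYOPIA (caps)", {"myopia"}),
        ],
    )
    def test_class_detection(self, lexicon, text, expected):
        record = PhenotypeRecord("1", "", text, text)
        result = classify_refractive(record, lexicon)
        assert set(result.classes_found) == expected

    def test_matches_carry_offsets_and_agree_with_classes(self, lexicon):
        text = "Cataract; severe myopia; mild astigmatism"
        record = PhenotypeRecord("1", "", text, text)
        result = classify_refractive(record, lexicon)
        assert set(result.classes_found) == {c for c, _, _ in result.matches}
        for cls, term, offset in result.matches:
            assert text[offset : offset + len(term)].lower() == term.lower()

    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz -;,", max_size=80))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_no_classes_without_terms(self, text):
        """Random letter soup never triggers a class unless a term occurs."""
        lexicon = TermLexicon.default()
        record = PhenotypeRecord("1", "", text, text)
        result = classify_refractive(record, lexicon)
        assert result.classes_found == frozenset(c for c, _, _ in result.matches)
        has_term = any(
            term in text.lower()
            for terms in lexicon.classes.values()
            for term in terms
        )
        if not has_term:
            assert result.classes_found == frozenset()

    def test_lexicon_rejects_term_shared_across_classes(self):
        with pytest.raises(ValueError, match="appears under both"):
            TermLexicon({"myopia": ["myopia"], "hyperopia": ["Myopia"]})

    def test_lexicon_rejects_empty_class(self):
        with pytest.raises(ValueError, match="no terms"):
            TermLexicon({"myopia": []})


def _classified(mim, classes):
    return RefractiveClassification(
        mim, frozenset(classes), tuple((c, c, 0) for c in classes)
    )


class TestLinkage:
    def test_links_skips_and_unmapped(self):
        classified = [
            _classified("1", {"myopia"}),
            _classified("2", {"myopia"}),
            _classified("3", {"hyperopia"}),
            _classified("4", {"myopia"}),
            _classified("5", set()),  # not refractive: ignored entirely
        ]
        morbidmap = "\n".join(
            [
                "Syndrome A, 1\tGENEA\t1",
                "Syndrome B, 2\tGENEB, GENEC\t2",
                "Syndrome C, 3\tGENEA\t3",
            ]
        )
        gene_ids = "\n".join(
            [
                "600001\tgene\t11\tGENEA\tENSG1",
                "600002\tgene\t12\tGENEB\tENSG2",
            ]
        )
        import io

        result = link_genes(
            classified,
            io.StringIO(morbidmap),
            io.StringIO(gene_ids),
        )
        assert [(l.mim_id, l.gene_symbol) for l in result.links] == [
            ("1", "GENEA"),
            ("2", "GENEB"),
            ("2", "GENEC"),
            ("3", "GENEA"),
        ]
        # phenotype 4 is refractive but has no gene row
        assert result.skipped_mim_ids == ["4"]
        # GENEC missing from the id table: link kept, symbol reported
        assert result.unmapped_symbols == ["GENEC"]
        assert [l.gene_id for l in result.links] == ["11", "12", "", "11"]

    def test_two_phenotypes_one_gene_stay_distinct_links(self):
        import io

        result = link_genes(
            [_classified("1", {"myopia"}), _classified("2", {"myopia"})],
            io.StringIO("A, 1\tG\t1\nB, 2\tG\t2"),
            io.StringIO("600001\tgene\t1\tG\tE1"),
        )
        assert len(result.links) == 2
        assert {l.mim_id for l in result.links} == {"1", "2"}


class TestGeneSets:
    def test_duplicate_collapse_matches_hand_count(self):
        # 130 myopia links over 119 genes: 7 genes carry 11 surplus links
        surplus = {"G1": 4, "G2": 3, "G3": 3, "G4": 2, "G5": 2, "G6": 2, "G7": 2}
        links, classifications, mim = [], [], 0
        for g, n_links in surplus.items():
            for _ in range(n_links):
                mim += 1
                links.append(GenePhenotypeLink(str(mim), g))
        for i in range(119 - len(surplus)):
            mim += 1
            links.append(GenePhenotypeLink(str(mim), f"H{i}"))
        classifications = [_classified(l.mim_id, {"myopia"}) for l in links]
        assert len(links) == 130
        sets = build_gene_sets(links, classifications)
        assert len(sets["any-myopia"]) == 119
        assert sets["any-myopia"].n_duplicates == 11
        # duplicate count equals sum over genes of (links - 1)
        per_gene = {}
        for l in links:
            per_gene[l.gene_symbol] = per_gene.get(l.gene_symbol, 0) + 1
        assert sets["any-myopia"].n_duplicates == sum(n - 1 for n in per_gene.values())

    def test_exclusive_sets_are_subsets_of_any_sets(self):
        links = [
            GenePhenotypeLink("1", "A"),
            GenePhenotypeLink("2", "B"),
            GenePhenotypeLink("3", "C"),
        ]
        classifications = [
            _classified("1", {"myopia"}),
            _classified("2", {"myopia", "astigmatism"}),
            _classified("3", {"hyperopia"}),
        ]
        sets = build_gene_sets(links, classifications)
        assert set(sets["myopia-only"].gene_symbols) == {"A"}
        assert set(sets["any-myopia"].gene_symbols) == {"A", "B"}
        assert set(sets["any-astigmatism"].gene_symbols) == {"B"}
        assert set(sets["all-ametropia"].gene_symbols) == {"A", "B", "C"}
        for label in ("myopia", "hyperopia", "astigmatism"):
            assert set(sets[f"{label}-only"].gene_symbols) <= set(
                sets[f"any-{label}"].gene_symbols
            )

    def test_disjoint_links_have_no_duplicates(self):
        links = [GenePhenotypeLink(str(i), f"G{i}") for i in range(5)]
        classifications = [_classified(str(i), {"myopia"}) for i in range(5)]
        sets = build_gene_sets(links, classifications)
        assert len(sets["any-myopia"]) == 5
        assert sets["any-myopia"].n_duplicates == 0

    def test_mining_report_counts(self):
        config = SyntheticConfig()
        text, morbid, ids, manifest = gen_omim_fixture(config, seed=3)
        import io

        records = parse_omim_records(text)
        classifications = [classify_refractive(r) for r in records]
        result = link_genes(classifications, io.StringIO(morbid), io.StringIO(ids))
        sets = build_gene_sets(result.links, classifications)
        report = mining_report(records, classifications, result, sets)
        assert report["n_records"] == config.n_omim_records
        assert report["n_skipped_without_gene"] == len(manifest.unlinked_mim_ids)
        assert report["n_linked_phenotypes"] + report["n_skipped_without_gene"] == (
            report["n_refractive_entities"]
        )
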