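"""Detection-table loading, binarization, and summary counts."""

import csv

import pytest

import chemotrace as ct
from chemotrace.chemo_matrix import ABSENT, MISSING, PRESENT, CodingPolicy
from chemotrace.errors import (
    ConfigurationError,
    DataFormatError,
    RankLookupError,
)


class TestLoading:
    def test_packaged_eupnoi_table_shape(self, library):
        m = ct.load_packaged_tables(("eupnoi",))
        assert len(m.taxa) == 40
        assert len(m.compounds) == 10
        assert m.compounds[0] == "NQ" and m.compounds[-1] == "ABQ"

    def test_packaged_tables_concatenate(self, all_tables):
        assert len(all_tables.taxa) == 85
        assert all_tables.cell("Phalangium_opilio", "NQ") is ct.DetectionState.DETECTED
        assert all_tables.cell("Opilio_ruzickai", "BQ") is ct.DetectionState.MISSING
        assert (
            all_tables.cell("Nemastoma_triste", "CNQ") is ct.DetectionState.PARTIAL
        )

    def test_empty_file_rejected(self, tmp_path, library):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(DataFormatError, match="empty"):
            ct.load_detection_table(p, library)

    def test_invalid_cell_symbol_named(self, tmp_path, library):
        p = tmp_path / "bad.csv"
        p.write_text("taxon,NQ,BQ\nA_b,D,N\nC_d,x,N\n")
        with pytest.raises(DataFormatError, match=r"row 3 \(C_d\), compound NQ.*'x'"):
            ct.load_detection_table(p, library)

    def test_ragged_row_rejected_with_index(self, tmp_path, library):
        p = tmp_path / "ragged.csv"
        p.write_text("taxon,NQ,BQ\nA_b,D\n")
        with pytest.raises(DataFormatError, match="row 2"):
            ct.load_detection_table(p, library)

    def test_unknown_compound_code_names_column(self, tmp_path, library):
        p = tmp_path / "unknown.csv"
        p.write_text("taxon,NQ,XYZ\nA_b,D,N\n")
        with pytest.raises(DataFormatError, match="column 3.*'XYZ'"):
            ct.load_detection_table(p, library)

    def test_unicode_table_symbols_accepted(self, tmp_path, library):
        p = tmp_path / "uni.csv"
        p.write_text("taxon,NQ,BQ\nA_b,■,□\nC_d,◩,?\nE_f,-,-\n")
        m = ct.load_detection_table(p, library)
        assert m.cell("A_b", "NQ") is ct.DetectionState.DETECTED
        assert m.cell("C_d", "NQ") is ct.DetectionState.PARTIAL
        assert m.cell("C_d", "BQ") is ct.DetectionState.INCONCLUSIVE
        assert m.cell("E_f", "BQ") is ct.DetectionState.MISSING


class TestBinarize:
    def test_benzoquinone_only_row(self, characters):
        # Megabunus armatus: BQ detected, everything else not detected
        assert characters.state("Megabunus_armatus", "NQ-class") == ABSENT
        assert characters.state("Megabunus_armatus", "BQ-class") == PRESENT

    def test_all_negative_row(self, characters):
        assert characters.state("Mitostoma_chrysomelas", "NQ-class") == ABSENT
        assert characters.state("Mitostoma_chrysomelas", "BQ-class") == ABSENT

    def test_all_inconclusive_row_is_missing(self, characters):
        assert characters.state("Odiellus_sp", "NQ-class") == MISSING
        assert characters.state("Odiellus_sp", "BQ-class") == MISSING

    def test_data_missing_cells_code_missing_not_absent(self, characters):
        # the one row with dash (no data) cells for both benzoquinone columns
        assert characters.state("Opilio_ruzickai", "BQ-class") == MISSING

    def test_partial_counts_as_present(self, characters):
        # alkylated benzoquinones reported for only part of the species
        assert characters.state("Gonyleptidae_spp", "BQ-class") == PRESENT

    def test_positive_iff_some_family_compound_positive(self, all_tables, characters):
        nq_codes = set(ct.DEFAULT_POLICY.characters["NQ-class"])
        for taxon in all_tables.taxon_names:
            expect = any(
                all_tables.cell(taxon, c).positive for c in nq_codes
            )
            assert (characters.state(taxon, "NQ-class") == PRESENT) is expect

    def test_permutation_invariance_and_idempotence(self, all_tables, rng):
        base = ct.binarize(all_tables).to_dataframe()
        order = list(rng.permutation(all_tables.taxon_names))
        taxa = [all_tables.taxon(t) for t in order]
        cells = {
            (t, c): all_tables.cell(t, c)
            for t in order
            for c in all_tables.compounds
        }
        shuffled = ct.DetectionMatrix(taxa, all_tables.compounds[::-1], cells)
        again = ct.binarize(shuffled).to_dataframe()
        assert base.sort_index().equals(again.sort_index())

    def test_policy_with_unknown_code_rejected(self, all_tables):
        bad = CodingPolicy("bad", {"X-class": ("NOPE",)})
        with pytest.raises(ConfigurationError, match="NOPE"):
            ct.binarize(all_tables, bad)

    def test_anthraquinones_excluded_by_default_available_on_request(
        self, all_tables
    ):
        assert ct.binarize(all_tables).characters == ["NQ-class", "BQ-class"]
        with_aq = ct.binarize(all_tables, ct.POLICY_WITH_AQ)
        assert with_aq.state("Paranemastoma_bicuspidatum", "AQ-class") == PRESENT


class TestSummarize:
    def test_nine_positive_quinones_among_palpatoreans(self, palpatores_tables):
        s = ct.summarize(palpatores_tables)
        assert s.n_positive_compounds == 9
        assert "ABQ" not in s.positive_compounds

    def test_five_megabunus_species_with_benzoquinone(self, all_tables):
        s = ct.summarize(
            all_tables,
            where={"genus": "Megabunus"},
            compounds=["BQ"],
            states=[ct.DetectionState.DETECTED],
        )
        assert s.taxa_per_compound == {"BQ": 5}

    def test_unknown_rank_value_raises(self, all_tables):
        with pytest.raises(RankLookupError):
            ct.summarize(all_tables, where={"genus": "Tyrannosaurus"})
        with pytest.raises(RankLookupError):
            ct.summarize(all_tables, where={"kingdom": "Animalia"})

    def test_all_negative_matrix_has_empty_support(self, tmp_path, library):
        p = tmp_path / "neg.csv"
        p.write_text("taxon,NQ,BQ\nA_b,N,N\nC_d,N,N\n")
        s = ct.summarize(ct.load_detection_table(p, library))
        assert s.n_positive_compounds == 0
        assert all(v == 0 for v in s.taxa_per_compound.values())

    def test_totals_match_brute_force_scan_of_raw_csv(self, all_tables):
        from importlib import resources

        positive = {"D", "P"}
        seen = set()
        for name in (
            "eupnoi_detections.csv",
            "dyspnoi_detections.csv",
            "laniatores_cyphophthalmi_detections.csv",
        ):
            text = (resources.files("chemotrace.data") / name).read_text()
            rows = list(csv.reader(text.splitlines()))
            header = rows[0][1:]
            for row in rows[1:]:
                for code, cell in zip(header, row[1:]):
                    if cell in positive:
                        seen.add(code)
        assert set(ct.summarize(all_tables).positive_compounds) == seen


class TestExport:
    def test_nexus_and_csv_round_trip(self, characters, tmp_path):
        nex = tmp_path / "chars.nex"
        csv_path = tmp_path / "chars.csv"
        characters.to_nexus(nex)
        characters.to_csv(csv_path)
        text = nex.read_text()
        assert "DATATYPE=STANDARD" in text and "SYMBOLS=\"01\"" in text
        assert "'NQ-class'" in text and "'BQ-class'" in text
        back = ct.CharacterMatrix.from_csv(csv_path)
        assert back.to_dataframe().equals(characters.to_dataframe())
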