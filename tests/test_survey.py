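"""Survey table I/O, validation, summaries, reduction and filtering."""

import numpy as np
import pandas as pd
import pytest

from wolbsurvey import (SurveyFormatError, SurveyTable, SurveyValidationError,
                        exclude_family, load_survey, read_column_map,
                        reduce_one_per_species, subset, summarize_survey,
                        write_survey)
from conftest import make_table


class TestLoadWrite:
    def test_csv_roundtrip_bit_identical(self, toy_table, tmp_path):
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_survey(toy_table, p1)
        reloaded = load_survey(p1)
        assert reloaded.frame.equals(toy_table.frame)
        write_survey(reloaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tab_delimiter_autodetected(self, toy_table, tmp_path):
        p = tmp_path / "a.tsv"
        write_survey(toy_table, p, sep="\t")
        assert load_survey(p).frame.equals(toy_table.frame)

    def test_three_row_identity_read(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "species_id,order,family,habitat,n_tested,n_infected,source\n"
            "s1,Diptera,Culicidae,aquatic,5,2,x\n"
            "s2,Odonata,,aquatic,3,0,x\n"
            "s3,Hymenoptera,,terrestrial,8,8,y\n")
        table = load_survey(p)
        assert len(table) == 3
        assert table.records[0].species_id == "s1"
        assert table.records[2].n_infected == 8

    def test_invalid_row_reported_with_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "species_id,order,family,habitat,n_tested,n_infected,source\n"
            "s1,Diptera,,aquatic,5,2,x\n"
            "s2,Odonata,,aquatic,3,5,x\n")
        with pytest.raises(SurveyValidationError) as exc:
            load_survey(p)
        assert exc.value.problems[0][0] == 2
        assert "n_infected=5 > n_tested=3" in str(exc.value)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("species_id,habitat,n_tested\ns1,aquatic,5\n")
        with pytest.raises(SurveyFormatError, match="missing required"):
            load_survey(p)

    def test_column_map_adapts_foreign_headers(self, tmp_path):
        p = tmp_path / "foreign.csv"
        p.write_text("Species,Order,Family,Habitat,Ntested,Npos,Ref\n"
                     "s1,Diptera,Culicidae,aquatic,5,2,x\n")
        cfg = tmp_path / "map.cfg"
        cfg.write_text("species_id=Species\norder=Order\nfamily=Family\n"
                       "habitat=Habitat\nn_tested=Ntested\nn_infected=Npos\n"
                       "source=Ref\n")
        table = load_survey(p, read_column_map(cfg))
        assert len(table) == 1
        assert table.records[0].n_tested == 5

    @pytest.mark.parametrize("habitat,n,i", [
        ("marine", 5, 1), ("aquatic", 0, 0), ("aquatic", 5, -1)])
    def test_invariant_violations_rejected(self, habitat, n, i):
        with pytest.raises(SurveyValidationError):
            make_table([("s1", "Diptera", "", habitat, n, i, "")])


class TestSummaries:
    def test_samples_vs_species_counting(self):
        t = make_table([("s1", "O", "", "aquatic", 5, 1, ""),
                        ("s1", "O", "", "aquatic", 9, 2, "")])
        s = summarize_survey(t)
        assert s.n_samples == 2
        assert s.n_species == 1

    def test_family_share_by_samples(self):
        t = make_table([("s1", "Diptera", "Culicidae", "aquatic", 5, 1, ""),
                        ("s2", "Odonata", "Libellulidae", "aquatic", 5, 0, ""),
                        ("s3", "Odonata", "", "aquatic", 5, 0, ""),
                        ("s4", "Coleoptera", "", "aquatic", 5, 0, ""),
                        ("s5", "Hymenoptera", "Apidae", "terrestrial", 5, 0, "")])
        s = summarize_survey(t)
        assert s.share_of_family("Culicidae", habitat="aquatic") == 0.25
        assert s.share_of_family("Culicidae") == 0.2
        # 5 of 20 aquatic individuals are Culicidae
        assert s.share_of_family("Culicidae", habitat="aquatic",
                                 basis="individuals") == 0.25

    def test_per_habitat_and_order_counts(self, toy_table):
        s = summarize_survey(toy_table)
        assert s.n_species_by_habitat == {"aquatic": 3, "terrestrial": 2}
        assert s.n_samples_by_habitat == {"aquatic": 4, "terrestrial": 2}
        assert s.n_samples_by_order["Ephemeroptera"] == 2

    def test_empty_table_summarizes_to_zeros(self):
        t = SurveyTable(pd.DataFrame(columns=[
            "species_id", "order", "family", "habitat", "n_tested",
            "n_infected", "source"]))
        s = summarize_survey(t)
        assert (s.n_samples, s.n_species) == (0, 0)
        assert s.share_of_family("Culicidae") == 0.0


class TestReduction:
    def test_keeps_largest_sample_per_species(self, toy_table):
        reduced = reduce_one_per_species(toy_table)
        baetis = [r for r in reduced if r.species_id == "Baetis_sp1"]
        assert len(baetis) == 1
        assert (baetis[0].n_tested, baetis[0].n_infected) == (10, 2)
        assert reduced.metadata["reduced"] is True

    def test_tie_break_prefers_more_infected_then_file_order(self):
        t = make_table([("sB", "O", "", "aquatic", 7, 0, "first"),
                        ("sB", "O", "", "aquatic", 7, 3, "second"),
                        ("sC", "O", "", "aquatic", 4, 1, "first"),
                        ("sC", "O", "", "aquatic", 4, 1, "second")])
        reduced = reduce_one_per_species(t)
        by_id = {r.species_id: r for r in reduced}
        assert by_id["sB"].n_infected == 3
        assert by_id["sC"].source == "first"

    def test_idempotent_and_species_preserving(self, toy_table):
        once = reduce_one_per_species(toy_table)
        twice = reduce_one_per_species(once)
        assert once.frame.equals(twice.frame)
        assert summarize_survey(once).n_species == summarize_survey(toy_table).n_species
        assert len(once) <= len(toy_table)

    def test_random_tables_obey_reduction_contract(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(1, 30)
            species = [f"sp{rng.integers(0, 8)}" for _ in range(n)]
            tested = rng.integers(1, 20, size=n)
            rows = [(s, "O", "", "aquatic", int(t), int(rng.integers(0, t + 1)), "")
                    for s, t in zip(species, tested)]
            t = make_table(rows)
            r = reduce_one_per_species(t)
            df = r.frame
            assert df["species_id"].is_unique
            # retained n_tested is the species maximum
            for sp, g in t.frame.groupby("species_id"):
                kept = df[df["species_id"] == sp]["n_tested"].iloc[0]
                assert kept == g["n_tested"].max()
            assert reduce_one_per_species(r).frame.equals(df)


class TestFilters:
    def test_exclude_family_counts(self):
        rows = [(f"c{i}", "Diptera", "Culicidae", "aquatic", 5, 1, "")
                for i in range(3)]
        rows += [(f"o{i}", "Odonata", "", "aquatic", 5, 1, "") for i in range(7)]
        t = make_table(rows)
        out = exclude_family(t, "Culicidae")
        assert len(out) == 7
        assert summarize_survey(out).share_of_family("Culicidae") == 0.0

    def test_exclude_absent_family_is_identity_with_warning(self, toy_table, caplog):
        with caplog.at_level("WARNING", logger="wolbsurvey"):
            out = exclude_family(toy_table, "Nycteribiidae")
        assert out.frame.equals(toy_table.frame)
        assert "not present" in caplog.text

    def test_exclude_matches_brute_force(self, toy_table):
        out = exclude_family(toy_table, "Baetidae")
        expected = [r for r in toy_table if r.family != "Baetidae"]
        assert out.records == expected

    def test_subset_predicates(self, toy_table):
        assert len(subset(toy_table, habitat="aquatic")) == 4
        both = subset(toy_table, habitat="aquatic", order="Ephemeroptera")
        assert [r.species_id for r in both] == ["Baetis_sp1", "Baetis_sp1"]
        assert subset(toy_table).frame.equals(toy_table.frame)
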