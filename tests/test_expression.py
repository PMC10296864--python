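import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genefabric import (
    DesignError,
    FormatError,
    GeneSet,
    gene_profiles,
    normalize_to_median,
    read_expression_table,
    read_gene_sets,
)

from conftest import make_table


def write_toy_tsv(path, rows, conditions=("CO", "HO", "CM", "HM"), nrep=4):
    cols = [f"{c}_r{j+1}" for c in conditions for j in range(nrep)]
    lines = ["\t".join(["gene", *cols])]
    for gene, values in rows:
        lines.append("\t".join([gene, *map(str, values)]))
    path.write_text("\n".join(lines) + "\n")
    return {
        "gene_column": "gene",
        "conditions": {c: [f"{c}_r{j+1}" for j in range(nrep)] for c in conditions},
    }


class TestReadExpressionTable:
    def test_parses_toy_four_condition_design(self, tmp_path):
        p = tmp_path / "x.tsv"
        layout = write_toy_tsv(p, [(f"g{i}", range(16)[0:16]) for i in range(4)])
        # all-zero rows are fine structurally; use 1..16 instead
        layout = write_toy_tsv(p, [(f"g{i}", [v + 1 for v in range(16)]) for i in range(4)])
        table = read_expression_table(p, layout)
        assert len(table.spot_ids) == 4
        assert table.conditions == ["CO", "HO", "CM", "HM"]
        assert all(table.n_replicates(c) == 4 for c in table.conditions)

    def test_duplicate_symbol_gives_redundant_spots(self, tmp_path):
        p = tmp_path / "x.tsv"
        layout = write_toy_tsv(
            p, [("g1", [v + 1 for v in range(16)]), ("g1", [v + 2 for v in range(16)])]
        )
        table = read_expression_table(p, layout)
        assert len(table.spots_of_gene("g1")) == 2
        prof = gene_profiles(table, "CO")["g1"]
        assert prof.n_spots == 2

    def test_na_cell_drops_row_and_counts_it(self, tmp_path):
        p = tmp_path / "x.tsv"
        vals_bad = ["NA"] + [str(v + 1) for v in range(15)]
        cols = [f"{c}_r{j+1}" for c in ("CO", "HO", "CM", "HM") for j in range(4)]
        p.write_text(
            "\t".join(["gene", *cols]) + "\n"
            + "\t".join(["g1", *vals_bad]) + "\n"
            + "\t".join(["g2", *[str(v + 1) for v in range(16)]]) + "\n"
        )
        layout = {
            "gene_column": "gene",
            "conditions": {c: [f"{c}_r{j+1}" for j in range(4)] for c in ("CO", "HO", "CM", "HM")},
        }
        table = read_expression_table(p, layout)
        assert table.log["rows_dropped"] == 1
        assert table.log["rows_kept"] == 1
        assert table.log["rows_dropped"] + table.log["rows_kept"] == table.log["rows_in"]

    def test_missing_gene_column_is_format_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        layout = write_toy_tsv(p, [("g1", [v + 1 for v in range(16)])])
        layout["gene_column"] = "symbol"
        with pytest.raises(FormatError):
            read_expression_table(p, layout)

    def test_single_replicate_condition_is_design_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        layout = write_toy_tsv(p, [("g1", [v + 1 for v in range(16)])])
        layout["conditions"]["CO"] = layout["conditions"]["CO"][:1]
        with pytest.raises(DesignError):
            read_expression_table(p, layout)

    def test_negative_intensity_is_value_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        layout = write_toy_tsv(p, [("g1", [-1] + [v + 1 for v in range(15)])])
        with pytest.raises(ValueError):
            read_expression_table(p, layout)


class TestGeneSets:
    def test_gmt_line_roundtrip(self, tmp_path):
        # citrate-cycle members as an 8-gene set
        members = ["Acly", "Aco2", "Fh", "Idh2", "Idh3g", "Ogdh", "Pck2", "Pdha1"]
        p = tmp_path / "s.gmt"
        p.write_text("citrate_cycle\tKEGG\t" + "\t".join(members) + "\n")
        (gs,) = read_gene_sets(p)
        assert gs.name == "citrate_cycle"
        assert len(gs.members) == 8

    def test_duplicate_members_deduplicated(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\td\tG1\tG1\tG2\n")
        (gs,) = read_gene_sets(p)
        assert gs.members == frozenset({"G1", "G2"})

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("")
        assert read_gene_sets(p) == []

    def test_short_line_is_format_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\tdesc\n")
        with pytest.raises(FormatError):
            read_gene_sets(p)

    def test_empty_member_set_rejected(self):
        with pytest.raises(FormatError):
            GeneSet("S", "d", frozenset())


class TestNormalizeToMedian:
    def test_constant_condition_becomes_one(self):
        t = make_table({"g1": [7.0] * 4, "g2": [7.0] * 4})
        out = normalize_to_median(t)
        assert np.allclose(out.values.to_numpy(), 1.0)

    def test_hand_median(self):
        t = make_table({"g1": [1.0, 2.0, 3.0, 4.0]})
        out = normalize_to_median(t)
        assert np.allclose(out.values.to_numpy(), [0.4, 0.8, 1.2, 1.6])

    def test_idempotent(self, toy_table):
        once = normalize_to_median(toy_table)
        twice = normalize_to_median(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    @settings(deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        t = make_table({"g1": [96.0, 98.0, 102.0, 104.0], "g2": [87.0, 83.0, 110.0, 120.0]})
        base = normalize_to_median(t).values.to_numpy()
        scaled = make_table({"g1": [c * v for v in [96, 98, 102, 104]],
                             "g2": [c * v for v in [87, 83, 110, 120]]})
        assert np.allclose(normalize_to_median(scaled).values.to_numpy(), base, rtol=1e-9)

    def test_per_condition_median_is_one(self, small_synthetic):
        table, _ = small_synthetic
        for c in table.conditions:
            med = np.nanmedian(table.condition_values(c).to_numpy())
            assert med == pytest.approx(1.0, abs=1e-12)


class TestGeneProfiles:
    def test_single_spot_replicate_values(self, toy_profiles):
        assert list(toy_profiles["A"].replicate_values) == [96, 98, 102, 104]
        assert toy_profiles["A"].spot_means[0] == 100

    def test_two_identical_spots(self):
        t = make_table({"g": [5.0, 6.0, 7.0, 8.0]})
        v = t.values.loc[["g_s1"]]
        dup = pd.concat([t.values, v.rename(index={"g_s1": "g_s2"})])
        t2 = type(t)(
            values=dup,
            gene_of_spot=pd.Series(["g", "g"], index=dup.index),
            replicate_columns=t.replicate_columns,
        )
        prof = gene_profiles(t2, "CO")["g"]
        assert np.allclose(prof.replicate_values, [5, 6, 7, 8])

    def test_gene_level_mean_over_spots(self):
        t = make_table({"g": [1.0, 1.0, 1.0, 1.0]})
        dup = pd.concat([t.values, (t.values * 3).rename(index={"g_s1": "g_s2"})])
        t2 = type(t)(
            values=dup,
            gene_of_spot=pd.Series(["g", "g"], index=dup.index),
            replicate_columns=t.replicate_columns,
        )
        assert np.allclose(gene_profiles(t2, "CO")["g"].replicate_values, [2, 2, 2, 2])

    def test_row_order_independence(self, toy_table):
        shuffled = type(toy_table)(
            values=toy_table.values.iloc[::-1],
            gene_of_spot=toy_table.gene_of_spot,
            replicate_columns=toy_table.replicate_columns,
        )
        a = gene_profiles(toy_table, "CO")
        b = gene_profiles(shuffled, "CO")
        assert set(a) == set(b)
        for g in a:
            assert np.allclose(a[g].replicate_values, b[g].replicate_values)

    def test_missing_value_excludes_spot_from_condition(self):
        t = make_table({"g1": [1.0, 2.0, 3.0, 4.0], "g2": [5.0, 6.0, 7.0, 8.0]})
        vals = t.values.copy()
        vals.iloc[0, 0] = np.nan
        t2 = type(t)(values=vals, gene_of_spot=t.gene_of_spot,
                     replicate_columns=t.replicate_columns)
        profs = gene_profiles(t2, "CO")
        assert "g1" not in profs and "g2" in profs
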