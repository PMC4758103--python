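import numpy as np
import pandas as pd
import pytest

from cellqc.exceptions import ValidationError
from cellqc.features import (
    COMMON_FEATURES,
    assemble_features,
    extract_biological_features,
    extract_features,
    extract_technical_features,
    normalize_counts,
    read_feature_table,
    write_feature_table,
)
from cellqc.io import AlignmentStats, CountMatrix, GeneSetCollection


def matrix_from(values, gene_ids, cell_ids, ercc_prefix="ERCC-"):
    df = pd.DataFrame(values, index=gene_ids, columns=cell_ids, dtype=float)
    mask = np.asarray(df.index.str.startswith(ercc_prefix))
    return CountMatrix(df, mask)


class TestNormalize:
    def test_proportions_and_ercc_denominator(self):
        m = matrix_from(
            [[2], [3], [5], [10]], ["g1", "g2", "g3", "ERCC-1"], ["c1"]
        )
        nm = normalize_counts(m)
        assert nm.values["c1"].tolist() == [0.2, 0.3, 0.5, 1.0]

    def test_scale_invariance(self):
        m1 = matrix_from([[2], [3], [5]], ["g1", "g2", "g3"], ["c1"])
        m2 = matrix_from([[14], [21], [35]], ["g1", "g2", "g3"], ["c1"])
        pd.testing.assert_frame_equal(
            normalize_counts(m1).values, normalize_counts(m2).values
        )

    def test_zero_cell_flagged(self):
        m = matrix_from([[0, 1], [0, 2]], ["g1", "g2"], ["dead", "ok"])
        nm = normalize_counts(m)
        assert nm.flagged_cells == ["dead"]
        assert (nm.values["dead"] == 0).all()
        assert nm.values["ok"].sum() == pytest.approx(1.0)

    def test_per_cell_sum_is_one(self, sim_default):
        matrix, *_ = sim_default
        nm = normalize_counts(matrix)
        sums = nm.endogenous().sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestBiologicalFeatures:
    def test_member_sum(self):
        m = matrix_from([[2], [3], [5]], ["g1", "g2", "g3"], ["c1"])
        nm = normalize_counts(m)
        ft = extract_biological_features(nm, GeneSetCollection({"s": ["g1", "g2"]}))
        assert ft.values.loc["c1", "s"] == pytest.approx(0.5)

    def test_full_coverage_gives_one(self):
        m = matrix_from([[2], [3], [5]], ["g1", "g2", "g3"], ["c1"])
        nm = normalize_counts(m)
        ft = extract_biological_features(
            nm, GeneSetCollection({"all": ["g1", "g2", "g3"]})
        )
        assert ft.values.loc["c1", "all"] == pytest.approx(1.0)

    def test_absent_set_zero_with_warning(self, caplog):
        m = matrix_from([[2]], ["g1"], ["c1"])
        nm = normalize_counts(m)
        with caplog.at_level("WARNING"):
            ft = extract_biological_features(
                nm, GeneSetCollection({"ghost": ["nope"]})
            )
        assert ft.values.loc["c1", "ghost"] == 0.0
        assert "ghost" in caplog.text

    def test_partition_sums_to_one(self, sim_default):
        matrix, _, _, _ = sim_default
        nm = normalize_counts(matrix)
        endo = [g for g, e in zip(matrix.gene_ids, matrix.ercc_mask) if not e]
        half = len(endo) // 2
        gs = GeneSetCollection({"a": endo[:half], "b": endo[half:]})
        ft = extract_biological_features(nm, gs)
        assert np.allclose(ft.values.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_collection_rejected(self):
        m = matrix_from([[2]], ["g1"], ["c1"])
        with pytest.raises(ValidationError):
            extract_biological_features(normalize_counts(m), GeneSetCollection({}))


def stats_from_rows(rows, cells):
    return AlignmentStats(pd.DataFrame(rows, index=pd.Index(cells)))


class TestTechnicalFeatures:
    def test_direct_ratios(self):
        m = matrix_from([[50], [20], [7]], ["g1", "g2", "ERCC-1"], ["c1"])
        st = stats_from_rows(
            [dict(total_reads=100, mapped=90, multimapped=5, unmapped=10,
                  exonic=70, non_exonic=20, duplicated=30, ercc_reads=7)],
            ["c1"],
        )
        ft = extract_technical_features(m, st)
        row = ft.values.loc["c1"]
        assert row["prop_mapped"] == pytest.approx(0.9)
        assert row["prop_multimapped"] == pytest.approx(0.05)
        assert row["prop_unmapped"] == pytest.approx(0.1)
        assert row["prop_non_exonic"] == pytest.approx(20 / 90)
        assert row["prop_duplicated"] == pytest.approx(30 / 90)
        assert row["ercc_to_exonic"] == pytest.approx(0.1)

    def test_single_gene_cell_bins(self):
        # cell expressing one gene: its CPM is 1e6, landing in the top bin
        m = matrix_from([[5, 1], [0, 1]], ["g1", "g2"], ["c1", "c2"])
        st = stats_from_rows(
            [dict(total_reads=10, mapped=8, multimapped=0, unmapped=2,
                  exonic=5, non_exonic=1, duplicated=0, ercc_reads=0)] * 2,
            ["c1", "c2"],
        )
        ft = extract_technical_features(m, st)
        row = ft.values.loc["c1"]
        assert row["n_detected_genes"] == 1
        assert row["n_genes_bin5"] == 1
        assert sum(row[f"n_genes_bin{i}"] for i in range(1, 5)) == 0

    def test_identical_cells_full_mean_correlation(self):
        vals = np.array([[5.0, 5.0], [2.0, 2.0], [9.0, 9.0]])
        m = matrix_from(vals, ["g1", "g2", "g3"], ["c1", "c2"])
        st = stats_from_rows(
            [dict(total_reads=20, mapped=16, multimapped=1, unmapped=4,
                  exonic=16, non_exonic=0, duplicated=2, ercc_reads=0)] * 2,
            ["c1", "c2"],
        )
        ft = extract_technical_features(m, st)
        assert (ft.values["cell_to_mean_correlation"] == 1.0).all()

    def test_cell_set_mismatch_rejected(self):
        m = matrix_from([[1]], ["g1"], ["c1"])
        st = stats_from_rows(
            [dict(total_reads=10, mapped=8, multimapped=0, unmapped=2,
                  exonic=5, non_exonic=1, duplicated=0, ercc_reads=0)],
            ["other"],
        )
        with pytest.raises(ValidationError, match="differ"):
            extract_technical_features(m, st)

    def test_bin_counts_sum_to_detected(self, sim_features):
        ft, _ = sim_features
        bins = ft.values[[f"n_genes_bin{i}" for i in range(1, 6)]].sum(axis=1)
        pd.testing.assert_series_equal(
            bins, ft.values["n_detected_genes"], check_names=False
        )


class TestAssemble:
    def test_common_flags_are_the_seven(self, sim_features):
        ft, _ = sim_features
        flagged = [f for f in ft.feature_names if ft.common_flag[f]]
        assert sorted(flagged) == sorted(COMMON_FEATURES)

    def test_duplicate_feature_name_rejected(self, sim_features):
        ft, _ = sim_features
        with pytest.raises(ValidationError, match="duplicate"):
            assemble_features(ft, ft)

    def test_feature_count_is_concatenation(self, sim_default):
        matrix, stats, sets, _ = sim_default
        nm = normalize_counts(matrix)
        bio = extract_biological_features(nm, sets)
        tech = extract_technical_features(matrix, stats)
        ft = assemble_features(bio, tech)
        assert ft.values.shape[1] == bio.values.shape[1] + tech.values.shape[1]


class TestInvariants:
    def test_proportions_invariant_to_cell_scaling(self, sim_default):
        matrix, stats, sets, _ = sim_default
        k = 7
        scaled_matrix = CountMatrix(
            matrix.values * k, matrix.ercc_mask, matrix.unit
        )
        scaled_stats = AlignmentStats(stats.table * k)
        ft1 = extract_features(matrix, stats, sets)
        ft2 = extract_features(scaled_matrix, scaled_stats, sets)
        proportions = [
            f for f in ft1.feature_names
            if f.startswith(("prop_", "go_", "mtDNA", "mito", "housekeeping"))
            or f in ("ercc_to_exonic", "cell_to_mean_correlation",
                     "transcriptome_variance")
        ]
        pd.testing.assert_frame_equal(
            ft1.values[proportions], ft2.values[proportions], rtol=1e-10
        )

    def test_extraction_deterministic(self, sim_default):
        matrix, stats, sets, _ = sim_default
        ft1 = extract_features(matrix, stats, sets)
        ft2 = extract_features(matrix, stats, sets)
        assert ft1.values.equals(ft2.values)

    def test_proportion_features_in_unit_interval(self, sim_features):
        ft, _ = sim_features
        props = [f for f in ft.feature_names if f.startswith("prop_")]
        vals = ft.values[props].to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1

    def test_table_round_trip(self, sim_features, tmp_path):
        ft, _ = sim_features
        write_feature_table(ft, tmp_path / "ft.tsv")
        back = read_feature_table(tmp_path / "ft.tsv")
        assert np.allclose(back.values, ft.values, rtol=1e-10)
        assert back.common_flag.equals(ft.common_flag)
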