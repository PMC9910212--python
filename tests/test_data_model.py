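import numpy as np
import pandas as pd
import pytest

from clonetrack import data_model
from clonetrack.data_model import REPLICATE_ID


def _write_wide(tmp_path, text, name="matrix.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSparseMatrix:
    def test_zero_and_na_cells_are_dropped(self, tmp_path):
        p = _write_wide(
            tmp_path,
            "chr\tintegration_locus\tstrand\tS1\tS2\n"
            "1\t100\t+\t10\t0\n"
            "2\t200\t-\t5\t3\n",
        )
        long, stats = data_model.read_sparse_matrix(p)
        assert len(long) == 3  # nonzero cells only
        assert stats["n_dropped_cells"] == 1
        assert long["value"].sum() == 18

    def test_single_cell_identity(self, tmp_path):
        p = _write_wide(
            tmp_path, "chr\tintegration_locus\tstrand\tS1\nX\t55\t+\t7\n"
        )
        long, _ = data_model.read_sparse_matrix(p)
        assert len(long) == 1
        row = long.iloc[0]
        assert (row["chr"], row["integration_locus"], row["value"]) == ("X", 55, 7)

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = _write_wide(
            tmp_path,
            "chr\tintegration_locus\tstrand\tS1\tS1\n1\t100\t+\t1\t2\n",
        )
        with pytest.raises(ValueError, match="S1"):
            data_model.read_sparse_matrix(p)

    def test_no_sample_columns_rejected(self, tmp_path):
        p = _write_wide(tmp_path, "chr\tintegration_locus\tstrand\n1\t100\t+\n")
        with pytest.raises(ValueError, match="no sample columns"):
            data_model.read_sparse_matrix(p)

    def test_malformed_locus_names_row(self, tmp_path):
        p = _write_wide(
            tmp_path,
            "chr\tintegration_locus\tstrand\tS1\n1\t100\t+\t1\n2\tabc\t-\t2\n",
        )
        with pytest.raises(ValueError, match="row 2"):
            data_model.read_sparse_matrix(p)

    def test_chr_prefix_stripped(self, tmp_path):
        p = _write_wide(
            tmp_path, "chr\tintegration_locus\tstrand\tS1\nchr17\t100\t+\t4\n"
        )
        long, _ = data_model.read_sparse_matrix(p)
        assert long["chr"].iloc[0] == "17"

    def test_roundtrip_preserves_values(self, tmp_path):
        p = _write_wide(
            tmp_path,
            "chr\tintegration_locus\tstrand\tS1\tS2\n"
            "1\t100\t+\t10\t2\n"
            "2\t200\t-\t5\t3\n",
        )
        long, _ = data_model.read_sparse_matrix(p)
        out = tmp_path / "rt.tsv"
        data_model.write_sparse_matrix(long, out)
        again, _ = data_model.read_sparse_matrix(out)
        key = ["chr", "integration_locus", "strand", REPLICATE_ID]
        pd.testing.assert_frame_equal(
            long.sort_values(key).reset_index(drop=True)[key + ["value"]],
            again.sort_values(key).reset_index(drop=True)[key + ["value"]],
        )


class TestImportGuided:
    def test_only_metadata_samples_imported(self, tmp_path):
        p = _write_wide(
            tmp_path,
            "chr\tintegration_locus\tstrand\tS1\tS2\n1\t100\t+\t10\t5\n",
        )
        meta = pd.DataFrame(
            {REPLICATE_ID: ["S1"], "pool_id": ["P1"], "path_to_matrix": [str(p)]}
        )
        m, report = data_model.import_guided(meta)
        assert set(m[REPLICATE_ID]) == {"S1"}
        assert report.totals_after["per_file"][0]["ignored_samples"] == 1

    def test_empty_metadata_yields_empty_matrix(self):
        meta = pd.DataFrame({REPLICATE_ID: pd.Series([], dtype=str)})
        m, report = data_model.import_guided(meta)
        assert m.empty
        assert report.per_pool == []

    def test_workers_do_not_change_output(self, scenario):
        m1, _ = data_model.import_guided(scenario.metadata, workers=1)
        m4, _ = data_model.import_guided(scenario.metadata, workers=4)
        pd.testing.assert_frame_equal(m1, m4)

    def test_melt_conserves_total_value(self, scenario):
        m, _ = data_model.import_guided(scenario.metadata)
        wide_total = sum(
            w.drop(columns=list(data_model.ANNOTATION_COLUMNS)).sum().sum()
            for w in scenario.matrices.values()
        )
        assert np.isclose(m["value"].sum(), wide_total)

    def test_missing_file_reported_or_raised(self, tmp_path):
        meta = pd.DataFrame(
            {
                REPLICATE_ID: ["S1"],
                "pool_id": ["P1"],
                "path_to_matrix": [str(tmp_path / "nope.tsv")],
            }
        )
        with pytest.raises(ValueError, match="failed to import"):
            data_model.import_guided(meta)
        m, report = data_model.import_guided(meta, on_missing_file="skip")
        assert m.empty
        assert any(f["reason"] == "file failed" for f in report.flagged_items)


class TestVispaStats:
    def test_left_join_flags_unmatched(self, tmp_path):
        meta = pd.DataFrame({REPLICATE_ID: ["S1", "S2"]})
        stats = pd.DataFrame({REPLICATE_ID: ["S1"], "raw_reads": [1_000_000]})
        merged, unmatched = data_model.attach_raw_reads(meta, stats)
        assert unmatched == ["S2"]
        assert merged.loc[merged[REPLICATE_ID] == "S1", "raw_reads"].iloc[0] == 1e6

    def test_empty_stats_leaves_all_missing(self):
        meta = pd.DataFrame({REPLICATE_ID: ["S1", "S2"]})
        stats = pd.DataFrame({REPLICATE_ID: pd.Series([], dtype=str),
                              "raw_reads": pd.Series([], dtype=int)})
        merged, unmatched = data_model.attach_raw_reads(meta, stats)
        assert merged["raw_reads"].isna().all()
        assert unmatched == ["S1", "S2"]

    def test_duplicate_stats_key_rejected(self, tmp_path):
        p = tmp_path / "stats.tsv"
        p.write_text(f"{REPLICATE_ID}\traw_reads\nS1\t10\nS1\t20\n")
        with pytest.raises(ValueError, match="duplicate"):
            data_model.read_vispa2_stats(p)


def test_metadata_validation_rejects_duplicates_and_blanks():
    with pytest.raises(ValueError, match="duplicate"):
        data_model.validate_metadata(pd.DataFrame({REPLICATE_ID: ["a", "a"]}))
    with pytest.raises(ValueError, match="empty"):
        data_model.validate_metadata(pd.DataFrame({REPLICATE_ID: ["a", ""]}))
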