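import numpy as np
import pandas as pd
import pytest

from clonetrack import cis_analysis
from clonetrack.data_model import REPLICATE_ID

from conftest import make_long, make_meta


def _matrix_from_gene_counts(counts: dict[str, int]) -> pd.DataFrame:
    """One distinct IS row per integration; genes per the given counts."""
    rows = []
    locus = 1
    for gene, k in counts.items():
        for _ in range(k):
            rows.append(("1", locus, "+", "S1", 1, gene))
            locus += 100
    return make_long(rows)


class TestGrubbs:
    def test_z_to_t_closed_form(self):
        # n=10, z=2: t = 2*sqrt(8)/sqrt(9-4)
        assert cis_analysis.grubbs_t_from_z(2.0, 10) == pytest.approx(2.5298, abs=1e-4)

    def test_z_at_sample_extreme_gives_infinite_t(self):
        assert cis_analysis.grubbs_t_from_z(3.0, 10) == np.inf  # z^2 = 9 = n-1

    def test_planted_gene_detected_and_only_it(self):
        counts = {f"G{i:03d}": 1 for i in range(100)}
        counts["G_PLANT"] = 50
        m = _matrix_from_gene_counts(counts)
        lengths = pd.DataFrame(
            {"gene_name": list(counts), "length_bp": 10_000}
        )
        out = cis_analysis.cis_grubbs(m, lengths)
        sig = out[out["significant"]]
        assert sig["gene_name"].tolist() == ["G_PLANT"]
        assert out.iloc[0]["gene_name"] == "G_PLANT"
        assert out.iloc[0]["z"] == out["z"].max()

    def test_constant_frequency_yields_no_significance(self):
        counts = {f"G{i}": 3 for i in range(10)}
        m = _matrix_from_gene_counts(counts)
        lengths = pd.DataFrame({"gene_name": list(counts), "length_bp": 10_000})
        out = cis_analysis.cis_grubbs(m, lengths)
        assert not out["significant"].any()
        assert out["p_value"].isna().all()

    def test_p_monotone_decreasing_in_z(self):
        counts = {f"G{i}": k for i, k in enumerate([1, 2, 3, 5, 8, 13, 30])}
        m = _matrix_from_gene_counts(counts)
        lengths = pd.DataFrame({"gene_name": list(counts), "length_bp": 50_000})
        out = cis_analysis.cis_grubbs(m, lengths).sort_values("z")
        p = out["p_value"].to_numpy()
        assert (np.diff(p) <= 1e-15).all()

    def test_scale_constant_does_not_change_calls(self):
        counts = {f"G{i:03d}": 1 for i in range(50)}
        counts["G_PLANT"] = 30
        m = _matrix_from_gene_counts(counts)
        lengths = pd.DataFrame({"gene_name": list(counts), "length_bp": 20_000})
        a = cis_analysis.cis_grubbs(m, lengths, scale="mean_length")
        b = cis_analysis.cis_grubbs(m, lengths, scale="none")
        pd.testing.assert_series_equal(a["p_value"], b["p_value"])

    def test_too_few_genes_rejected(self):
        m = _matrix_from_gene_counts({"G1": 2, "G2": 1})
        lengths = pd.DataFrame({"gene_name": ["G1", "G2"], "length_bp": 1000})
        with pytest.raises(ValueError, match=">= 3 genes"):
            cis_analysis.cis_grubbs(m, lengths)


class TestGeneFrequency:
    def test_fraction_of_total_distinct_is(self):
        rows = [("1", i * 10, "+", "S1", 1, "GeneA" if i < 2 else None)
                for i in range(10)]
        m = make_long(rows)
        out = cis_analysis.gene_frequency(m)
        assert out.loc[out["gene_name"] == "GeneA", "frequency"].iloc[0] == 0.2

    def test_frequencies_sum_at_most_one(self):
        rng = np.random.default_rng(2)
        rows = [
            ("1", int(i * 10), "+", "S1", 1,
             f"G{rng.integers(5)}" if rng.random() < 0.7 else None)
            for i in range(50)
        ]
        out = cis_analysis.gene_frequency(make_long(rows))
        assert out["frequency"].sum() <= 1 + 1e-12


class TestFisherCompare:
    def test_identical_proportions_not_significant(self):
        a = pd.DataFrame({"gene_name": ["G1", "rest"], "is_count": [5, 95]})
        b = pd.DataFrame({"gene_name": ["G1", "rest"], "is_count": [5, 95]})
        out = cis_analysis.fisher_track_compare(a, b)
        g1 = out[out["gene_name"] == "G1"].iloc[0]
        assert g1["odds_ratio"] == pytest.approx(1.0)
        assert g1["p_value"] == pytest.approx(1.0)
        assert not out["significant"].any()

    def test_strong_enrichment_detected_matches_hypergeom(self):
        from scipy.stats import fisher_exact

        a = pd.DataFrame({"gene_name": ["G1", "rest"], "is_count": [50, 50]})
        b = pd.DataFrame({"gene_name": ["G1", "rest"], "is_count": [1, 99]})
        out = cis_analysis.fisher_track_compare(a, b)
        g1 = out[out["gene_name"] == "G1"].iloc[0]
        _, p_expected = fisher_exact([[50, 50], [1, 99]])
        assert g1["p_value"] == pytest.approx(p_expected, rel=1e-9)
        assert g1["p_value"] < 1e-10
        assert g1["significant"]

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(20)]
        a = pd.DataFrame({"gene_name": genes, "is_count": rng.integers(0, 30, 20)})
        b = pd.DataFrame({"gene_name": genes, "is_count": rng.integers(0, 30, 20)})
        a.loc[0, "is_count"] += 1
        ab = cis_analysis.fisher_track_compare(a, b)
        ba = cis_analysis.fisher_track_compare(b, a)
        assert np.allclose(ab["p_value"], ba["p_value"])
        both = (ab["odds_ratio"] > 0) & np.isfinite(ab["odds_ratio"]) & \
               (ba["odds_ratio"] > 0) & np.isfinite(ba["odds_ratio"])
        assert np.allclose(
            ab.loc[both, "odds_ratio"], 1.0 / ba.loc[both, "odds_ratio"]
        )

    def test_gene_absent_from_one_track_is_valid(self):
        a = pd.DataFrame({"gene_name": ["G1", "G2"], "is_count": [5, 5]})
        b = pd.DataFrame({"gene_name": ["G2"], "is_count": [10]})
        out = cis_analysis.fisher_track_compare(a, b)
        assert set(out["gene_name"]) == {"G1", "G2"}
        assert out.loc[out["gene_name"] == "G1", "count_b"].iloc[0] == 0


def test_fdr_control_on_null_simulations():
    """Uniform IS over equal-length genes: few datasets show any CIS call."""
    rng = np.random.default_rng(123)
    n_datasets, hits = 100, 0
    genes = [f"G{i:03d}" for i in range(80)]
    lengths = pd.DataFrame({"gene_name": genes, "length_bp": 50_000})
    for _ in range(n_datasets):
        assignment = rng.integers(0, len(genes), size=600)
        counts = dict(zip(*np.unique(assignment, return_counts=True)))
        m = _matrix_from_gene_counts(
            {genes[i]: int(k) for i, k in counts.items()}
        )
        out = cis_analysis.cis_grubbs(m, lengths)
        hits += int(out["significant"].any())
    assert hits / n_datasets <= 0.10
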