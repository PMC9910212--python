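import math

import numpy as np
import pandas as pd
import pytest

from clonetrack import diversity_stats
from clonetrack.data_model import REPLICATE_ID
from clonetrack.diversity_stats import diversity_index

from conftest import make_long, make_meta


class TestClosedForms:
    def test_two_point_uniform(self):
        v = [5, 5]  # p = (0.5, 0.5)
        assert diversity_index(v, "shannon") == pytest.approx(math.log(2), abs=1e-12)
        assert diversity_index(v, "simpson") == pytest.approx(0.5, abs=1e-12)
        assert diversity_index(v, "invsimpson") == pytest.approx(2.0, abs=1e-12)
        assert diversity_index(v, "pielou") == pytest.approx(1.0, abs=1e-12)

    def test_single_clone_degenerate(self):
        assert diversity_index([7], "shannon") == 0
        assert diversity_index([7], "simpson") == 0
        assert diversity_index([7], "invsimpson") == 1
        assert math.isnan(diversity_index([7], "pielou"))

    def test_uniform_four_clones_renyi_constant(self):
        v = [10, 10, 10, 10]
        assert diversity_index(v, "shannon") == pytest.approx(math.log(4), abs=1e-12)
        assert diversity_index(v, "pielou") == pytest.approx(1.0, abs=1e-12)
        for q in (0, 0.5, 2, 5):
            assert diversity_index(v, "renyi", q=q) == pytest.approx(
                math.log(4), abs=1e-12
            )

    def test_renyi_order_identities(self):
        v = [1, 2, 3, 10]
        p = np.array(v) / sum(v)
        assert diversity_index(v, "renyi", q=0) == pytest.approx(math.log(4), abs=1e-12)
        assert diversity_index(v, "renyi", q=1) == pytest.approx(
            diversity_index(v, "shannon"), abs=1e-12
        )
        assert diversity_index(v, "renyi", q=2) == pytest.approx(
            math.log(diversity_index(v, "invsimpson")), abs=1e-12
        )
        # large-q limit: min-diversity -ln(max p), approached as q/(q-1)
        assert diversity_index(v, "renyi", q=1000) == pytest.approx(
            -math.log(p.max()), abs=1e-3
        )

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            diversity_index([], "shannon")
        with pytest.raises(ValueError):
            diversity_index([1, 0], "shannon")


def test_reference_implementation_agreement():
    """Shannon/Simpson/inverse-Simpson/Pielou match scikit-bio to 1e-9."""
    alpha = pytest.importorskip("skbio.diversity.alpha")
    rng = np.random.default_rng(42)
    for _ in range(100):
        counts = rng.integers(1, 1000, size=rng.integers(2, 40))
        assert diversity_index(counts, "shannon") == pytest.approx(
            alpha.shannon(counts, base=math.e), abs=1e-9
        )
        assert diversity_index(counts, "simpson") == pytest.approx(
            alpha.simpson(counts), abs=1e-9
        )
        assert diversity_index(counts, "invsimpson") == pytest.approx(
            alpha.enspie(counts), abs=1e-9
        )
        assert diversity_index(counts, "pielou") == pytest.approx(
            alpha.pielou_e(counts), abs=1e-9
        )


class TestInvariants:
    def test_bounds_and_scaling_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.integers(1, 500, size=rng.integers(2, 30)).astype(float)
            s = len(v)
            h = diversity_index(v, "shannon")
            j = diversity_index(v, "pielou")
            inv = diversity_index(v, "invsimpson")
            assert 0 <= j <= 1 + 1e-12
            assert h <= math.log(s) + 1e-12
            assert 1 - 1e-12 <= inv <= s + 1e-12
            for idx in ("shannon", "simpson", "invsimpson", "pielou"):
                assert diversity_index(v * 7.5, idx) == pytest.approx(
                    diversity_index(v, idx), abs=1e-12
                )

    def test_shannon_max_iff_uniform(self):
        assert diversity_index([3, 3, 3], "shannon") == pytest.approx(math.log(3))
        assert diversity_index([1, 1, 10], "shannon") < math.log(3)


class TestSampleStatistics:
    def test_hand_computed_group(self):
        m = make_long(
            [("1", 100, "+", "R0", 1), ("2", 50, "-", "R0", 2), ("3", 9, "+", "R0", 3)]
        )
        meta = make_meta([{REPLICATE_ID: "R0", "sample": "s1"}])
        out = diversity_stats.sample_statistics(
            m, meta, ["sample"], functions=("count", "sum", "mean", "median", "sd")
        )
        row = out.iloc[0]
        assert row["distinct_is"] == 3
        assert row["seqCount_count"] == 3
        assert row["seqCount_sum"] == 6
        assert row["seqCount_mean"] == 2
        assert row["seqCount_median"] == 2
        assert row["seqCount_sd"] == pytest.approx(1.0)

    def test_single_value_sd_missing(self):
        m = make_long([("1", 100, "+", "R0", 5)])
        meta = make_meta([{REPLICATE_ID: "R0", "sample": "s1"}])
        out = diversity_stats.sample_statistics(m, meta, ["sample"], functions=("sd",))
        assert math.isnan(out["seqCount_sd"].iloc[0])

    def test_empty_function_selection_keeps_distinct_is(self):
        m = make_long([("1", 100, "+", "R0", 5), ("2", 1, "-", "R0", 1)])
        meta = make_meta([{REPLICATE_ID: "R0", "sample": "s1"}])
        out = diversity_stats.sample_statistics(
            m, meta, ["sample"], functions=(), diversity=()
        )
        assert out["distinct_is"].iloc[0] == 2

    def test_unknown_function_rejected(self):
        m = make_long([("1", 100, "+", "R0", 5)])
        meta = make_meta([{REPLICATE_ID: "R0", "sample": "s1"}])
        with pytest.raises(ValueError, match="harmonic"):
            diversity_stats.sample_statistics(m, meta, ["sample"], functions=("harmonic",))


class TestAbundance:
    def test_relative_fractions(self):
        m = make_long([("1", 100, "+", "R0", 1), ("2", 50, "-", "R0", 3)])
        out = diversity_stats.compute_abundance(m)
        assert sorted(out["relative_abundance"]) == [25.0, 75.0]

    def test_single_is_hundred_percent(self):
        m = make_long([("1", 100, "+", "R0", 9)])
        out = diversity_stats.compute_abundance(m)
        assert out["relative_abundance"].tolist() == [100.0]

    def test_groups_normalize_independently(self):
        m = make_long(
            [("1", 100, "+", "R0", 1), ("2", 50, "-", "R0", 3),
             ("1", 100, "+", "R1", 10)]
        )
        out = diversity_stats.compute_abundance(m)
        sums = out.groupby(REPLICATE_ID)["relative_abundance"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestTopClones:
    def _series(self):
        rows = []
        for tp, ab in zip((30, 90, 180), (0.5, 2.0, 0.1)):
            rows.append(
                {"chr": "1", "integration_locus": 100, "strand": "+",
                 "timepoint": tp, "relative_abundance": ab}
            )
        rows.append(
            {"chr": "2", "integration_locus": 5, "strand": "-",
             "timepoint": 30, "relative_abundance": 0.4}
        )
        return pd.DataFrame(rows)

    def test_flagged_if_above_threshold_at_any_timepoint(self):
        out = diversity_stats.top_clones(self._series(), threshold_pct=1.0)
        by_event = out.groupby("integration_locus")["flagged"].all()
        assert bool(by_event[100]) is True
        assert bool(by_event[5]) is False

    def test_threshold_extremes(self):
        none = diversity_stats.top_clones(self._series(), threshold_pct=100.0)
        assert not none["flagged"].any()
        all_ = diversity_stats.top_clones(self._series(), threshold_pct=0.0)
        assert all_["flagged"].all()
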