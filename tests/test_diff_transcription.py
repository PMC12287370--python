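import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screenscore as ss
from screenscore.errors import DomainError, InputError, SchemaError

# Engineered 6-transcript matrix (2 replicates per condition, replicates
# identical so averaging is exercised but transparent). Library sums are
# pinned by the ballast transcript Z: parental 42,000,000 / resistant
# 35,000,000, giving per-count CPM thresholds of 21 (parental) and 17.5
# (resistant). Per-transcript design, all clauses hand-checked:
#   A  p=10,  r=100  altered (CPM 2.857 via resistant; MC 55; L2FC +3.20)
#   B  p=200, r=10   altered (CPM 4.76 via parental; MC 105; L2FC -4.19)
#   C  p=0,   r=18   fails ONLY MC   (CPM 0.514 > 0.5; MC 9; |L2FC| 4.25)
#   D  p=100, r=120  fails ONLY L2FC (CPM pass; MC 110; |L2FC| 0.26)
#   E  p=20,  r=0    fails ONLY CPM  (0.476/0 <= 0.5; MC 10; |L2FC| 4.39)
#   Z  ballast       fails ONLY L2FC (ratio 0.833, |L2FC| 0.26)
TOY_COUNTS = {
    "A": (10, 100),
    "B": (200, 10),
    "C": (0, 18),
    "D": (100, 120),
    "E": (20, 0),
    "Z": (41999670, 34999752),
}


def toy_matrix() -> ss.CountMatrix:
    data = {
        "L_parental_1": [p for p, _ in TOY_COUNTS.values()],
        "L_parental_2": [p for p, _ in TOY_COUNTS.values()],
        "L_resistant_1": [r for _, r in TOY_COUNTS.values()],
        "L_resistant_2": [r for _, r in TOY_COUNTS.values()],
    }
    return ss.CountMatrix(
        pd.DataFrame(data, index=pd.Index(list(TOY_COUNTS), name="transcript_id"))
    )


class TestElementaryStatistics:
    def test_cpm_direct_arithmetic(self):
        np.testing.assert_allclose(
            ss.cpm(np.array([5, 15, 80]), 100), [50000, 150000, 800000]
        )

    def test_cpm_identities(self):
        assert ss.cpm(np.array([0.0]), 10)[0] == 0.0
        assert ss.cpm(np.array([10.0]), 10)[0] == 1e6

    def test_cpm_bad_library_sum(self):
        with pytest.raises(DomainError):
            ss.cpm(np.array([1.0]), 0)

    @pytest.mark.parametrize(
        "p,r,expected", [(10, 20, 15.0), (0, 0, 0.0), (9, 10, 9.5)]
    )
    def test_mean_counts(self, p, r, expected):
        assert ss.mean_counts(p, r) == expected

    @pytest.mark.parametrize(
        "p,r,expected", [(3, 31, 3.0), (7, 7, 0.0), (0, 0, 0.0)]
    )
    def test_log2_fc_with_pseudocount(self, p, r, expected):
        assert ss.log2_fc(p, r) == pytest.approx(expected)


class TestAlteredTranscripts:
    def test_each_exclusion_attributable_to_one_clause(self):
        res = ss.altered_transcripts(toy_matrix(), "L")
        assert res.altered_ids == {"A", "B"}
        t = res.table.set_index("transcript_id")
        # C fails only the MC clause
        assert t.loc["C", "mc"] < 10
        assert max(t.loc["C", "cpm_parental"], t.loc["C", "cpm_resistant"]) > 0.5
        assert abs(t.loc["C", "l2fc"]) > 2
        # D fails only the fold-change clause
        assert abs(t.loc["D", "l2fc"]) <= 2
        assert t.loc["D", "mc"] >= 10
        assert max(t.loc["D", "cpm_parental"], t.loc["D", "cpm_resistant"]) > 0.5
        # E fails only the CPM clause (MC exactly at its non-strict bound)
        assert max(t.loc["E", "cpm_parental"], t.loc["E", "cpm_resistant"]) <= 0.5
        assert t.loc["E", "mc"] >= 10
        assert abs(t.loc["E", "l2fc"]) > 2

    def test_identical_conditions_flag_nothing(self):
        m = toy_matrix()
        counts = m.counts.copy()
        counts[["L_resistant_1", "L_resistant_2"]] = counts[
            ["L_parental_1", "L_parental_2"]
        ].to_numpy()
        res = ss.altered_transcripts(ss.CountMatrix(counts), "L")
        assert res.altered_ids == set()

    def test_filter_idempotent_on_its_own_output(self):
        m = toy_matrix()
        first = ss.altered_transcripts(m, "L")
        sub = ss.CountMatrix(m.counts.loc[sorted(first.altered_ids)])
        second = ss.altered_transcripts(sub, "L")
        assert second.altered_ids == first.altered_ids

    def test_raising_thresholds_never_adds_transcripts(self):
        m = toy_matrix()
        base = ss.altered_transcripts(m, "L").altered_ids
        for th in (
            ss.FilterThresholds(cpm_min=5.0),
            ss.FilterThresholds(mc_min=100.0),
            ss.FilterThresholds(l2fc_min=4.0),
        ):
            assert ss.altered_transcripts(m, "L", th).altered_ids <= base

    def test_cpm_sums_to_one_million(self):
        res = ss.altered_transcripts(toy_matrix(), "L")
        assert res.table["cpm_parental"].sum() == pytest.approx(1e6)
        assert res.table["cpm_resistant"].sum() == pytest.approx(1e6)

    def test_both_conditions_cpm_mode_is_stricter(self):
        m = toy_matrix()
        strict = ss.altered_transcripts(
            m, "L", ss.FilterThresholds(cpm_mode="both")
        ).altered_ids
        assert strict <= ss.altered_transcripts(m, "L").altered_ids

    def test_missing_state_rejected(self):
        m = toy_matrix()
        parental_only = ss.CountMatrix(
            m.counts[["L_parental_1", "L_parental_2"]]
        )
        with pytest.raises(InputError):
            ss.altered_transcripts(parental_only, "L")

    def test_bad_column_encoding_rejected(self):
        with pytest.raises(SchemaError):
            ss.CountMatrix(pd.DataFrame({"sample1": [1, 2]}))

    def test_round_trip_tsv(self, tmp_path):
        m = toy_matrix()
        path = tmp_path / "counts.tsv"
        m.counts.to_csv(path, sep="\t")
        back = ss.read_count_matrix(path)
        pd.testing.assert_frame_equal(back.counts, m.counts)


class TestVenn:
    def test_study_scale_overlap(self):
        a = {f"t{i}" for i in range(204)}
        b = {f"t{i}" for i in range(197, 365)}  # 168 ids, 7 shared with a
        summary = ss.venn(a, b)
        assert (summary.only_a, summary.only_b, summary.both) == (197, 161, 7)
        assert summary.union == 365

    def test_disjoint(self):
        s = ss.venn({"1"}, {"2"})
        assert (s.only_a, s.only_b, s.both, s.union) == (1, 1, 0, 2)

    def test_identical(self):
        s = ss.venn({"a", "b"}, {"a", "b"})
        assert (s.only_a, s.only_b, s.both, s.union) == (0, 0, 2, 2)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.sets(st.integers(min_value=0, max_value=30)),
        b=st.sets(st.integers(min_value=0, max_value=30)),
    )
    def test_inclusion_exclusion(self, a, b):
        s = ss.venn(map(str, a), map(str, b))
        assert s.union == len(a | b)
        assert s.both == len(a & b)
        assert s.union == len(a) + len(b) - s.both
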