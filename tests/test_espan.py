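"""Bias-statistic pipeline: filtering, counting, log-ratio, averaging,
folding — checked against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from espantools import espan
from espantools.espan import (
    CountsTensor,
    OriginAnnotation,
    average_bias_profile,
    bias_matrix,
    count_by_nucleosome,
    filter_fragments,
    fold_leading_lagging,
)
from espantools.io import ORIGIN_POSITIONS


def make_origin(name="o1", chrom="chrI", mid=10_000, spacing=165, half=73):
    intervals = {}
    for k in range(1, 11):
        off = 70 + half + (k - 1) * spacing
        intervals[k] = (mid + off - half, mid + off + half + 1)
        intervals[-k] = (mid - off - half, mid - off + half + 1)
    return OriginAnnotation(name, chrom, mid, intervals)


def naive_count(frags, origins):
    """Independent per-fragment loop used as the counting oracle."""
    origins = sorted(origins, key=lambda o: (o.chrom, o.mid))
    pos_index = {p: i for i, p in enumerate(ORIGIN_POSITIONS)}
    counts = np.zeros((len(origins), 20, 2), dtype=np.int64)
    for row in frags.itertuples(index=False):
        mid = (row.start + row.end) // 2
        for oi, o in enumerate(origins):
            if o.chrom != row.chrom:
                continue
            for idx, (s, e) in o.intervals.items():
                if s <= mid < e:
                    counts[oi, pos_index[idx], 0 if row.strand == "+" else 1] += 1
    return counts


class TestFilterFragments:
    def test_inclusive_bounds(self, fragments_df):
        rows = [("chrI", 0, L, "+", ".") for L in (119, 120, 150, 170, 171)]
        out = filter_fragments(fragments_df(rows), 120, 170)
        assert sorted(out["end"]) == [120, 150, 170]

    def test_mixed_set_brute_force(self, fragments_df):
        rng = np.random.default_rng(3)
        rows = [
            ("chrI", 0, int(L), "+", ".")
            for L in rng.integers(50, 400, size=10)
        ]
        df = fragments_df(rows)
        out = filter_fragments(df, 120, 170)
        expected = [r for r in rows if 120 <= r[2] <= 170]
        assert len(out) == len(expected)
        assert list(out["end"]) == [r[2] for r in expected]


class TestCountByNucleosome:
    def test_single_watson_fragment(self, fragments_df):
        o = make_origin()
        s, e = o.intervals[1]
        mid = (s + e) // 2
        frags = fragments_df([("chrI", mid - 75, mid + 75, "+", ".")])
        t = count_by_nucleosome(frags, [o])
        assert t.counts[0, ORIGIN_POSITIONS.index(1), 0] == 1
        assert t.total() == 1

    def test_midpoint_rule_on_boundary_spanner(self, fragments_df):
        """A fragment spanning the +1/+2 boundary counts only where its
        midpoint lies."""
        o = make_origin()
        s2, _ = o.intervals[2]
        # midpoint just inside +2 though the fragment starts inside +1
        frags = fragments_df([("chrI", s2 - 60, s2 + 62, "+", ".")])
        t = count_by_nucleosome(frags, [o])
        assert t.counts[0, ORIGIN_POSITIONS.index(2), 0] == 1
        assert t.counts[0, ORIGIN_POSITIONS.index(1), 0] == 0

    def test_overlapping_origins_rejected(self, fragments_df):
        o1 = make_origin("a", mid=10_000)
        o2 = make_origin("b", mid=10_400)  # windows collide
        with pytest.raises(ValueError, match="overlap"):
            count_by_nucleosome(fragments_df([]), [o1, o2])

    def test_matches_naive_loop_on_random_fragments(self, fragments_df):
        """Cell-exact agreement with an independent per-fragment oracle."""
        rng = np.random.default_rng(4)
        origins = [make_origin("a", mid=10_000), make_origin("b", mid=20_000),
                   make_origin("c", mid=30_000)]
        rows = []
        for _ in range(100):
            start = int(rng.integers(6000, 34_000))
            length = int(rng.integers(120, 171))
            rows.append(("chrI", start, start + length,
                         "+" if rng.random() < 0.5 else "-", "."))
        frags = fragments_df(rows)
        t = count_by_nucleosome(frags, origins)
        np.testing.assert_array_equal(t.counts, naive_count(frags, origins))


class TestBiasMatrix:
    def _tensor(self, w, c):
        counts = np.zeros((1, 20, 2), dtype=np.int64)
        counts[0, :, 0] = w
        counts[0, :, 1] = c
        return CountsTensor(["o1"], list(ORIGIN_POSITIONS), counts)

    @pytest.mark.parametrize("w,c,pc,expected", [
        (8, 2, 0.0, 2.0),
        (5, 5, 0.0, 0.0),
        (5, 5, 3.0, 0.0),
        (0, 0, 1.0, 0.0),
    ])
    def test_closed_forms(self, w, c, pc, expected):
        mat = bias_matrix(self._tensor(w, c), pc)
        assert mat.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_counts_missing_without_pseudocount(self):
        mat = bias_matrix(self._tensor(0, 0), 0.0)
        assert mat.isna().all().all()
        mat = bias_matrix(self._tensor(3, 0), 0.0)
        assert mat.isna().all().all()

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            bias_matrix(self._tensor(1, 1), -1.0)


class TestAverageProfileAndFolding:
    def test_single_origin_identity(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.standard_normal((1, 20)), index=["o1"],
                           columns=ORIGIN_POSITIONS)
        prof = average_bias_profile(mat)
        np.testing.assert_allclose(prof["mean"], mat.iloc[0].to_numpy())
        assert (prof["n"] == 1).all()

    def test_opposite_values_average_to_zero(self):
        v = np.linspace(-2, 2, 20)
        mat = pd.DataFrame([v, -v], index=["a", "b"], columns=ORIGIN_POSITIONS)
        prof = average_bias_profile(mat)
        np.testing.assert_allclose(prof["mean"], 0.0, atol=1e-12)

    def test_all_missing_position_flagged(self):
        mat = pd.DataFrame(np.ones((3, 20)), columns=ORIGIN_POSITIONS,
                           index=list("abc"))
        mat[4] = np.nan
        prof = average_bias_profile(mat).set_index("position")
        assert prof.loc[4, "n"] == 0
        assert np.isnan(prof.loc[4, "mean"])

    def test_fold_definition(self):
        prof = pd.DataFrame({
            "position": [-1, 1], "mean": [1.0, -1.0],
            "sem": [0.1, 0.1], "n": [10, 10],
        })
        folded = fold_leading_lagging(prof)
        assert len(folded) == 1
        assert folded.loc[0, "mean"] == pytest.approx(1.0)
        assert folded.loc[0, "n"] == 20

    def test_fold_of_symmetric_null(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal(10) * 0.01
        prof = pd.DataFrame({
            "position": ORIGIN_POSITIONS,
            "mean": np.concatenate([vals[::-1], -vals]),
            "sem": 0.1, "n": 10,
        })
        folded = fold_leading_lagging(prof)
        # folded[k] averages prof[-k] and -prof[+k]; both equal vals[k-1]
        np.testing.assert_allclose(folded["mean"], vals, atol=1e-12)


@st.composite
def fragment_tables(draw):
    n = draw(st.integers(min_value=1, max_value=60))
    rows = []
    for _ in range(n):
        start = draw(st.integers(min_value=6000, max_value=24_000))
        length = draw(st.integers(min_value=120, max_value=170))
        strand = draw(st.sampled_from(["+", "-"]))
        rows.append(("chrI", start, start + length, strand, "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "mark"])


class TestAntisymmetryProperty:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(frags=fragment_tables(), pc=st.sampled_from([0.0, 0.5, 1.0]))
    def test_strand_relabeling_negates_bias(self, frags, pc):
        """Swapping every fragment's strand negates every finite bias cell
        exactly and preserves the missing pattern."""
        origins = [make_origin("a", mid=10_000), make_origin("b", mid=20_000)]
        mat = bias_matrix(count_by_nucleosome(frags, origins), pc)
        flipped = frags.assign(
            strand=frags["strand"].map({"+": "-", "-": "+"})
        )
        mat2 = bias_matrix(count_by_nucleosome(flipped, origins), pc)
        a, b = mat.to_numpy(), mat2.to_numpy()
        assert np.array_equal(np.isnan(a), np.isnan(b))
        finite = ~np.isnan(a)
        np.testing.assert_array_equal(a[finite], -b[finite])


class TestCountConservation:
    def test_total_equals_in_window_midpoints(self, fragments_df):
        rng = np.random.default_rng(7)
        origins = [make_origin("a", mid=10_000)]
        rows = []
        for _ in range(500):
            start = int(rng.integers(7000, 13_000))
            rows.append(("chrI", start, start + 150,
                         "+" if rng.random() < 0.5 else "-", "."))
        frags = fragments_df(rows)
        t = count_by_nucleosome(frags, origins)
        mids = (frags["start"] + frags["end"]) // 2
        expected = sum(
            any(s <= m < e for s, e in origins[0].intervals.values())
            for m in mids
        )
        assert t.total() == expected
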