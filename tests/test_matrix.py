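"""Aggregation-matrix model, averaging statistics, witness construction."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from methcompare import (AggregationMatrix, ValidationError,
                         build_matrix_pair, column_profile, summary_stats,
                         witness_matrix)
from conftest import random_masked_matrix


def brute_force_stats(matrix):
    """Independent loop-based recomputation of C, R, M."""
    row_means, col_means, cells = [], [], []
    for i in range(matrix.n):
        obs = [matrix.values[i, j] for j in range(matrix.m)
               if matrix.mask[i, j]]
        if obs:
            row_means.append(sum(obs) / len(obs))
            cells.extend(obs)
    for j in range(matrix.m):
        obs = [matrix.values[i, j] for i in range(matrix.n)
               if matrix.mask[i, j]]
        if obs:
            col_means.append(sum(obs) / len(obs))
    return (sum(col_means) / len(col_means),
            sum(row_means) / len(row_means),
            sum(cells) / len(cells))


class TestAggregationMatrix:
    def test_mask_defaults_to_nan_pattern(self):
        mat = AggregationMatrix([[0.5, np.nan], [np.nan, 1.0]])
        assert mat.mask.tolist() == [[True, False], [False, True]]
        assert mat.n_observed == 2

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValidationError):
            AggregationMatrix([[1.5, 0.0]])

    def test_rejects_empty_shape(self):
        with pytest.raises(ValidationError):
            AggregationMatrix(np.empty((0, 3)))


class TestSummaryStats:
    def test_complete_matrix_collapses_to_single_mean(self):
        st = summary_stats(AggregationMatrix([[1.0, 1.0], [0.0, 0.0]]))
        assert st.C == st.R == st.M == 0.5

    def test_complete_random_matrices_have_equal_statistics(self, rng):
        for _ in range(20):
            mat = random_masked_matrix(rng, density=1.0)
            st = summary_stats(mat)
            assert st.C == pytest.approx(st.R, abs=1e-12)
            assert st.R == pytest.approx(st.M, abs=1e-12)

    def test_fig1_left_matrix_statistics(self, fig1):
        st = summary_stats(fig1.left)
        assert st.C == pytest.approx(1 / 3, abs=1e-12)
        assert st.R == pytest.approx(2 / 3, abs=1e-12)
        assert st.M == pytest.approx(1 / 3, abs=1e-12)
        # sparse rows are the methylated ones: negative count-value link
        assert st.r < 0

    def test_fig1_right_matrix_statistics(self, fig1):
        st = summary_stats(fig1.right)
        assert st.C == pytest.approx(2 / 3, abs=1e-12)
        assert st.R == pytest.approx(2 / 3, abs=1e-12)

    def test_matches_brute_force_on_random_masked_matrices(self, rng):
        for _ in range(200):
            mat = random_masked_matrix(rng)
            st = summary_stats(mat)
            C, R, M = brute_force_stats(mat)
            assert st.C == pytest.approx(C, abs=1e-12)
            assert st.R == pytest.approx(R, abs=1e-12)
            assert st.M == pytest.approx(M, abs=1e-12)

    def test_row_permutation_invariance(self, rng):
        mat = random_masked_matrix(rng, n=8, m=6)
        perm = rng.permutation(8)
        permuted = AggregationMatrix(mat.values[perm], mat.mask[perm])
        a, b = summary_stats(mat), summary_stats(permuted)
        assert a.C == pytest.approx(b.C, abs=1e-12)
        assert a.R == pytest.approx(b.R, abs=1e-12)
        assert a.M == pytest.approx(b.M, abs=1e-12)

    def test_column_permutation_preserves_C_and_M(self, rng):
        mat = random_masked_matrix(rng, n=8, m=6)
        perm = rng.permutation(6)
        permuted = AggregationMatrix(mat.values[:, perm],
                                     mat.mask[:, perm])
        a, b = summary_stats(mat), summary_stats(permuted)
        assert a.C == pytest.approx(b.C, abs=1e-12)
        assert a.M == pytest.approx(b.M, abs=1e-12)
        assert a.R == pytest.approx(b.R, abs=1e-12)

    def test_pearson_uses_row_site_counts(self):
        # 3 rows: counts 1, 2, 3 with means 1.0, 0.5, 0.0 -> r = -1
        vals = np.array([[1.0, np.nan, np.nan],
                         [0.5, 0.5, np.nan],
                         [0.0, 0.0, 0.0]])
        st = summary_stats(AggregationMatrix(vals))
        assert st.r == pytest.approx(-1.0)

    def test_all_missing_matrix_errors(self):
        mat = AggregationMatrix(np.full((2, 2), np.nan))
        with pytest.raises(ValidationError, match="no observed data"):
            summary_stats(mat)


class TestColumnProfile:
    def test_hand_example(self):
        mat = AggregationMatrix(np.array([[1.0], [0.0], [np.nan]]))
        prof = column_profile(mat)
        assert prof.loc[0, "average"] == 0.5
        assert prof.loc[0, "count"] == 2

    def test_min_obs_marks_sparse_columns_undefined(self, rng):
        mat = random_masked_matrix(rng, n=5, m=3, density=0.9)
        prof = column_profile(mat, min_obs=10)
        assert prof["average"].isna().all()
        assert (prof["count"] <= 5).all()

    def test_profile_mean_equals_C(self, rng):
        for _ in range(10):
            mat = random_masked_matrix(rng)
            prof = column_profile(mat, min_obs=1)
            defined = prof.dropna(subset=["average"])
            assert defined["average"].mean() == pytest.approx(
                summary_stats(mat).C, abs=1e-12)

    def test_binning_pools_observations(self):
        mat = AggregationMatrix(np.array([[1.0, 0.0, 1.0, np.nan]]))
        prof = column_profile(mat, bin_width=2)
        assert list(prof["position"]) == [0, 2]
        assert prof.loc[0, "average"] == 0.5
        assert prof.loc[1, "count"] == 1


class TestBuildMatrixPair:
    @staticmethod
    def calls_df(rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                           "rate", "coverage"])

    @staticmethod
    def bounds_df(rows):
        return pd.DataFrame(rows, columns=[
            "chrom", "boundary_pos", "strand", "upstream_span",
            "downstream_span", "label"])

    def test_right_side_placement_by_distance(self):
        calls = self.calls_df([("chr1", 100, "+", 1.0, 5),
                               ("chr1", 103, "+", 0.0, 5)])
        bounds = self.bounds_df([("chr1", 100, "+", 5, 5, "j1")])
        pair = build_matrix_pair(calls, bounds)
        row = pair.right.values[0]
        assert row[0] == 1.0 and row[3] == 0.0
        assert np.isnan(row[1]) and np.isnan(row[2]) and np.isnan(row[4])

    def test_minus_strand_mirrors_placement(self):
        # on the minus strand the downstream side runs to genomic left
        calls = self.calls_df([("chr1", 99, "+", 1.0, 5),
                               ("chr1", 96, "+", 0.0, 5)])
        bounds = self.bounds_df([("chr1", 100, "-", 5, 5, "j1")])
        pair = build_matrix_pair(calls, bounds)
        row = pair.right.values[0]
        assert row[0] == 1.0 and row[3] == 0.0

    def test_boundary_off_call_index_gives_all_missing_row(self):
        calls = self.calls_df([("chr1", 100, "+", 1.0, 5)])
        bounds = self.bounds_df([("chr2", 100, "+", 4, 4, "j1")])
        pair = build_matrix_pair(calls, bounds)
        assert not pair.left.mask.any() and not pair.right.mask.any()
        assert pair.build_report["rows_all_missing_left"] == 1

    def test_duplicate_positions_rejected(self):
        calls = self.calls_df([("chr1", 100, "+", 1.0, 5),
                               ("chr1", 100, "-", 0.0, 5)])
        bounds = self.bounds_df([("chr1", 100, "+", 4, 4, "j1")])
        with pytest.raises(ValidationError, match="duplicate"):
            build_matrix_pair(calls, bounds)

    def test_matches_naive_per_boundary_scan(self, rng):
        # 50 random boundaries vs an independent linear scan
        positions = rng.choice(5000, size=800, replace=False)
        rates = rng.random(800)
        calls = self.calls_df([("chrA", int(p), "+", float(r), 5)
                               for p, r in zip(positions, rates)])
        lookup = dict(zip(positions.tolist(), rates.tolist()))
        bounds = self.bounds_df([
            ("chrA", int(b), "+" if rng.random() < 0.5 else "-", 6, 6,
             f"j{i}")
            for i, b in enumerate(rng.integers(10, 4990, size=50))])
        pair = build_matrix_pair(calls, bounds)
        for i, row in enumerate(bounds.itertuples(index=False)):
            b = row.boundary_pos
            for j in range(6):
                if row.strand == "+":
                    up, down = b - 1 - j, b + j
                else:
                    up, down = b + j, b - 1 - j
                for mat, pos in ((pair.left, up), (pair.right, down)):
                    if pos in lookup:
                        assert mat.values[i, j] == lookup[pos]
                    else:
                        assert not mat.mask[i, j]


class TestWitnessMatrix:
    def test_realizes_fig1_left_statistics(self):
        mat = witness_matrix(Fraction(2, 3), Fraction(1, 3),
                             Fraction(1, 3))
        st = summary_stats(mat)
        assert abs(st.R - 2 / 3) <= 1e-9
        assert abs(st.C - 1 / 3) <= 1e-9
        assert abs(st.M - 1 / 3) <= 1e-9

    def test_equal_triple_yields_valid_matrix(self):
        st = summary_stats(witness_matrix(0.5, 0.5, 0.5))
        assert st.C == st.R == st.M == pytest.approx(0.5, abs=1e-12)

    def test_random_rational_triples_realized_exactly(self):
        import random
        rnd = random.Random(7)
        for _ in range(100):
            r = Fraction(rnd.randint(6, 94), 100)
            c = Fraction(rnd.randint(1, 96), 97)
            m = Fraction(rnd.randint(1, 88), 89)
            st = summary_stats(witness_matrix(r, c, m))
            assert abs(st.R - float(r)) <= 1e-9
            assert abs(st.C - float(c)) <= 1e-9
            assert abs(st.M - float(m)) <= 1e-9

    def test_accepts_tuples_and_floats(self):
        st = summary_stats(witness_matrix((3, 4), 0.25, (1, 2)))
        assert st.R == pytest.approx(0.75, abs=1e-9)
        assert st.C == pytest.approx(0.25, abs=1e-9)
        assert st.M == pytest.approx(0.5, abs=1e-9)

    def test_rejects_degenerate_targets(self):
        with pytest.raises(ValidationError):
            witness_matrix(Fraction(1), Fraction(1, 2), Fraction(1, 2))

    def test_size_cap_raises_informatively(self):
        with pytest.raises(ValidationError, match="larger cap"):
            witness_matrix(Fraction(1, 2), Fraction(1, 3), Fraction(1, 5),
                           max_size=2)


class TestSimpsonParadox:
    def test_sign_reversal_between_row_and_column_comparison(self):
        from methcompare.simulate import simpson_reversal_pair
        w1, w2 = simpson_reversal_pair()
        s1, s2 = summary_stats(w1), summary_stats(w2)
        assert s1.R > s2.R
        assert s1.C < s2.C
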