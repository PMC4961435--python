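import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betadismantle import (
    CommunityMatrix,
    DomainError,
    ModeError,
    PairComposition,
    UndefinedPairError,
    beta_partition_matrix,
    beta_partition_pair,
    bray_curtis_matrix,
    haversine_matrix,
    pair_composition,
    scalar_distance_matrix,
    SiteAttributes,
)
import pandas as pd


class TestPairComposition:
    def test_counting_example(self):
        assert pair_composition([1, 1, 0, 1], [1, 0, 1, 1]) == (2, 1, 1)

    def test_identical_rows(self):
        assert pair_composition([1, 0, 1], [1, 0, 1]) == (2, 0, 0)

    def test_non_binary_rejected(self):
        with pytest.raises(ModeError):
            pair_composition([1, 2], [0, 1])

    def test_matches_set_operation_oracle(self, rng):
        for _ in range(50):
            x = (rng.random(50) < 0.4).astype(float)
            y = (rng.random(50) < 0.4).astype(float)
            sx = {i for i, v in enumerate(x) if v}
            sy = {i for i, v in enumerate(y) if v}
            assert pair_composition(x, y) == (
                len(sx & sy), len(sx - sy), len(sy - sx)
            )


class TestBetaPartitionPair:
    @pytest.mark.parametrize(
        "abc, expected",
        [
            ((2, 1, 1), (0.5, 0.0, 0.5)),
            ((5, 0, 0), (0.0, 0.0, 0.0)),  # perfect similarity
            ((0, 3, 3), (1.0, 0.0, 1.0)),  # complete replacement
            ((1, 2, 0), (2 / 3, 2 / 3, 0.0)),  # nested / pure richness diff
        ],
    )
    def test_formula_oracle(self, abc, expected):
        got = beta_partition_pair(PairComposition(*abc))
        np.testing.assert_allclose(got, expected, atol=1e-15)

    def test_both_empty_is_undefined(self):
        with pytest.raises(UndefinedPairError):
            beta_partition_pair(PairComposition(0, 0, 0))

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        a=st.integers(0, 50), b=st.integers(0, 50), c=st.integers(0, 50)
    )
    def test_additivity_and_bounds(self, a, b, c):
        if a + b + c == 0:
            return
        cc, rich, rep = beta_partition_pair(PairComposition(a, b, c))
        assert abs(cc - (rich + rep)) <= 1e-12
        for v in (cc, rich, rep):
            assert 0.0 <= v <= 1.0
        if min(b, c) == 0:
            assert rep == 0.0
        if b == c:
            assert rich == 0.0


class TestBetaPartitionMatrix:
    def test_identical_sites_give_zero(self):
        cm = CommunityMatrix(["A", "B"], ["x", "y", "z"], [[1, 1, 0], [1, 1, 0]])
        part = beta_partition_matrix(cm)
        for m in (part.beta_cc, part.beta_rich, part.beta_3):
            np.testing.assert_array_equal(m.d, 0.0)

    def test_two_site_formula_example(self):
        cm = CommunityMatrix(["A", "B"], ["x", "y", "z"], [[1, 1, 0], [0, 1, 1]])
        part = beta_partition_matrix(cm)
        assert part.beta_cc.d[0, 1] == pytest.approx(2 / 3)
        assert part.beta_rich.d[0, 1] == 0.0
        assert part.beta_3.d[0, 1] == pytest.approx(2 / 3)

    def test_matches_pairwise_loop(self, random_incidence):
        cm = random_incidence(10, 30)
        part = beta_partition_matrix(cm)
        for i in range(cm.n_sites):
            for j in range(i + 1, cm.n_sites):
                pc = pair_composition(cm.values[i], cm.values[j])
                cc, rich, rep = beta_partition_pair(pc)
                assert part.beta_cc.d[i, j] == cc
                assert part.beta_rich.d[i, j] == rich
                assert part.beta_3.d[i, j] == rep

    def test_empty_pair_names_sites(self):
        cm = CommunityMatrix(["A", "B", "C"], ["x"], [[1], [0], [0]])
        with pytest.raises(UndefinedPairError, match="'B'.*'C'"):
            beta_partition_matrix(cm)

    def test_mean_summaries(self, random_incidence):
        cm = random_incidence(8, 25)
        part = beta_partition_matrix(cm)
        iu = np.triu_indices(8, 1)
        assert part.mean_beta_rich == pytest.approx(part.beta_rich.d[iu].mean())
        assert part.mean_beta_3 == pytest.approx(part.beta_3.d[iu].mean())

    def test_external_cross_check_frozen(self):
        # 8x12 incidence table with partition values computed by an
        # independent R implementation (vegan designdist), frozen here.
        X = np.array(
            [
                [0, 1, 1, 0, 0, 1, 1, 1, 0, 0, 1, 0],
                [0, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0, 1],
                [1, 1, 1, 0, 0, 0, 1, 1, 1, 1, 1, 1],
                [1, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1],
                [0, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0],
                [1, 0, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1],
                [1, 1, 0, 0, 1, 1, 1, 0, 0, 1, 1, 0],
                [1, 1, 1, 1, 0, 1, 1, 0, 1, 0, 1, 0],
            ],
            dtype=float,
        )
        cm = CommunityMatrix(
            [f"s{i}" for i in range(8)], [f"sp{j}" for j in range(12)], X
        )
        part = beta_partition_matrix(cm)
        # pairs (2,1), (3,1), (4,1) in 1-based site order
        np.testing.assert_allclose(
            [part.beta_cc.d[1, 0], part.beta_cc.d[2, 0], part.beta_cc.d[3, 0]],
            [0.6666666667, 0.5, 0.5555555556],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            [part.beta_rich.d[1, 0], part.beta_rich.d[2, 0], part.beta_rich.d[3, 0]],
            [0.0, 0.3, 0.1111111111],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            [part.beta_3.d[1, 0], part.beta_3.d[2, 0], part.beta_3.d[3, 0]],
            [0.6666666667, 0.2, 0.4444444444],
            atol=1e-9,
        )


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        cm = CommunityMatrix(["A", "B"], list("xyz"), [[1, 2, 3], [1, 2, 3]],
                             mode="abundance")
        assert bray_curtis_matrix(cm).d[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        cm = CommunityMatrix(["A", "B"], list("xyz"), [[0, 0, 5], [5, 0, 0]],
                             mode="abundance")
        assert bray_curtis_matrix(cm).d[0, 1] == 1.0

    def test_hand_value(self):
        cm = CommunityMatrix(["A", "B"], list("xy"), [[2, 0], [1, 1]],
                             mode="abundance")
        assert bray_curtis_matrix(cm).d[0, 1] == pytest.approx(0.5)

    def test_matches_double_loop(self, rng):
        vals = rng.random((6, 5)) * 10
        cm = CommunityMatrix([f"s{i}" for i in range(6)],
                             [f"f{j}" for j in range(5)], vals, mode="abundance")
        d = bray_curtis_matrix(cm).d
        for i in range(6):
            for j in range(6):
                expect = np.abs(vals[i] - vals[j]).sum() / (vals[i] + vals[j]).sum()
                assert d[i, j] == pytest.approx(expect)

    def test_all_zero_pair_undefined(self):
        cm = CommunityMatrix(["A", "B", "C"], list("xy"),
                             [[0, 0], [0, 0], [1, 2]], mode="abundance")
        with pytest.raises(UndefinedPairError):
            bray_curtis_matrix(cm)


class TestScalarDistance:
    def test_constant_values_zero_matrix(self):
        dm = scalar_distance_matrix([10, 10, 10], ["a", "b", "c"])
        np.testing.assert_array_equal(dm.d, 0.0)

    def test_log_closed_form(self):
        dm = scalar_distance_matrix([1.0, math.e], ["a", "b"], transform="log")
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_log_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            scalar_distance_matrix([1.0, 0.0], ["a", "b"], transform="log")

    def test_matches_double_loop(self, rng):
        v = rng.random(8) + 0.1
        dm = scalar_distance_matrix(v, [f"s{i}" for i in range(8)], transform="log")
        for i in range(8):
            for j in range(8):
                assert dm.d[i, j] == pytest.approx(abs(math.log(v[i]) - math.log(v[j])))


class TestHaversine:
    def _attrs(self, lon, lat):
        n = len(lon)
        return SiteAttributes(pd.DataFrame({
            "site_id": [f"s{i}" for i in range(n)], "lon": lon, "lat": lat,
            "temp": [10.0] * n, "rain": [800.0] * n,
            "forest_area": [1.0] * n, "import_value": [1.0] * n,
        }))

    def test_identical_points_zero(self):
        dm = haversine_matrix(self._attrs([10.0, 10.0], [45.0, 45.0]))
        assert dm.d[0, 1] == 0.0

    def test_semicircumference(self):
        dm = haversine_matrix(self._attrs([0.0, 180.0], [0.0, 0.0]))
        assert dm.d[0, 1] == pytest.approx(math.pi * 6371.0, rel=1e-9)

    def test_quarter_circumference(self):
        dm = haversine_matrix(self._attrs([0.0, 0.0], [0.0, 90.0]))
        assert dm.d[0, 1] == pytest.approx(math.pi * 6371.0 / 2.0, rel=1e-9)
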