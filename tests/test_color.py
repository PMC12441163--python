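"""CIELab arithmetic, classification, and the ANOVA/Tukey group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibermap as fm

finite_lab = st.tuples(
    st.floats(0, 100), st.floats(-60, 60), st.floats(-60, 60)
)


class TestDeltaE:
    @pytest.mark.parametrize(
        "c1, c2, expected",
        [
            ((96.49, 0.64, 10.25), (67.75, 11.58, 30.33), 36.73),  # parental lines
            ((5.0, 3.0, -2.0), (5.0, 3.0, -2.0), 0.0),
            ((10, 0, 0), (13, 4, 0), 5.0),  # 3-4-5 triangle
        ],
    )
    def test_values(self, c1, c2, expected):
        assert fm.delta_e(c1, c2) == pytest.approx(expected, abs=0.01)

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            fm.delta_e((np.nan, 0, 0), (1, 2, 3))

    def test_triangle_inequality_bulk(self, rng):
        """ΔE is a metric: triangle inequality over 10,000 random triples."""
        a, b, c = rng.uniform(-100, 100, size=(3, 10_000, 3))
        dab = np.linalg.norm(a - b, axis=1)
        dbc = np.linalg.norm(b - c, axis=1)
        dac = np.linalg.norm(a - c, axis=1)
        assert np.all(dac <= dab + dbc + 1e-9)
        # spot-check agreement with the scalar implementation
        for i in range(0, 10_000, 997):
            assert fm.delta_e(a[i], c[i]) == pytest.approx(dac[i])

    @settings(derandomize=True, max_examples=200)
    @given(c1=finite_lab, c2=finite_lab)
    def test_symmetry_and_nonnegativity(self, c1, c2):
        d = fm.delta_e(c1, c2)
        assert d >= 0
        assert d == pytest.approx(fm.delta_e(c2, c1))


class TestAverageReplicates:
    def test_mean_of_replicates(self):
        df = pd.DataFrame(
            {
                "id": ["s1"] * 3,
                "replicate": [1, 2, 3],
                "L": [0.0, 2.0, 4.0],
                "a": [0.0, 2.0, 4.0],
                "b": [0.0, 2.0, 4.0],
            }
        )
        out = fm.average_replicates(df)
        assert out.loc[0, ["L", "a", "b"]].tolist() == [2.0, 2.0, 2.0]

    def test_single_replicate_is_itself(self):
        df = pd.DataFrame({"id": ["x"], "L": [50.0], "a": [1.0], "b": [2.0]})
        out = fm.average_replicates(df)
        assert out.loc[0, ["L", "a", "b"]].tolist() == [50.0, 1.0, 2.0]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fm.average_replicates(
                pd.DataFrame(columns=["id", "L", "a", "b"])
            )


class TestClassifyColors:
    BROWN = fm.BROWN_PARENT_LAB
    WHITE = fm.WHITE_PARENT_LAB

    def _frame(self, labs):
        return pd.DataFrame(
            [{"id": f"s{i}", "L": L, "a": a, "b": b} for i, (L, a, b) in enumerate(labs)]
        )

    def test_reference_colors_classify_to_themselves(self):
        out = fm.classify_colors(self._frame([self.BROWN, self.WHITE]), self.BROWN, self.WHITE)
        assert out.tolist() == ["brown", "white"]

    def test_midpoint_is_cream_for_any_band(self):
        mid = tuple((x + y) / 2 for x, y in zip(self.BROWN, self.WHITE))
        for band in (0.5, 2.0, 5.0):
            out = fm.classify_colors(self._frame([mid]), self.BROWN, self.WHITE, cream_band=band)
            assert out.tolist() == ["cream"]

    def test_order_invariance(self, rng):
        labs = [tuple(x) for x in rng.uniform(0, 100, size=(40, 3))]
        f = self._frame(labs)
        out = fm.classify_colors(f, self.BROWN, self.WHITE)
        shuffled = f.sample(frac=1, random_state=1)
        out2 = fm.classify_colors(shuffled, self.BROWN, self.WHITE)
        assert (out.loc[out2.index] == out2).all()

    def test_too_close_references_rejected(self):
        with pytest.raises(ValueError, match="closer"):
            fm.classify_colors(self._frame([self.BROWN]), self.BROWN, self.BROWN, cream_band=5)


class TestCompareGroups:
    def test_huge_effect_flags_third_group(self, rng):
        values = np.concatenate(
            [rng.normal(0, 0.1, 20), rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)]
        )
        labels = np.repeat(["g1", "g2", "g3"], 20)
        cmp = fm.compare_groups(values, labels)
        assert cmp.p_value < 1e-6
        pw = cmp.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        assert pw[("g1", "g3")] < 1e-3 and pw[("g2", "g3")] < 1e-3
        assert pw[("g1", "g2")] > 0.5

    def test_identical_groups_pairwise_p_near_one(self, rng):
        base = np.zeros(15) + rng.normal(0, 1e-3, 15)
        values = np.concatenate([base, base, base + 5])
        labels = np.repeat(["a", "b", "c"], 15)
        cmp = fm.compare_groups(values, labels)
        pw = cmp.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        assert pw[("a", "b")] > 0.95

    def test_anova_p_matches_permutation_test(self, rng):
        """Overall p agrees with a brute-force permutation of the F statistic."""
        values = np.concatenate(
            [rng.normal(0, 1, 6), rng.normal(0.8, 1, 6), rng.normal(0.2, 1, 6)]
        )
        labels = np.repeat(["a", "b", "c"], 6)
        cmp = fm.compare_groups(values, labels)

        def f_stat(v):
            grand = v.mean()
            groups = [v[i * 6 : (i + 1) * 6] for i in range(3)]
            ssb = sum(6 * (g.mean() - grand) ** 2 for g in groups) / 2
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups) / 15
            return ssb / ssw

        observed = f_stat(values)
        n_perm, hits = 5000, 0
        v = values.copy()
        for _ in range(n_perm):
            rng.shuffle(v)
            hits += f_stat(v) >= observed
        p_perm = hits / n_perm
        assert cmp.p_value == pytest.approx(p_perm, abs=0.04)

    def test_requires_two_values_per_group(self):
        with pytest.raises(ValueError):
            fm.compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])
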