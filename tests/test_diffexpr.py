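import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from keystonekit import diffexpr as de
from keystonekit import synthetic_data as sd
from keystonekit.io_formats import ExpressionMatrix


def _bh_oracle(p):
    """Independent BH step-up: sort, scale by m/rank, cumulative min from
    the bottom, cap at 1, restore input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestZscoreNormalize:
    def test_hand_computed_column(self):
        m = ExpressionMatrix(
            ["G1", "G2", "G3"], ["s1", "s2"],
            np.array([[10.0, 7.0], [100.0, 8.0], [1000.0, 9.0]]),
            {"s1": "A", "s2": "B"},
        )
        z = de.zscore_normalize(m, log_base=10)
        # log10 -> [1,2,3]; population sd sqrt(2/3)
        np.testing.assert_allclose(
            z.zscores[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_multiplicative_shift_invariance(self, tiny_matrix):
        z1 = de.zscore_normalize(tiny_matrix)
        shifted = ExpressionMatrix(
            tiny_matrix.gene_ids, tiny_matrix.sample_ids,
            tiny_matrix.values * 37.0, tiny_matrix.groups,
        )
        z2 = de.zscore_normalize(shifted)
        np.testing.assert_allclose(z1.zscores, z2.zscores, atol=1e-9)

    def test_columns_standardised(self):
        m, _ = sd.gen_expression(n_genes=200, n_de=10, seed=1)
        z = de.zscore_normalize(m)
        np.testing.assert_allclose(z.zscores.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.zscores.std(axis=0), 1, atol=1e-9)

    def test_zero_variance_sample_named(self):
        m = ExpressionMatrix(
            ["G1", "G2"], ["s1", "s2"],
            np.array([[5.0, 1.0], [5.0, 2.0]]),
            {"s1": "A", "s2": "B"},
        )
        with pytest.raises(ValueError, match="s1"):
            de.zscore_normalize(m)


class TestZRatio:
    def _zmat(self, d):
        """Build a ZScoreMatrix whose group-A minus group-B difference is d."""
        d = np.asarray(d, float)
        z = np.column_stack([d / 2, d / 2, -d / 2, -d / 2])
        return de.ZScoreMatrix(
            [f"G{i}" for i in range(len(d))], ["a1", "a2", "b1", "b2"], z,
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )

    def test_four_gene_spreadsheet_oracle(self):
        zr = de.z_ratio(self._zmat([2.0, 1.0, -1.0, -2.0]), "A", "B")
        # sample sd of [2,1,-1,-2] = sqrt(10/3)
        expected = np.array([2, 1, -1, -2]) / np.sqrt(10 / 3)
        np.testing.assert_allclose(
            [zr[f"G{i}"] for i in range(4)], expected, atol=1e-4
        )

    def test_zero_difference_is_zero(self):
        zr = de.z_ratio(self._zmat([0.0, 3.0, -1.0]), "A", "B")
        assert zr["G0"] == 0.0

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(2)
        zm = self._zmat(rng.normal(size=50))
        ab = de.z_ratio(zm, "A", "B")
        ba = de.z_ratio(zm, "B", "A")
        for g in ab:
            assert ab[g] == pytest.approx(-ba[g], abs=1e-12)

    def test_degenerate_identical_groups(self):
        with pytest.raises(ValueError, match="no dispersion"):
            de.z_ratio(self._zmat([0.0, 0.0, 0.0]), "A", "B")


class TestBhFdr:
    def test_hand_step_up(self):
        assert de.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity_and_cap(self):
        assert de.bh_fdr([0.2]) == [pytest.approx(0.2)]
        assert de.bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(de.bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_qvalues_dominate_p_and_match_oracle(self, p):
        q = de.bh_fdr(p)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, p))
        np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)


class TestAnovaGate:
    def test_two_group_matches_t_test(self):
        m, _ = sd.gen_expression(n_genes=50, n_de=10, seed=3)
        p = de.anova_gate(m)
        logged = np.log10(m.values)
        ia = [i for i, s in enumerate(m.sample_ids) if m.groups[s] == "WT"]
        ib = [i for i, s in enumerate(m.sample_ids) if m.groups[s] == "KO"]
        for gi, g in enumerate(m.gene_ids):
            t = stats.ttest_ind(logged[gi, ia], logged[gi, ib], equal_var=True)
            assert p[g] == pytest.approx(t.pvalue, rel=1e-9)

    def test_equal_means_with_noise_gives_high_p(self):
        values = 10.0 ** np.array([[1.0, 1.2, 0.8, 1.0, 1.2, 0.8]])
        m = ExpressionMatrix(
            ["G1"], [f"s{i}" for i in range(6)], values,
            {f"s{i}": ("A" if i < 3 else "B") for i in range(6)},
        )
        assert de.anova_gate(m)["G1"] > 0.99

    def test_planted_effects_have_lower_p_than_nulls(self):
        m, t = sd.gen_expression(n_genes=400, n_de=40, seed=5)
        p = de.anova_gate(m)
        planted = [p[g] for g in t.planted_de_genes]
        nulls = [p[g] for g in m.gene_ids if g not in t.planted_de_genes]
        assert np.median(planted) < np.median(nulls)


class TestCallDifferential:
    def test_thresholds_inclusive_z_strict_q_p(self):
        recs = de.call_differential(
            {"a": 1.50, "b": 3.0, "c": 1.49},
            {"a": 0.049, "b": 0.05, "c": 0.001},
            {"a": 0.049, "b": 0.01, "c": 0.001},
        )
        by_id = {r.gene_id: r for r in recs}
        assert by_id["a"].significant  # z exactly at the inclusive cut
        assert not by_id["b"].significant  # q must be strictly < 0.05
        assert not by_id["c"].significant  # |z| below cut
        assert [r.gene_id for r in recs] == ["b", "a", "c"]  # |z| descending

    def test_missing_gene_named(self):
        with pytest.raises(ValueError, match="b"):
            de.call_differential({"a": 2.0, "b": 2.0}, {"a": 0.01}, {"a": 0.01, "b": 0.01})


class TestIntensityFloor:
    def test_filter_drops_dim_probes_only(self, tiny_matrix):
        floor = float(tiny_matrix.values.mean(axis=1)[1])
        filtered = de.filter_low_intensity(tiny_matrix, floor)
        assert set(filtered.gene_ids) == {
            g for g, m in zip(tiny_matrix.gene_ids, tiny_matrix.values.mean(axis=1))
            if m >= floor
        }

    def test_everything_filtered_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="floor"):
            de.filter_low_intensity(tiny_matrix, 1e12)


class TestFullChain:
    def test_planted_recovery_at_n3(self):
        """Planted 4-residual-sd fold-changes at n = 3/group: the
        z-ratio -> FDR -> ANOVA chain recovers >=80% with <=5% false calls."""
        m, t = sd.gen_expression(
            n_genes=4000, n_de=60, lfc_min=1.0, lfc_sd=0.0, seed=1
        )
        recs = de.differential_expression(m, "KO", "WT")
        sig = {r.gene_id for r in recs if r.significant}
        planted = set(t.planted_de_genes)
        sensitivity = len(sig & planted) / len(planted)
        false_rate = len(sig - planted) / (4000 - 60)
        assert sensitivity >= 0.80
        assert false_rate <= 0.05

    def test_null_matrix_calls_almost_nothing(self):
        m, _ = sd.gen_expression(n_genes=1000, n_de=0, seed=3)
        recs = de.differential_expression(m, "KO", "WT")
        assert sum(r.significant for r in recs) / 1000 <= 0.01
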