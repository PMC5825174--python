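import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from nemacge import (
    ArgumentError,
    DataError,
    ExpressionMatrix,
    bias_simulation,
    cge_matrix,
    contingency,
    similarity,
)
from nemacge.cge import (
    MASK_BILATERAL,
    MASK_SELF,
    MASK_UNDEFINED,
    load_expression,
    pairwise_counts,
)


class TestContingency:
    def test_hand_count(self):
        c = contingency([1, 0, 1, 0, 0], [1, 0, 0, 1, 0])
        assert (c.n11, c.n10, c.n01, c.n00) == (1, 1, 1, 2)
        assert c.L == 5

    def test_all_zero(self):
        c = contingency([0, 0, 0], [0, 0, 0])
        assert (c.n11, c.n10, c.n01, c.n00) == (0, 0, 0, 3)

    def test_length_mismatch(self):
        with pytest.raises(ArgumentError):
            contingency([1], [1, 0])

    def test_non_binary_rejected(self):
        with pytest.raises(DataError):
            contingency([1, 2], [0, 1])


class TestSimilarity:
    def test_identical_vectors_phi_one(self):
        c = contingency([1, 0, 1], [1, 0, 1])
        assert similarity(c, "r_phi") == pytest.approx(1.0)

    def test_fully_mismatched_phi_minus_one(self):
        c = contingency([1, 1, 0, 0], [0, 0, 1, 1])
        assert similarity(c, "r_phi") == pytest.approx(-1.0)

    def test_substitution_into_formulas(self):
        c = contingency([1, 0, 1, 0, 0], [1, 0, 0, 1, 0])  # (1,1,1,2)
        assert similarity(c, "r_phi") == pytest.approx(1 / 6)
        assert similarity(c, "yule_q") == pytest.approx(1 / 3)
        assert similarity(c, "jaccard") == pytest.approx(1 / 3)

    def test_zero_marginal_phi_undefined_not_zero(self):
        c = contingency([0, 0, 0], [1, 0, 1])
        assert np.isnan(similarity(c, "r_phi"))

    def test_p_match_exhaustive_enumeration(self):
        # L=4, both vectors two 1s, full overlap: tail = C(2,2)C(2,0)/C(4,2)
        c = contingency([1, 1, 0, 0], [1, 1, 0, 0])
        tail = 1.0 - similarity(c, "p_match")
        assert tail == pytest.approx(1 / comb(4, 2))

    @pytest.mark.parametrize("method", ["r_phi", "jaccard", "yule_q", "p_match"])
    def test_symmetry(self, method):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 2, 20)
            y = rng.integers(0, 2, 20)
            a = similarity(contingency(x, y), method)
            b = similarity(contingency(y, x), method)
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_phi_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = rng.integers(0, 2, 15)
            y = rng.integers(0, 2, 15)
            v = similarity(contingency(x, y), "r_phi")
            assert np.isnan(v) or -1.0 <= v <= 1.0


class TestContingencyProperties:
    """Invariants over arbitrary binary vector pairs."""

    @given(
        st.integers(min_value=1, max_value=40).flatmap(
            lambda L: st.tuples(
                st.lists(st.integers(0, 1), min_size=L, max_size=L),
                st.lists(st.integers(0, 1), min_size=L, max_size=L),
            )
        )
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_counts_partition_and_marginals(self, xy):
        x, y = xy
        c = contingency(x, y)
        assert c.n11 + c.n10 + c.n01 + c.n00 == len(x)
        assert c.n1x == sum(x) and c.nx1 == sum(y)
        assert min(c.n11, c.n10, c.n01, c.n00) >= 0

    @given(
        st.integers(min_value=2, max_value=40).flatmap(
            lambda L: st.tuples(
                st.lists(st.integers(0, 1), min_size=L, max_size=L),
                st.lists(st.integers(0, 1), min_size=L, max_size=L),
            )
        )
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_similarity_ranges_and_symmetry(self, xy):
        x, y = xy
        fwd, rev = contingency(x, y), contingency(y, x)
        for method, lo, hi in (("r_phi", -1, 1), ("jaccard", 0, 1),
                               ("yule_q", -1, 1), ("p_match", 0, 1)):
            a = similarity(fwd, method)
            b = similarity(rev, method)
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert lo - 1e-12 <= a <= hi + 1e-12
                assert a == pytest.approx(b)


class TestMatrix:
    def test_vectorized_counts_match_elementwise(self):
        rng = np.random.default_rng(2)
        X = (rng.random((10, 30)) < 0.3).astype(np.uint8)
        n11, n10, n01, n00 = pairwise_counts(X)
        for i in range(10):
            for j in range(10):
                c = contingency(X[i], X[j])
                assert (n11[i, j], n10[i, j], n01[i, j], n00[i, j]) == (
                    c.n11, c.n10, c.n01, c.n00)

    def test_masking_counts(self):
        e = ExpressionMatrix(["A", "B", "C"], ["g1", "g2", "g3"],
                             [[1, 0, 1], [1, 0, 0], [0, 1, 1]])
        m = cge_matrix(e, bilateral_pairs=[("A", "B")])
        assert m.mask_reason[0, 1] == MASK_BILATERAL
        assert np.isnan(m.values[0, 1])
        assert (np.diag(m.mask_reason) == MASK_SELF).all()
        # exactly 1 masked pair, 2 scored pairs
        iu, ju = np.triu_indices(3, 1)
        assert np.isnan(m.values[iu, ju]).sum() == 1

    def test_all_zero_neuron_flagged_undefined(self):
        e = ExpressionMatrix(["A", "B"], ["g1", "g2"], [[0, 0], [1, 0]])
        m = cge_matrix(e)
        assert np.isnan(m.values[0, 1])
        assert m.mask_reason[0, 1] == MASK_UNDEFINED

    def test_symmetric(self, small_ds):
        m = cge_matrix(small_ds.expression, bilateral_pairs=small_ds.bilateral_pairs)
        v = m.values
        assert np.allclose(v, v.T, equal_nan=True)

    def test_bilateral_homologs_highly_similar(self, planted_ds):
        """Bilateral pair profiles are near-copies: their phi (inspected
        unmasked) is high for every pair."""
        m = cge_matrix(planted_ds.expression,
                       bilateral_pairs=planted_ds.bilateral_pairs,
                       mask_bilateral=False)
        idx = {n: i for i, n in enumerate(m.neurons)}
        vals = [m.values[idx[a], idx[b]] for a, b in planted_ds.bilateral_pairs]
        assert np.nanmin(vals) > 0.6
        assert np.nanmedian(vals) > 0.8


class TestLoader:
    def test_long_format_roundtrip(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("neuron\tgene\nA\tg2\nB\tg1\nA\tg1\n")
        e = load_expression(p, ["A", "B", "C"])
        assert e.genes == ["g1", "g2"]
        assert e.values[0].tolist() == [1, 1]
        assert e.values[2].tolist() == [0, 0]

    def test_uncertain_annotations_dropped(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("neuron\tgene\tevidence\nA\tg1\tcertain\nB\tg1\tuncertain\n")
        e = load_expression(p, ["A", "B"])
        assert e.values[:, 0].tolist() == [1, 0]
        e2 = load_expression(p, ["A", "B"], drop_uncertain=False)
        assert e2.values[:, 0].tolist() == [1, 1]

    def test_unknown_neuron(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("neuron\tgene\nZZ\tg1\n")
        with pytest.raises(DataError, match="ZZ"):
            load_expression(p, ["A"])


class TestBiasSimulation:
    def test_zero_density_cell_undefined_for_phi(self):
        t = bias_simulation(L=100, density_grid=[0.0, 0.05], n_pairs=20, seed=0)
        cell = t[(t.density_a == 0.0) & (t.density_b == 0.05)]
        assert np.isnan(cell["r_phi"]).all()

    def test_phi_unbiased_jaccard_biased_small(self):
        """Scaled-down density sweep: phi stays centred on 0 while the
        Jaccard mean grows along the equal-density diagonal."""
        grid = [0.05, 0.10, 0.15]
        t = bias_simulation(L=300, density_grid=grid, n_pairs=300, seed=1)
        assert t["r_phi"].abs().max() < 0.05
        diag = [float(t[(t.density_a == d) & (t.density_b == d)]["jaccard"].iloc[0])
                for d in grid]
        assert diag == sorted(diag) and diag[-1] > diag[0]
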