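import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from nemacge import (
    ArgumentError,
    DataError,
    ExpressionMatrix,
    bh_fdr,
    binomial_score,
    edge_match_counts,
    ora,
    score_genes,
)

from conftest import make_connectome


def enumerate_binomial_tail(m, n, p):
    """Exhaustive enumeration of P(X >= m) over all 2^n outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=n):
        k = sum(outcome)
        if k >= m:
            total += (p ** k) * ((1 - p) ** (n - k))
    return total


class TestBinomialScore:
    def test_zero_matches_scores_one(self):
        assert binomial_score(0, 25, 0.35) == 1.0

    def test_closed_form(self):
        assert binomial_score(10, 10, 0.5) == pytest.approx(0.5 ** 10)

    def test_small_enumeration(self):
        assert binomial_score(2, 3, 0.35) == pytest.approx(0.28175)

    @pytest.mark.parametrize("p", [0.1, 0.35, 0.5])
    @pytest.mark.parametrize("n", [1, 4, 8])
    def test_oracle_exhaustive_enumeration(self, n, p):
        for m in range(n + 1):
            assert binomial_score(m, n, p) == pytest.approx(
                enumerate_binomial_tail(m, n, p), abs=1e-12)

    def test_monotone_in_m_and_p_class(self):
        scores = [binomial_score(m, 8, 0.35) for m in range(9)]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        by_p = [binomial_score(4, 8, p) for p in (0.1, 0.3, 0.5, 0.7)]
        assert all(a < b for a, b in zip(by_p, by_p[1:]))

    def test_invalid_p_class(self):
        with pytest.raises(ArgumentError):
            binomial_score(1, 2, 0.0)
        with pytest.raises(ArgumentError):
            binomial_score(1, 2, 1.0)


class TestFdr:
    def test_step_up_by_hand(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_constant(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.5])


class TestMatchCounts:
    def _expr(self, rows, genes=("g1",)):
        return ExpressionMatrix(
            [f"N{i}" for i in range(len(rows))], list(genes), np.array(rows))

    def test_three_neuron_toy(self):
        # A, B express; class {A-B}, alternative {A-C, B-C}
        e = self._expr([[1], [1], [0]])
        t = edge_match_counts(e, [(0, 1)], [(0, 2), (1, 2)])
        assert t.loc[0, ["m", "n", "M", "n_class"]].tolist() == [1, 1, 3, 1]

    def test_gene_everywhere_saturates(self):
        e = self._expr([[1], [1], [1], [1]])
        t = edge_match_counts(e, [(0, 1), (2, 3)], [(0, 2), (1, 3)])
        assert t.loc[0, "m"] == t.loc[0, "n_class"] == 2
        assert t.loc[0, "n"] == t.loc[0, "M"] == 4

    def test_single_expressing_neuron_no_matches(self):
        e = self._expr([[1], [0], [0]])
        t = edge_match_counts(e, [(0, 1)], [(1, 2)])
        assert t.loc[0, "m"] == 0 and t.loc[0, "n"] == 0

    def test_overlapping_sets_rejected(self):
        e = self._expr([[1], [1], [0]])
        with pytest.raises(ArgumentError):
            edge_match_counts(e, [(0, 1)], [(1, 0)])


class TestScoreGenes:
    def _planted(self, planted_ds):
        return score_genes(
            planted_ds.expression, planted_ds.connectome,
            "hub_involved_vs_peripheral", k_threshold=44,
            bilateral_pairs=planted_ds.bilateral_pairs)

    def test_planted_genes_rank_top(self, planted_ds):
        t = self._planted(planted_ds)
        top = set(t.head(max(1, len(t) // 10))["gene"])
        planted = {g for g in t["gene"] if g.startswith("hubgene")}
        assert len(planted & top) >= 15

    def test_p_class_recomputed_from_pair_universe(self, planted_ds):
        t = score_genes(
            planted_ds.expression, planted_ds.connectome,
            "connected_vs_unconnected",
            bilateral_pairs=planted_ds.bilateral_pairs)
        n = planted_ds.connectome.n_neurons
        M_expected = n * (n - 1) // 2 - len(planted_ds.bilateral_pairs)
        assert t["M"].iloc[0] == M_expected
        assert 0 < t["p_class"].iloc[0] < 1

    def test_min_n_filter_excludes_from_hits(self, planted_ds):
        t = self._planted(planted_ds)
        assert not t.loc[~t["passes_min_n"], "hit"].any()
        assert t.loc[~t["passes_min_n"], "p_corr"].isna().all()

    def test_mismatched_universe_rejected(self, planted_ds, small_ds):
        with pytest.raises(DataError):
            score_genes(small_ds.expression, planted_ds.connectome)


class TestScoreCalibration:
    def test_exact_calibration_when_model_holds(self):
        """When the score's null model is exactly true — iid expression and
        a constant connection probability, so matches fall on the
        connected class independently — the score distribution is
        super-uniform (its ECDF never exceeds the uniform CDF beyond
        sampling noise)."""
        from nemacge.synthetic import (SynthConfig, generate_connectome,
                                       generate_expression, generate_neurons)
        cfg = SynthConfig(n_hubs=0, n_hub_genes=0, n_bilateral_pairs=0,
                          lambda_conn=0.0, A_conn=0.0, B_conn=0.04)
        pooled = []
        for seed in range(15):
            neurons = generate_neurons(cfg, seed=seed)
            c, _ = generate_connectome(neurons, cfg, seed=seed)
            e = generate_expression(neurons, [], cfg, seed=seed)
            t = score_genes(e, c, "connected_vs_unconnected")
            pooled.append(t.loc[t.passes_min_n, "p_a"].to_numpy())
        u = np.sort(np.concatenate(pooled))
        ecdf = np.arange(1, len(u) + 1) / len(u)
        d_plus = np.max(ecdf - u)
        crit = np.sqrt(-np.log(0.01) / (2 * len(u)))
        assert d_plus < crit


class TestOra:
    def _ann(self, mapping):
        rows = [(g, cid, cid) for cid, genes in mapping.items() for g in genes]
        return pd.DataFrame(rows, columns=["gene", "category_id", "category_name"])

    def test_fully_nested_closed_form(self):
        bg = {f"g{i}" for i in range(10)}
        hits = {f"g{i}" for i in range(5)}
        ann = self._ann({"cat": sorted(hits)})
        t = ora(hits, bg, ann)
        assert t.loc[0, "p"] == pytest.approx(1 / comb(10, 5))

    def test_disjoint_category_p_one(self):
        bg = {f"g{i}" for i in range(12)}
        hits = {"g0", "g1"}
        ann = self._ann({"cat": [f"g{i}" for i in range(5, 11)]})
        t = ora(hits, bg, ann)
        # overlap 0 is the minimum possible here (6 + 2 <= 12)
        assert t.loc[0, "p"] == pytest.approx(1.0)

    def test_size_window(self):
        bg = {f"g{i}" for i in range(30)}
        ann = self._ann({"small": ["g0"], "ok": [f"g{i}" for i in range(6)]})
        t = ora({"g0"}, bg, ann, min_size=5, max_size=100)
        assert t["category_id"].tolist() == ["ok"]

    def test_empty_annotations_warn(self):
        with pytest.warns(UserWarning):
            t = ora({"g0"}, {"g0", "g1"}, self._ann({}))
        assert t.empty

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ArgumentError):
            ora({"gX"}, {"g0"}, self._ann({"c": ["g0"]}))
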