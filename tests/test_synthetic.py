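import numpy as np
import pytest

from nemacge import (
    ConfigurationError,
    SynthConfig,
    cge_matrix,
    rich_club_phi,
    simulate,
)
from nemacge.connectome import degree_sequence
from nemacge.synthetic import (
    generate_connectome,
    generate_expression,
    generate_neurons,
    select_hubs,
    write_dataset,
)


class TestConfig:
    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(n_head=-1)

    def test_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(p_hub=1.5)

    def test_hub_count_bound(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(n_head=5, n_body=50, n_tail=0, n_hubs=10,
                        n_bilateral_pairs=0)


class TestNeurons:
    def test_region_counts_default(self):
        t = generate_neurons(SynthConfig(seed=0))
        assert len(t) == 279
        counts = t["region"].value_counts()
        assert counts["head"] == 147 and counts["body"] == 105 and counts["tail"] == 27

    def test_degenerate_single_cluster(self):
        t = generate_neurons(SynthConfig(n_head=5, n_body=0, n_tail=0, n_hubs=0,
                                         n_bilateral_pairs=0, seed=0))
        assert len(t) == 5 and (t["region"] == "head").all()

    def test_determinism_byte_identical(self):
        cfg = SynthConfig(seed=123)
        a = generate_neurons(cfg).to_csv()
        b = generate_neurons(cfg).to_csv()
        assert a == b

    def test_cluster_extents(self):
        t = generate_neurons(SynthConfig(seed=1))
        head = t[t.region == "head"][["x_um", "y_um"]].to_numpy()
        from scipy.spatial.distance import pdist
        assert pdist(head).max() <= 130.0 + 1e-9
        tail = t[t.region == "tail"][["x_um", "y_um"]].to_numpy()
        assert pdist(tail).max() <= 90.0 + 1e-9
        body_x = t[t.region == "body"]["x_um"]
        assert body_x.max() - body_x.min() > 0.8 * 1020

    def test_birth_times_bimodal(self):
        t = generate_neurons(SynthConfig(seed=2))
        bt = t["birth_time_min"]
        assert ((bt < 550) | (bt > 1200)).all()
        assert (bt < 550).any() and (bt > 1200).any()

    def test_bilateral_pairs_symmetric(self):
        t = generate_neurons(SynthConfig(seed=3))
        by_name = t.set_index("neuron")["bilateral_partner"]
        paired = by_name[by_name != ""]
        assert len(paired) == 2 * 92
        for a, b in paired.items():
            assert by_name[b] == a


class TestConnectome:
    def test_determinism(self):
        cfg = SynthConfig(seed=5)
        t = generate_neurons(cfg)
        c1, h1 = generate_connectome(t, cfg)
        c2, h2 = generate_connectome(t, cfg)
        assert h1 == h2
        assert (c1.adjacency() == c2.adjacency()).all()

    def test_distance_free_limit_density(self):
        cfg = SynthConfig(n_head=60, n_body=0, n_tail=0, n_hubs=0,
                          n_bilateral_pairs=0, lambda_conn=0.0,
                          A_conn=0.12, B_conn=0.0, gap_fraction=0.0, seed=6)
        t = generate_neurons(cfg)
        c, _ = generate_connectome(t, cfg)
        n_ordered = 60 * 59
        density = c.adjacency().sum() / n_ordered
        se = np.sqrt(0.12 * 0.88 / n_ordered)
        assert abs(density - 0.12) < 3 * se

    def test_hub_density_one_complete_club(self):
        cfg = SynthConfig(n_head=30, n_body=0, n_tail=0, n_hubs=6,
                          hub_density=1.0, n_bilateral_pairs=0,
                          A_conn=0.02, B_conn=0.0, seed=7)
        t = generate_neurons(cfg)
        c, hubs = generate_connectome(t, cfg)
        P = c.pair_matrix()
        idx = {n: i for i, n in enumerate(c.neurons)}
        hi = [idx[h] for h in hubs]
        assert all(P[a, b] for i, a in enumerate(hi) for b in hi[i + 1:])
        # phi over the club is therefore 1 at any k that isolates the hubs
        deg = degree_sequence(c)
        k_iso = int(sorted(deg["k"])[-len(hubs) - 1])
        club = deg[deg.k > k_iso]["neuron"]
        if set(club) == set(hubs):
            assert rich_club_phi(c, k_iso) == 1.0

    def test_planted_hubs_higher_degree_many_seeds(self):
        """Expected-degree argument: with hub_density = 0.8 over a sparse
        background (A = 0.05), planted hubs out-degree the rest."""
        cfg = SynthConfig(n_head=60, n_body=30, n_tail=10, n_hubs=8,
                          hub_density=0.8, A_conn=0.05, n_bilateral_pairs=0)
        diffs = []
        for seed in range(20):
            t = generate_neurons(cfg, seed=seed)
            c, hubs = generate_connectome(t, cfg, seed=seed)
            deg = degree_sequence(c).set_index("neuron")["k"]
            is_hub = deg.index.isin(hubs)
            diffs.append(deg[is_hub].mean() - deg[~is_hub].mean())
        assert np.mean(diffs) > 0
        assert (np.array(diffs) > 0).all()


class TestExpression:
    def test_flip_zero_bilateral_identical(self):
        cfg = SynthConfig(flip_prob=0.0, seed=8)
        t = generate_neurons(cfg)
        hubs = select_hubs(t, cfg)
        e = generate_expression(t, hubs, cfg)
        m = cge_matrix(e, mask_bilateral=False)
        idx = {n: i for i, n in enumerate(e.neurons)}
        by_name = t.set_index("neuron")["bilateral_partner"]
        for a, b in by_name[by_name != ""].items():
            v = m.values[idx[a], idx[b]]
            assert np.isnan(v) or v == pytest.approx(1.0)

    def test_forced_matches_when_hub_genes_deterministic(self):
        cfg = SynthConfig(n_head=20, n_body=0, n_tail=0, n_hubs=5,
                          n_genes=10, n_hub_genes=3, p_hub=1.0, p_base=0.0,
                          n_bilateral_pairs=0, flip_prob=0.0, seed=9)
        t = generate_neurons(cfg)
        hubs = select_hubs(t, cfg)
        e = generate_expression(t, hubs, cfg)
        hub_rows = [e.neurons.index(h) for h in hubs]
        assert (e.values[hub_rows, :3] == 1).all()
        non_hub = [i for i in range(20) if i not in hub_rows]
        assert (e.values[non_hub] == 0).all()

    def test_mean_genes_per_neuron_binomial(self):
        cfg = SynthConfig(p_base=0.03, n_hubs=0, n_hub_genes=0,
                          n_bilateral_pairs=0, seed=10)
        t = generate_neurons(cfg)
        e = generate_expression(t, [], cfg)
        per_neuron = e.values.sum(axis=1)
        expected = 948 * 0.03
        se = np.sqrt(948 * 0.03 * 0.97 / 279)
        assert abs(per_neuron.mean() - expected) < 3 * se

    def test_unknown_hub_rejected(self):
        cfg = SynthConfig(seed=11)
        t = generate_neurons(cfg)
        from nemacge import DataError
        with pytest.raises(DataError, match="NOPE"):
            generate_expression(t, ["NOPE"], cfg)


class TestSimulate:
    def test_full_determinism(self, tmp_path):
        cfg = SynthConfig(n_head=30, n_body=10, n_tail=5, n_hubs=4,
                          n_genes=50, n_hub_genes=5, n_bilateral_pairs=8,
                          seed=12)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate(cfg), d1)
        write_dataset(simulate(cfg), d2)
        for f in ("neurons.tsv", "edges.tsv", "expression.tsv",
                  "lineage.csv", "simulation.json"):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_command_interneurons_flagged_among_hubs(self, small_ds):
        flagged = small_ds.neurons.loc[
            small_ds.neurons["command_interneuron"] == 1, "neuron"]
        assert set(flagged) <= set(small_ds.hubs)
        assert len(flagged) == min(10, len(small_ds.hubs))

    def test_dataset_roundtrips_through_loaders(self, tmp_path):
        from nemacge import load_connectome
        from nemacge.cge import load_expression
        cfg = SynthConfig(n_head=25, n_body=10, n_tail=5, n_hubs=3,
                          n_genes=40, n_hub_genes=4, n_bilateral_pairs=6,
                          seed=13)
        ds = simulate(cfg)
        write_dataset(ds, tmp_path)
        c = load_connectome(tmp_path / "edges.tsv", tmp_path / "neurons.tsv")
        assert (c.adjacency() == ds.connectome.adjacency()).all()
        e = load_expression(tmp_path / "expression.tsv", c.neurons)
        # loaders keep only annotated genes; every annotation survives
        assert e.values.sum() == ds.expression.values.sum()
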