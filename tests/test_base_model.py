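"""Base predictor: GCN layers, SIB losses, classifier — against closed
forms and dense-matrix oracles."""

import numpy as np
import pytest

from metabind.autodiff import Tensor, constant
from metabind.base_model import (ModelConfig, bce_loss, base_forward,
                                 batched_task_forward, classify,
                                 connectivity_loss, desk_config,
                                 encode_molecule, encode_protein, fit_critic,
                                 gcn_layer, init_params, make_molecule_batch,
                                 mi_proxy_loss, normalized_adjacency,
                                 sib_assign, subgraph_embedding)
from metabind.graphs import build_protein_graph
from metabind.synthetic import SyntheticSpec, make_benchmark


@pytest.fixture(scope="module")
def bench():
    return make_benchmark(SyntheticSpec(n_proteins=4, n_molecules=12,
                                        residues_per_protein=(20, 30), seed=3))


def _rand_graph(n, seed, p_edge=0.4):
    rng = np.random.default_rng(seed)
    a = np.triu((rng.uniform(size=(n, n)) < p_edge).astype(float), 1)
    a = a + a.T
    return a


class TestGCNLayer:
    def test_single_node_identity(self):
        h = Tensor(np.array([[1.0, 2.0]]))
        out = gcn_layer(h, normalized_adjacency(np.zeros((1, 1))),
                        Tensor(np.eye(2)), Tensor(np.zeros(2)))
        assert np.allclose(out.data, [[1.0, 2.0]])   # A_hat = 1 for one node

    def test_large_negative_bias_zeroes_output(self):
        rng = np.random.default_rng(0)
        h = Tensor(rng.normal(size=(5, 3)))
        out = gcn_layer(h, normalized_adjacency(_rand_graph(5, 1)),
                        Tensor(rng.normal(size=(3, 4))),
                        Tensor(np.full(4, -1e6)))
        assert np.all(out.data == 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, din, dout = 6, 4, 3
        a = _rand_graph(n, seed)
        h = rng.normal(size=(n, din))
        w = rng.normal(size=(din, dout))
        b = rng.normal(size=dout)
        # explicit D^-1/2 (A + I) D^-1/2 computation
        ai = a + np.eye(n)
        dinv = np.diag(1.0 / np.sqrt(ai.sum(axis=1)))
        expected = np.maximum(dinv @ ai @ dinv @ h @ w + b, 0.0)
        out = gcn_layer(Tensor(h), normalized_adjacency(a), Tensor(w), Tensor(b))
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            gcn_layer(Tensor(np.ones((3, 4))), normalized_adjacency(_rand_graph(3, 0)),
                      Tensor(np.ones((5, 2))), Tensor(np.zeros(2)))


class TestEncoders:
    def test_zero_weights_zero_embeddings(self, bench):
        cfg = desk_config(32)
        params, _ = init_params(cfg, seed=0)
        for k in params:
            if k.startswith("theta_P"):
                params[k] = Tensor(np.zeros_like(params[k].data))
        g = next(iter(bench.proteins.values())).graph
        assert np.all(encode_protein(g, params, cfg).data == 0.0)

    def test_protein_permutation_equivariance(self, bench):
        cfg = desk_config(32)
        params, _ = init_params(cfg, seed=1)
        g = next(iter(bench.proteins.values())).graph
        h = encode_protein(g, params, cfg)
        rng = np.random.default_rng(5)
        perm = rng.permutation(g.n_residues)
        g2 = build_protein_graph(g.coords[perm], g.node_features[perm],
                                 "permuted")
        h2 = encode_protein(g2, params, cfg)
        assert np.allclose(h2.data, h.data[perm], atol=1e-9)

    def test_molecule_pooling_permutation_invariance(self, bench):
        from metabind.graphs import MoleculeGraph
        cfg = desk_config(32)
        params, _ = init_params(cfg, seed=1)
        g = next(iter(bench.molecules.values())).graph
        _, pooled = encode_molecule(g, params, cfg)
        rng = np.random.default_rng(6)
        perm = rng.permutation(g.n_atoms)
        inv = np.argsort(perm)
        edges = np.sort(inv[g.edges], axis=1)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        g2 = MoleculeGraph("perm", None, g.node_features[perm],
                           edges[order], g.edge_features[order])
        _, pooled2 = encode_molecule(g2, params, cfg)
        assert np.allclose(pooled2.data, pooled.data, atol=1e-9)

    def test_two_layer_dense_unroll(self):
        rng = np.random.default_rng(2)
        cfg = ModelConfig(protein_widths=(3, 4, 2), molecule_widths=(3, 3),
                          assign_hidden=(4,), critic_hidden=(4,),
                          classifier_hidden=(4,))
        params, _ = init_params(cfg, seed=0)
        coords = rng.uniform(0, 10, size=(5, 3))
        feats = rng.normal(size=(5, 3))
        g = build_protein_graph(coords, feats, "p")
        a_hat = normalized_adjacency(g.adjacency)
        h = np.maximum(a_hat @ feats @ params["theta_P.0.W"].data
                       + params["theta_P.0.b"].data, 0)
        h = np.maximum(a_hat @ h @ params["theta_P.1.W"].data
                       + params["theta_P.1.b"].data, 0)
        assert np.allclose(encode_protein(g, params, cfg).data, h, atol=1e-6)


class TestSIB:
    def test_assignment_rows_sum_to_one(self):
        cfg = desk_config(16)
        params, _ = init_params(cfg, seed=0)
        rng = np.random.default_rng(0)
        z = sib_assign(Tensor(rng.normal(size=(1000, 16))),
                       Tensor(rng.normal(size=16)), params, cfg)
        assert np.allclose(z.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((z.data >= 0) & (z.data <= 1))

    def test_equal_logits_give_half(self):
        cfg = desk_config(8)
        params, _ = init_params(cfg, seed=0)
        # zero out the assignment MLP: all logits equal -> rows (0.5, 0.5)
        for k in params:
            if k.startswith("phi1"):
                params[k] = Tensor(np.zeros_like(params[k].data))
        z = sib_assign(Tensor(np.random.default_rng(1).normal(size=(7, 8))),
                       Tensor(np.zeros(8)), params, cfg)
        assert np.allclose(z.data, 0.5)

    def test_subgraph_embedding_indicator(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(6, 4))
        z = np.zeros((6, 2))
        sel = [0, 2, 5]
        z[sel, 0] = 1.0
        z[[1, 3, 4], 1] = 1.0
        out = subgraph_embedding(Tensor(z), Tensor(h))
        assert np.allclose(out.data, h[sel].sum(axis=0))

    def test_subgraph_embedding_uniform_half(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=(5, 3))
        z = np.full((5, 2), 0.5)
        out = subgraph_embedding(Tensor(z), Tensor(h))
        assert np.allclose(out.data, 0.5 * h.sum(axis=0))

    @pytest.mark.parametrize("seed", range(5))
    def test_subgraph_embedding_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(size=(8, 5))
        raw = rng.uniform(size=(8, 2))
        z = raw / raw.sum(axis=1, keepdims=True)
        assert np.allclose(subgraph_embedding(Tensor(z), Tensor(h)).data,
                           (z.T @ h)[0], atol=1e-12)


class TestConnectivityLoss:
    def test_component_indicator_is_zero(self):
        # two disconnected triangles
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            a[i, j] = a[j, i] = 1
        z = np.zeros((6, 2))
        z[:3, 0] = 1.0
        z[3:, 1] = 1.0
        assert connectivity_loss(Tensor(z), a).item() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_assignment_quarter(self):
        for seed in range(3):
            a = _rand_graph(8, seed)
            if a.sum() == 0:
                continue
            z = np.full((8, 2), 0.5)
            assert connectivity_loss(Tensor(z), a).item() == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _rand_graph(8, seed + 100)
        if a.sum() == 0:
            return
        raw = rng.uniform(0.01, 1.0, size=(8, 2))
        z = raw / raw.sum(axis=1, keepdims=True)
        c = z.T @ a @ z
        p = c / (c.sum(axis=1, keepdims=True) + 1e-12)
        expected = np.mean((np.diag(p) - 1.0) ** 2)
        assert connectivity_loss(Tensor(z), a).item() == pytest.approx(
            expected, abs=1e-9)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            connectivity_loss(Tensor(np.full((3, 2), 0.5)), np.zeros((3, 3)))

    def test_gradient_descent_hardens_assignments(self):
        """On a two-component graph, descending the connectivity loss from a
        near-uniform Z drives rows toward hard memberships."""
        a = np.zeros((8, 8))
        for i, j in [(0, 1), (1, 2), (2, 3), (0, 3), (4, 5), (5, 6), (6, 7), (4, 7)]:
            a[i, j] = a[j, i] = 1
        rng = np.random.default_rng(0)
        logits = Tensor(0.1 * rng.normal(size=(8, 2)), requires_grad=True)
        from metabind.autodiff import softmax
        maxes = []
        for _ in range(200):
            logits.grad = None
            z = softmax(logits, axis=1)
            loss = connectivity_loss(z, a)
            loss.backward()
            logits.data = logits.data - 0.5 * logits.grad
            maxes.append(z.data.max(axis=1).mean())
        # memberships harden monotonically from ~0.5 toward 1
        assert np.all(np.diff(maxes) > -1e-9)
        assert maxes[0] < 0.6 < 0.85 < maxes[-1]


class TestMIProxy:
    def _setup(self, d=6, n=4, seed=0):
        cfg = desk_config(d)
        _, critic = init_params(cfg, seed=seed)
        rng = np.random.default_rng(seed)
        return cfg, critic, rng.normal(size=(n, d)), rng.normal(size=(n, d))

    @pytest.mark.parametrize("n", range(2, 11))
    def test_constant_critic_closed_form(self, n):
        cfg, critic, w, s = self._setup(n=n)
        for k in critic:      # zero weights, constant bias c on the output
            critic[k] = Tensor(np.zeros_like(critic[k].data))
        c = 1.7
        critic[f"phi2.{len(cfg.critic_hidden)}.b"] = Tensor(np.array([c]))
        got = mi_proxy_loss(Tensor(w), Tensor(s), critic, cfg).item()
        assert got == pytest.approx(-np.log(n - 1), abs=1e-9)

    def test_n2_hand_formula(self):
        cfg, critic, w, s = self._setup(n=2, seed=1)

        def score(wi, sj):
            from metabind.base_model import critic_scores
            from metabind.autodiff import concat
            x = concat([Tensor(wi.reshape(1, -1)), Tensor(sj.reshape(1, -1))],
                       axis=1)
            return critic_scores(x, critic, cfg).item()

        a11, a22 = score(w[0], s[0]), score(w[1], s[1])
        a12, a21 = score(w[0], s[1]), score(w[1], s[0])
        expected = 0.5 * (a11 + a22) - np.log(0.5 * (np.exp(a12) + np.exp(a21)))
        got = mi_proxy_loss(Tensor(w), Tensor(s), critic, cfg).item()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_joint_permutation_invariance(self):
        cfg, critic, w, s = self._setup(n=5, seed=2)
        v1 = mi_proxy_loss(Tensor(w), Tensor(s), critic, cfg).item()
        perm = np.array([3, 0, 4, 1, 2])
        v2 = mi_proxy_loss(Tensor(w[perm]), Tensor(s[perm]), critic, cfg).item()
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_batch_of_one_rejected(self):
        cfg, critic, w, s = self._setup(n=2)
        with pytest.raises(ValueError):
            mi_proxy_loss(Tensor(w[:1]), Tensor(s[:1]), critic, cfg)

    def test_ascent_increases_bound(self):
        cfg, critic, w, _ = self._setup(n=6, seed=3)
        s = w + 0.1 * np.random.default_rng(3).normal(size=w.shape)
        before = mi_proxy_loss(Tensor(w), Tensor(s), critic, cfg).item()
        fit_critic(w, s, critic, cfg, steps=50)
        after = mi_proxy_loss(Tensor(w), Tensor(s), critic, cfg).item()
        assert after > before

    def test_dependent_pairs_beat_shuffled(self):
        """The maximized DV bound is larger for dependent (whole, sub) pairs
        than for a shuffled pairing (sign test over 20 seeds)."""
        from scipy.stats import binomtest
        cfg = desk_config(6)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            # batch large enough that the critic cannot overfit an arbitrary
            # pairing (the DV bound is biased upward at tiny n)
            w = rng.normal(size=(24, 6))
            s = w + 0.05 * rng.normal(size=(24, 6))
            s_shuf = s[rng.permutation(24)]
            vals = []
            for sub in (s, s_shuf):
                _, critic = init_params(cfg, seed=seed)
                fit_critic(w, sub, critic, cfg, steps=200)
                vals.append(mi_proxy_loss(Tensor(w), Tensor(sub),
                                          critic, cfg).item())
            wins += vals[0] > vals[1]
        assert binomtest(wins, 20, 0.5, alternative="greater").pvalue < 0.05


class TestClassifier:
    def test_bce_values(self):
        assert bce_loss(1.0, Tensor(np.array(0.5))).item() == pytest.approx(
            np.log(2), abs=1e-12)
        assert bce_loss(1.0, Tensor(np.array(0.9))).item() == pytest.approx(
            -np.log(0.9), abs=1e-12)
        assert bce_loss(0.0, Tensor(np.array(1e-7))).item() == pytest.approx(
            0.0, abs=1e-6)

    def test_probability_in_open_interval(self):
        cfg = desk_config(8)
        params, _ = init_params(cfg, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = classify(Tensor(rng.normal(size=8) * 50),
                         Tensor(rng.normal(size=8) * 50), params, cfg)
            assert 0.0 < p.item() < 1.0


class TestBaseForward:
    def test_lambda_zero_reduces_to_bce(self, bench):
        cfg = desk_config(32)
        cfg.lambda1 = cfg.lambda2 = 0.0
        params, critic = init_params(cfg, seed=0)
        sp = next(iter(bench.proteins.values()))
        sm = next(iter(bench.molecules.values()))
        prob, loss, _ = base_forward(sp.graph, sm.graph, params, critic, cfg,
                                     label=1.0)
        assert loss.item() == pytest.approx(-np.log(prob.item()), abs=1e-9)

    def test_random_z_no_gradient_to_assignment_mlp(self, bench):
        cfg = desk_config(32)
        cfg.random_z = True
        params, critic = init_params(cfg, seed=0)
        sp = next(iter(bench.proteins.values()))
        sm = next(iter(bench.molecules.values()))
        rng = np.random.default_rng(0)
        _, loss, z = base_forward(sp.graph, sm.graph, params, critic, cfg,
                                  label=1.0, rng=rng)
        loss.backward()
        assert np.allclose(z.sum(axis=1), 1.0)
        for k, t in params.items():
            if k.startswith("phi1"):
                assert t.grad is None or np.all(t.grad == 0.0)

    def test_three_term_hand_computation(self, bench):
        from metabind.base_model import (encode_protein, encode_molecule,
                                         pair_forward)
        cfg = desk_config(32)
        cfg.mi_inner_steps = 0
        params, critic = init_params(cfg, seed=2)
        sp = next(iter(bench.proteins.values()))
        mols = [m.graph for m in list(bench.molecules.values())[:3]]
        labels = np.array([1.0, 0.0, 1.0])
        mb = make_molecule_batch(mols, cfg)
        loss, probs, zs, _ = batched_task_forward(sp.graph, mb, labels,
                                                  params, critic, cfg)
        # hand recomposition from the per-op functions
        nodes = encode_protein(sp.graph, params, cfg)
        terms_cls, terms_conn = [], []
        whole, subs = [], []
        for mol, y in zip(mols, labels):
            r = pair_forward(nodes, mol, params, cfg)
            terms_cls.append(bce_loss(y, r.prob).item())
            terms_conn.append(connectivity_loss(r.Z_graph,
                                                sp.graph.adjacency).item())
            whole.append(r.whole_embed.data)
            subs.append(r.sub_embed.data)
        mi = mi_proxy_loss(Tensor(np.stack(whole)), Tensor(np.stack(subs)),
                           critic, cfg).item()
        expected = (np.mean(terms_cls) + cfg.lambda1 * np.mean(terms_conn)
                    + cfg.lambda2 * mi)
        assert loss.item() == pytest.approx(expected, abs=1e-9)

    def test_batched_equals_looped(self, bench):
        from metabind.base_model import batch_forward
        cfg = desk_config(32)
        cfg.mi_inner_steps = 0      # keep the critic identical on both paths
        params, critic = init_params(cfg, seed=4)
        sp = next(iter(bench.proteins.values()))
        mols = [m.graph for m in list(bench.molecules.values())[:5]]
        labels = np.array([1, 0, 1, 0, 0], dtype=float)
        l1, p1, z1, _ = batch_forward(sp.graph, mols, labels, params, critic, cfg)
        mb = make_molecule_batch(mols, cfg)
        l2, p2, z2, _ = batched_task_forward(sp.graph, mb, labels, params,
                                             critic, cfg)
        assert l1.item() == pytest.approx(l2.item(), abs=1e-10)
        assert np.allclose([p.data for p in p1], p2.data, atol=1e-10)
        assert np.allclose(np.stack(z1), z2, atol=1e-10)

    def test_whole_pipeline_permutation_invariance(self, bench):
        cfg = desk_config(32)
        params, critic = init_params(cfg, seed=5)
        sp = next(iter(bench.proteins.values()))
        sm = next(iter(bench.molecules.values()))
        prob1, _, _ = base_forward(sp.graph, sm.graph, params, critic, cfg)
        rng = np.random.default_rng(8)
        perm = rng.permutation(sp.graph.n_residues)
        g2 = build_protein_graph(sp.graph.coords[perm],
                                 sp.graph.node_features[perm], "perm")
        prob2, _, _ = base_forward(g2, sm.graph, params, critic, cfg)
        assert prob1.item() == pytest.approx(prob2.item(), abs=1e-6)
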