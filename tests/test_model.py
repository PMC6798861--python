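"""Network model: hand-worked oracles for each stage, residual and
permutation invariants, analytic-vs-numeric gradients, and agreement between
the reference per-operation path and the packed-batch path."""

import numpy as np
import pytest

import molgcn as m
from molgcn.model import ConvLayerParams


def tiny_params(d_atom, d_bond, d_mol, c=2, k=3, h=3, layers=2, seed=0):
    return m.init_params((d_atom, d_bond, d_mol), c=c, k=k, h=h, m=layers,
                         seed=seed)


# ---------------------------------------------------------------------- leaky


def test_leaky_relu_definition():
    assert m.leaky_relu(2.0, 0.01) == 2.0
    assert m.leaky_relu(-1.0, 0.01) == pytest.approx(-0.01)
    assert m.leaky_relu(0.0, 0.01) == 0.0
    with pytest.raises(ValueError):
        m.leaky_relu(1.0, 1.5)


# ------------------------------------------------------------- initial hidden


def test_initial_hidden_hand_example():
    p = tiny_params(2, 0, 0, k=2)
    p.W0 = np.array([[1.0, 2.0], [3.0, -4.0]])
    p.b0 = np.zeros(2)
    out = m.initial_hidden(np.array([[1.0, 1.0]]), p)
    # z = [4, -2] -> leaky(0.01) -> [4, -0.02]
    assert np.allclose(out, [[4.0, -0.02]])


def test_initial_hidden_contracts():
    p = tiny_params(5, 0, 0, k=3)
    out = m.initial_hidden(np.zeros((4, 5)), p)
    assert out.shape == (4, 3)
    assert np.allclose(out, 0.0)  # F(0) = 0 with zero bias
    with pytest.raises(ValueError):
        m.initial_hidden(np.zeros((4, 7)), p)


# --------------------------------------------------------------- pair message


def test_pair_message_hand_example():
    layer = ConvLayerParams(W=np.array([[2.0], [-1.0], [0.5]]),
                            b=np.array([0.1]), V=np.eye(1))
    out = m.pair_message([1.0], [1.0], [2.0], layer)
    assert out == pytest.approx([2.0 - 1.0 + 1.0 + 0.1])  # 2.1
    swapped = m.pair_message([2.0], [1.0], [1.0], layer)
    assert swapped == pytest.approx([4.0 - 1.0 + 0.5 + 0.1])  # ordered concat
    assert not np.allclose(out, swapped)


def test_pair_message_zero_inputs():
    layer = ConvLayerParams(W=np.zeros((3, 1)), b=np.zeros(1), V=np.eye(1))
    assert m.pair_message([0.0], [0.0], [0.0], layer) == pytest.approx([0.0])
    with pytest.raises(ValueError):
        m.pair_message([0.0, 0.0], [0.0], [0.0], layer)


# ------------------------------------------------------------------ conv step


def test_conv_step_residual_identity(sample_smiles):
    cfg = m.FeatureConfig(level=3)
    p = tiny_params(*m.feature_dimensions(cfg), k=4)
    zero_v = ConvLayerParams(W=p.layers[0].W, b=p.layers[0].b, V=np.zeros((4, 4)))
    for s in sample_smiles[:6]:
        g = m.build_graph(s, cfg)
        A = m.initial_hidden(g.atom_features, p)
        assert np.array_equal(m.conv_step(g, A, zero_v), A)


def test_conv_step_isolated_atom_unchanged():
    cfg = m.FeatureConfig(level=3)
    g = m.build_graph("C", cfg)  # methane: no heavy-atom neighbours
    p = tiny_params(*m.feature_dimensions(cfg), k=4, seed=7)
    A = m.initial_hidden(g.atom_features, p)
    assert np.array_equal(m.conv_step(g, A, p.layers[0]), A)


def test_conv_step_path_graph_pooling():
    # 3-atom path (propane): middle atom pools the element-wise max of its two
    # neighbour messages; end atoms pool their single message
    cfg = m.FeatureConfig(level=3)
    g = m.build_graph("CCC", cfg)
    rng = np.random.default_rng(5)
    k = 2
    layer = ConvLayerParams(W=rng.normal(size=(2 * k + 4, k)),
                            b=rng.normal(size=k), V=np.eye(k))
    A = rng.normal(size=(3, k))
    B = g.bond_features[0]  # both bonds are single bonds
    msg = lambda i, j: m.pair_message(A[i], B, A[j], layer)
    pooled = np.stack([
        msg(0, 1),
        np.maximum(msg(1, 0), msg(1, 2)),
        msg(2, 1),
    ])
    assert np.allclose(m.conv_step(g, A, layer), A + pooled @ layer.V.T)


# -------------------------------------------------------------------- readout


def test_readout_properties(rng):
    A = rng.normal(size=(5, 4))
    M = np.array([1.0, 2.0])
    out = m.readout(A, M)
    assert np.allclose(out, m.readout(A[rng.permutation(5)], M))
    assert np.allclose(m.readout(A[:1], np.zeros(0)), A[0])
    a, b = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
    assert np.allclose(m.readout(np.stack([a[0], b[0]]), M),
                       np.concatenate([a[0] + b[0], M]))


# ----------------------------------------------------------------------- head


def test_head_forward():
    p = tiny_params(2, 0, 0, c=3, k=2, h=4)
    for name in ("Wh", "bh", "Wo", "bo"):
        getattr(p, name)[...] = 0.0
    assert np.allclose(m.head_forward(np.zeros(2), p), 0.5)  # sigmoid(0)
    p2 = tiny_params(2, 0, 0, c=5, k=2, h=4, seed=9)
    out = m.head_forward(np.array([0.3, -1.2]), p2)
    assert np.all((out > 0) & (out < 1))
    with pytest.raises(ValueError):
        m.head_forward(np.zeros(3), p2)


def test_head_forward_hand_example():
    p = tiny_params(1, 0, 0, c=1, k=1, h=1)
    p.Wh = np.array([[0.5]]); p.bh = np.array([0.2])
    p.Wo = np.array([[2.0]]); p.bo = np.array([-0.1])
    out = m.head_forward(np.array([2.0]), p)
    # hidden = leaky(1.2) = 1.2; logit = 2.3; sigmoid(2.3) = 0.908877...
    assert out[0] == pytest.approx(1.0 / (1.0 + np.exp(-2.3)), abs=1e-12)


# -------------------------------------------------------------------- forward


def test_forward_eval_deterministic():
    cfg = m.FeatureConfig(level=4)
    g = m.build_graph("CC(=O)NC", cfg)
    p = tiny_params(*m.feature_dimensions(cfg), seed=2)
    assert np.array_equal(m.forward(g, p), m.forward(g, p))


def test_forward_permutation_invariant(sample_smiles, rng):
    cfg = m.FeatureConfig(level=4)
    p = tiny_params(*m.feature_dimensions(cfg), seed=4)
    for s in sample_smiles[:8]:
        g = m.build_graph(s, cfg)
        ref = m.forward(g, p)
        for _ in range(3):
            gp = m.permute_graph(g, rng.permutation(g.n_atoms))
            assert np.allclose(m.forward(gp, p), ref, atol=1e-6)


def test_forward_matches_stagewise_composition(sample_smiles):
    cfg = m.FeatureConfig(level=5)
    p = tiny_params(*m.feature_dimensions(cfg), seed=6)
    for s in sample_smiles[:5]:
        g = m.build_graph(s, cfg)
        A = m.initial_hidden(g.atom_features, p)
        for layer in p.layers:
            A = m.conv_step(g, A, layer, p.leaky_slope)
        ref = m.head_forward(m.readout(A, g.mol_features), p)
        assert np.allclose(m.forward(g, p), ref, atol=1e-12)


def test_batch_forward_matches_single(sample_smiles):
    cfg = m.FeatureConfig(level=3)
    p = tiny_params(*m.feature_dimensions(cfg), seed=8)
    graphs = [m.build_graph(s, cfg) for s in sample_smiles[:6]]
    probs, _ = m.batch_forward(m.pack_graphs(graphs), p)
    for i, g in enumerate(graphs):
        assert np.allclose(probs[i], m.forward(g, p), atol=1e-12)


def test_forward_shape_mismatch_raises():
    cfg1, cfg5 = m.FeatureConfig(level=1), m.FeatureConfig(level=5)
    p = tiny_params(*m.feature_dimensions(cfg5))
    g = m.build_graph("CCO", cfg1)
    with pytest.raises(ValueError):
        m.forward(g, p)


@pytest.mark.parametrize("level", [1, 2, 3, 4, 5])
def test_forward_runs_at_every_level(sample_smiles, level):
    cfg = m.FeatureConfig(level=level)
    p = tiny_params(*m.feature_dimensions(cfg), c=3, seed=level)
    for s in sample_smiles:
        out = m.forward(m.build_graph(s, cfg), p)
        assert out.shape == (3,) and np.all((out > 0) & (out < 1))


def test_train_mode_dropout_differs_and_eval_ignores_rng():
    cfg = m.FeatureConfig(level=2)
    g = m.build_graph("CCO", cfg)
    p = tiny_params(*m.feature_dimensions(cfg), seed=3)
    rng = np.random.default_rng(0)
    a = m.forward(g, p, mode="train", dropout_rng=rng, dropout_rate=0.5)
    b = m.forward(g, p, mode="train", dropout_rng=rng, dropout_rate=0.5)
    assert not np.allclose(a, b)  # different masks
    assert np.array_equal(m.forward(g, p, mode="eval"), m.forward(g, p))


# ---------------------------------------------------------------- init params


def test_init_params_seeding():
    p1 = m.init_params((5, 4, 0), c=2, k=6, h=3, m=2, seed=42)
    p2 = m.init_params((5, 4, 0), c=2, k=6, h=3, m=2, seed=42)
    p3 = m.init_params((5, 4, 0), c=2, k=6, h=3, m=2, seed=43)
    for (n1, a1), (n2, a2) in zip(p1.param_items(), p2.param_items()):
        assert n1 == n2 and np.array_equal(a1, a2)
    assert any(not np.array_equal(a1, a3) for (_, a1), (_, a3)
               in zip(p1.param_items(), p3.param_items()))
    assert all(layer.V.shape == (6, 6) for layer in p1.layers)
    with pytest.raises(ValueError):
        m.init_params((5, 0, 0), c=0)


def test_residual_identity_all_layers(sample_smiles):
    # zeroing every V makes the final atom states equal the initial hidden ones
    cfg = m.FeatureConfig(level=3)
    p = tiny_params(*m.feature_dimensions(cfg), k=5, seed=11)
    for layer in p.layers:
        layer.V[...] = 0.0
    for s in sample_smiles[:6]:
        g = m.build_graph(s, cfg)
        A = m.initial_hidden(g.atom_features, p)
        out = A
        for layer in p.layers:
            out = m.conv_step(g, out, layer, p.leaky_slope)
        assert np.array_equal(out, A)


# ------------------------------------------------------------------ gradients


def test_analytic_gradients_match_finite_differences():
    cfg = m.FeatureConfig(level=3)
    graphs = [m.build_graph(s, cfg, labels=[y, 1 - y])
              for s, y in [("CCO", 1), ("c1ccccc1", 0), ("CC(=O)NC", 1)]]
    p = m.init_params(m.feature_dimensions(cfg), c=2, k=4, h=4, m=2, seed=3)
    batch = m.pack_graphs(graphs)

    def total_loss():
        probs, _ = m.batch_forward(batch, p, mode="eval")
        return m.bce_loss(batch.labels, probs, batch.mask)

    probs, cache = m.batch_forward(batch, p, mode="eval")
    grads = m.batch_backward(batch, p, cache,
                             m.bce_logit_grad(batch.labels, probs, batch.mask))
    eps = 1e-5
    for name, arr in p.param_items():
        fd = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + eps
            up = total_loss()
            arr[ix] = orig - eps
            down = total_loss()
            arr[ix] = orig
            fd[ix] = (up - down) / (2 * eps)
        rel = (np.linalg.norm(grads[name] - fd)
               / max(np.linalg.norm(grads[name]) + np.linalg.norm(fd), 1e-12))
        assert rel < 1e-4, f"{name}: rel err {rel:.2e}"


# ----------------------------------------------------------------- checkpoint


def test_checkpoint_roundtrip(tmp_path):
    cfg = m.FeatureConfig(level=5)
    p = tiny_params(*m.feature_dimensions(cfg), seed=13)
    p.fingerprint = cfg.fingerprint()
    p.mol_standardization = (np.array([100.0, 0.0, 1.0]), np.array([50.0, 1.0, 2.0]))
    path = tmp_path / "ckpt.npz"
    m.save_checkpoint(p, path)
    q = m.load_checkpoint(path, expected_fingerprint=cfg.fingerprint())
    for (n1, a1), (n2, a2) in zip(p.param_items(), q.param_items()):
        assert n1 == n2 and np.array_equal(a1, a2)
    assert np.array_equal(q.mol_standardization[0], p.mol_standardization[0])
    g = m.build_graph("CC(=O)NC", cfg)
    assert np.array_equal(m.forward(g, p), m.forward(g, q))
    with pytest.raises(ValueError):
        m.load_checkpoint(path,
                          expected_fingerprint=m.FeatureConfig(level=1).fingerprint())
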