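"""Complex graph construction, the toy denoiser networks and their gradients."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from rnacodesign.cg_io import CGProteinStructure
from rnacodesign.models import (ModelConfig, SequenceDenoiser,
                                StructurePredictor, build_complex_graph,
                                cross_entropy_seq, load_checkpoint,
                                save_checkpoint, softmax,
                                toy_sequence_denoiser, toy_structure_predictor)
from rnacodesign.synthetic_data import GeneratorConfig, generate_complex


@pytest.fixture()
def toy_complex():
    return generate_complex(GeneratorConfig(), np.random.default_rng(1),
                            ident="toy")


def protein_from_ca(ca):
    """Minimal protein whose N/C beads sit right next to each CA."""
    ca = np.asarray(ca, dtype=float)
    coords = np.stack([ca - [0.5, 0, 0], ca, ca + [0.5, 0, 0]], axis=1)
    return CGProteinStructure("A" * len(ca), coords)


class TestComplexGraph:
    def test_collinear_nearest_neighbors(self):
        protein = protein_from_ca([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        rna_coords = np.zeros((1, 3, 3)) + 100.0  # far away, 4th node
        graph = build_complex_graph(protein, rna_coords, k=1)
        nbr = {int(s): int(d) for s, d in graph.edges}
        assert nbr[0] == 1  # endpoints pick the middle protein node
        assert nbr[2] == 1

    def test_edge_distances_match_bruteforce(self, toy_complex):
        graph = build_complex_graph(toy_complex.protein,
                                    toy_complex.rna.coords, k=4)
        d = cdist(graph.positions, graph.positions)
        for (src, dst), dist in zip(graph.edges, graph.edge_dist):
            assert dist == pytest.approx(d[src, dst], rel=1e-12)

    def test_complete_graph_at_max_k(self):
        protein = protein_from_ca(np.random.default_rng(0).normal(size=(4, 3)))
        rna_coords = np.random.default_rng(1).normal(size=(3, 3, 3)) + 20.0
        n = 7
        graph = build_complex_graph(protein, rna_coords, k=n - 1)
        assert len(graph.edges) == n * (n - 1)
        assert not np.any(graph.edges[:, 0] == graph.edges[:, 1])

    def test_topology_invariant_under_rigid_motion(self, toy_complex):
        g1 = build_complex_graph(toy_complex.protein, toy_complex.rna.coords,
                                 k=3)
        rot = Rotation.random(random_state=3).as_matrix()
        trans = np.array([7.0, -4.0, 2.0])

        def move(coords):
            return (coords.reshape(-1, 3) @ rot.T + trans).reshape(coords.shape)

        moved_protein = CGProteinStructure(
            toy_complex.protein.sequence, move(toy_complex.protein.coords))
        g2 = build_complex_graph(moved_protein, move(toy_complex.rna.coords),
                                 k=3)
        np.testing.assert_array_equal(g1.edges, g2.edges)
        np.testing.assert_allclose(g1.edge_dist, g2.edge_dist, atol=1e-9)

    def test_bad_k_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            build_complex_graph(toy_complex.protein, toy_complex.rna.coords,
                                k=0)
        n = len(toy_complex.protein) + len(toy_complex.rna)
        with pytest.raises(ValueError):
            build_complex_graph(toy_complex.protein, toy_complex.rna.coords,
                                k=n)


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        seq = "ACGU"
        logits = np.full((4, 4), -1e3)
        for i, c in enumerate(seq):
            logits[i, "ACGU".index(c)] = 1e3
        assert cross_entropy_seq(logits, seq) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_give_ln4(self):
        assert cross_entropy_seq(np.zeros((7, 4)), "ACGUACG") == \
            pytest.approx(np.log(4.0), rel=1e-12)

    def test_matches_direct_formula(self, rng):
        seq = "GCAUGCAU"
        logits = rng.normal(size=(8, 4))
        probs = softmax(logits)
        idx = ["ACGU".index(c) for c in seq]
        expected = -np.mean([np.log(probs[i, j]) for i, j in enumerate(idx)])
        assert cross_entropy_seq(logits, seq) == pytest.approx(expected,
                                                               rel=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy_seq(np.zeros((3, 4)), "ACGU")


class TestSequenceDenoiser:
    def test_seeded_init_is_bitwise_identical(self):
        a = toy_sequence_denoiser(seed=3)
        b = toy_sequence_denoiser(seed=3)
        for pa, pb in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(pa, pb)

    def test_output_shape_and_finiteness(self, toy_complex):
        model = toy_sequence_denoiser(seed=0)
        logits = model(toy_complex.rna.coords, toy_complex.protein)
        assert logits.shape == (len(toy_complex.rna), 4)
        assert np.all(np.isfinite(logits))

    def test_untrained_argmax_at_random_baseline(self):
        """Untrained predictions against random targets hit ~25%."""
        rng = np.random.default_rng(0)
        model = toy_sequence_denoiser(seed=1)
        hits = total = 0
        for i in range(60):
            cplx = generate_complex(GeneratorConfig(seed=0),
                                    np.random.default_rng(500 + i))
            logits = model(cplx.rna.coords, cplx.protein)
            pred = np.argmax(logits, axis=1)
            truth = rng.integers(0, 4, size=len(pred))
            hits += int(np.sum(pred == truth))
            total += len(pred)
        assert abs(hits / total - 0.25) < 0.05

    def test_param_gradients_match_finite_differences(self, toy_complex):
        model = toy_sequence_denoiser(ModelConfig(hidden=8), seed=2)
        truth = toy_complex.rna.sequence
        coords = toy_complex.rna.coords

        def loss(params=None):
            if params is not None:
                model.net.set_parameters(params)
            return cross_entropy_seq(model(coords, toy_complex.protein), truth)

        from rnacodesign.models import cross_entropy_grad
        logits = model(coords, toy_complex.protein)
        grads = model.backward(cross_entropy_grad(logits, truth))
        params = [p.copy() for p in model.net.parameters]
        eps = 1e-6
        for pi in (0, len(params) - 1):
            idx = (0,) * params[pi].ndim
            up = [p.copy() for p in params]
            dn = [p.copy() for p in params]
            up[pi][idx] += eps
            dn[pi][idx] -= eps
            fd = (loss(up) - loss(dn)) / (2 * eps)
            assert grads[pi][idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestStructurePredictor:
    def test_zero_init_head_is_identity(self, toy_complex):
        model = toy_structure_predictor(ModelConfig(init_scale=0.0), seed=0)
        soft = np.full((len(toy_complex.rna), 4), 0.25)
        out = model(soft, toy_complex.protein, toy_complex.rna.coords)
        np.testing.assert_allclose(out, toy_complex.rna.coords, atol=1e-12)

    def test_seeded_reproducibility(self, toy_complex):
        a = toy_structure_predictor(seed=4)
        b = toy_structure_predictor(seed=4)
        soft = np.full((len(toy_complex.rna), 4), 0.25)
        np.testing.assert_array_equal(
            a(soft, toy_complex.protein, toy_complex.rna.coords),
            b(soft, toy_complex.protein, toy_complex.rna.coords))

    def test_backward_matches_finite_differences(self, toy_complex):
        model = toy_structure_predictor(ModelConfig(hidden=8), seed=5)
        lr = len(toy_complex.rna)
        rng = np.random.default_rng(0)
        soft = rng.dirichlet(np.ones(4), size=lr)
        coords = rng.normal(size=(lr, 3, 3))
        target = rng.normal(size=(lr, 3, 3))

        def loss(c=coords, s=soft):
            out = model(s, toy_complex.protein, c)
            model.pop_cache()
            return 0.5 * np.sum((out - target) ** 2)

        out = model(soft, toy_complex.protein, coords)
        _, g_coords, g_seq = model.backward(out - target)
        eps = 1e-6
        for idx in [(0, 0, 0), (3, 1, 2), (lr - 1, 2, 1)]:
            up, dn = coords.copy(), coords.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (loss(c=up) - loss(c=dn)) / (2 * eps)
            assert g_coords[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        for idx in [(0, 0), (4, 3)]:
            up, dn = soft.copy(), soft.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (loss(s=up) - loss(s=dn)) / (2 * eps)
            assert g_seq[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestOverfitCapacity:
    """Both toy networks drive their overfit tests home in CPU-seconds —
    guards against silently broken gradients."""

    def test_sequence_overfit_five_complexes(self, sdfe):
        from rnacodesign.evaluation import sequence_recovery
        from rnacodesign.pipeline import TrainingConfig, design, train
        from rnacodesign.synthetic_data import generate_dataset

        dataset = generate_dataset(GeneratorConfig(n_complexes=5, seed=12))
        config = TrainingConfig(epochs=500, batch_size=5, seed=1,
                                learning_rate=0.02)
        seq_model, struct_model, _ = train(dataset, [], config, sdfe=sdfe)
        recs = [sequence_recovery(
            design(c.protein, len(c.rna), seq_model, struct_model, seed=i)[0],
            c.rna.sequence) for i, c in enumerate(dataset)]
        assert np.mean(recs) > 0.9

    def test_structure_overfit_single_complex(self, sdfe):
        from rnacodesign.geometry import aligned_rmsd
        from rnacodesign.pipeline import TrainingConfig, design, train
        from rnacodesign.synthetic_data import generate_dataset

        dataset = generate_dataset(GeneratorConfig(n_complexes=1, seed=11))
        config = TrainingConfig(epochs=2000, batch_size=1, seed=0,
                                learning_rate=0.05)
        seq_model, struct_model, _ = train(dataset, [], config, sdfe=sdfe)
        _, structure = design(dataset[0].protein, len(dataset[0].rna),
                              seq_model, struct_model, seed=0)
        assert aligned_rmsd(structure.coords, dataset[0].rna.coords) < 0.5


class TestCheckpoints:
    def test_round_trip(self, tmp_path, toy_complex):
        seq = toy_sequence_denoiser(seed=6)
        struct = toy_structure_predictor(seed=7)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, seq, struct, extra={"note": "test"})
        seq2, struct2, extra = load_checkpoint(path)
        assert extra == {"note": "test"}
        soft = np.full((len(toy_complex.rna), 4), 0.25)
        np.testing.assert_array_equal(
            seq(toy_complex.rna.coords, toy_complex.protein),
            seq2(toy_complex.rna.coords, toy_complex.protein))
        np.testing.assert_array_equal(
            struct(soft, toy_complex.protein, toy_complex.rna.coords),
            struct2(soft, toy_complex.protein, toy_complex.rna.coords))
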