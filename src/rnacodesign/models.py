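"""Pluggable denoiser contracts and small trainable reference networks.

Two learned components drive the co-design loop:

* a :class:`SequenceDenoiser` — inverse-folding head mapping (noisy RNA bead
  coordinates, protein context) to per-position nucleotide logits;
* a :class:`StructurePredictor` — refinement head mapping (sequence
  encoding, protein context, current RNA coordinates) to updated
  coordinates, residually parameterized so the identity map is reachable.

The reference implementations are deliberately small per-node numpy MLPs
over features of the protein-RNA k-nearest-neighbor graph; they exist to
exercise the training and refinement machinery on a CPU in seconds, not to
have the capacity of a full geometric network.  Both honor a shape contract
so that heavier architectures can be dropped in unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.spatial.distance import cdist

from .cg_io import CGProteinStructure
from .nnet import MLP

RNA_TOKENS = "ACGU"


# ---------------------------------------------------------------------------
# classification utilities
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_seq(logits: np.ndarray, truth: str) -> float:
    """Mean per-position categorical cross-entropy of softmax(logits)
    against a hard token string."""
    logits = np.asarray(logits, dtype=float)
    if logits.shape != (len(truth), 4):
        raise ValueError(f"logits shape {logits.shape} != ({len(truth)}, 4)")
    idx = np.array([RNA_TOKENS.index(c) for c in truth])
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(len(truth)), idx].mean())


def cross_entropy_grad(logits: np.ndarray, truth: str) -> np.ndarray:
    """d cross_entropy_seq / d logits, shape (Lr, 4)."""
    idx = np.array([RNA_TOKENS.index(c) for c in truth])
    p = softmax(logits)
    p[np.arange(len(truth)), idx] -= 1.0
    return p / len(truth)


# ---------------------------------------------------------------------------
# the protein-RNA graph
# ---------------------------------------------------------------------------

@dataclass
class ComplexGraph:
    """k-nearest-neighbor graph over protein CA and RNA C4' nodes.

    Edges are directed: ``edges[e] = (i, j)`` means j is one of i's k
    nearest neighbors.  ``node_is_protein`` flags node type; node order is
    all protein residues first, then all RNA residues, each carrying its
    within-chain residue index in ``node_residue_index``.
    """

    positions: np.ndarray
    node_is_protein: np.ndarray
    node_residue_index: np.ndarray
    edges: np.ndarray
    edge_dist: np.ndarray
    edge_unit: np.ndarray
    edge_same_molecule: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")


def build_complex_graph(protein: CGProteinStructure, rna_coords,
                        k: int = 3) -> ComplexGraph:
    """kNN graph by Euclidean distance over the mixed CA/C4' node set."""
    rna_coords = np.asarray(rna_coords, dtype=float)
    ca = np.asarray(protein.coords, dtype=float)[:, 1]
    c4 = rna_coords[:, 1]
    positions = np.vstack([ca, c4])
    n = positions.shape[0]
    if n < 2:
        raise ValueError("graph needs at least 2 nodes")
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < {n}")

    d = cdist(positions, positions)
    np.fill_diagonal(d, np.inf)
    nbr = np.argsort(d, axis=1, kind="stable")[:, :k]
    src = np.repeat(np.arange(n), k)
    dst = nbr.reshape(-1)
    dist = d[src, dst]
    unit = (positions[dst] - positions[src]) / dist[:, None]
    is_protein = np.concatenate(
        [np.ones(len(ca), dtype=bool), np.zeros(len(c4), dtype=bool)])
    residue_index = np.concatenate(
        [np.arange(len(ca)), np.arange(len(c4))])
    return ComplexGraph(
        positions=positions,
        node_is_protein=is_protein,
        node_residue_index=residue_index,
        edges=np.stack([src, dst], axis=1),
        edge_dist=dist,
        edge_unit=unit,
        edge_same_molecule=is_protein[src] == is_protein[dst],
        k=k,
    )


# ---------------------------------------------------------------------------
# shared feature helpers
# ---------------------------------------------------------------------------

_PE_PERIODS = (2.0, 4.0, 8.0, 16.0, 32.0)


def _positional_encoding(lr: int) -> np.ndarray:
    i = np.arange(lr)[:, None]
    cols = []
    for period in _PE_PERIODS:
        cols.append(np.sin(2 * np.pi * i / period))
        cols.append(np.cos(2 * np.pi * i / period))
    cols.append(i / max(lr, 1))
    return np.hstack(cols)  # (Lr, 11)


def _protein_summary(protein: CGProteinStructure) -> np.ndarray:
    ca = protein.coords[:, 1]
    centroid = ca.mean(axis=0)
    rg = np.sqrt(np.mean(np.sum((ca - centroid) ** 2, axis=1)))
    if len(ca) > 1:
        mean_pair = cdist(ca, ca)[np.triu_indices(len(ca), k=1)].mean()
    else:
        mean_pair = 0.0
    return np.array([len(ca) / 50.0, rg / 10.0, mean_pair / 10.0])


def _mapped_protein_index(lr: int, lp: int) -> np.ndarray:
    """Fractional index mapping RNA residue i to the protein residue that
    tracks it (both chains run along the interface in register)."""
    if lr == 1:
        return np.zeros(1, dtype=int)
    return np.round(np.arange(lr) * (lp - 1) / (lr - 1)).astype(int)


def _normalize(v, axis=-1):
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.maximum(n, 1e-9)


def _orientation_features(protein: CGProteinStructure) -> np.ndarray:
    """Per-protein-residue backbone orientation descriptors (Lp, 4):
    components of the N-CA and C-CA directions along the chain tangent and
    the radial direction from the chain centroid.  These capture how each
    residue's backbone is rotated about the chain axis — the channel
    through which an interface can be sequence-specific."""
    coords = protein.coords
    ca = coords[:, 1]
    centroid = ca.mean(axis=0)
    prev_idx = np.maximum(np.arange(len(ca)) - 1, 0)
    next_idx = np.minimum(np.arange(len(ca)) + 1, len(ca) - 1)
    tangent = _normalize(ca[next_idx] - ca[prev_idx])
    radial = _normalize(ca - centroid)
    v_n = _normalize(coords[:, 0] - ca)
    v_c = _normalize(coords[:, 2] - ca)
    return np.stack([
        np.sum(v_n * tangent, axis=1),
        np.sum(v_n * radial, axis=1),
        np.sum(v_c * tangent, axis=1),
        np.sum(v_c * radial, axis=1),
    ], axis=1)


# ---------------------------------------------------------------------------
# sequence denoiser
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    hidden: int = 64
    n_hidden_layers: int = 2
    k_neighbors: int = 3
    init_scale: float = 1.0  # scale of the output head at initialization
                             # (0 makes a residual predictor exactly identity)

    def __post_init__(self) -> None:
        if self.hidden < 1 or self.n_hidden_layers < 1:
            raise ValueError("hidden and n_hidden_layers must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.init_scale < 0:
            raise ValueError("init_scale must be >= 0")


class SequenceDenoiser:
    """Per-node feed-forward inverse-folding head over the complex graph.

    ``__call__(rna_coords, protein) -> (Lr, 4) logits``.  Features per RNA
    node: positional encoding, global protein summary, the backbone
    orientation descriptors of the protein residues tracking this position,
    and local graph statistics from the (noisy) RNA coordinates.
    """

    N_FEATURES = 11 + 3 + 12 + 3

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = seed
        sizes = [self.N_FEATURES] + \
            [self.config.hidden] * self.config.n_hidden_layers + [4]
        self.net = MLP(sizes, seed=seed, out_init_scale=1.0)
        self._cache = None

    # -- features ----------------------------------------------------------
    def featurize(self, rna_coords, protein: CGProteinStructure) -> np.ndarray:
        rna_coords = np.asarray(rna_coords, dtype=float)
        lr = rna_coords.shape[0]
        lp = len(protein)
        pe = _positional_encoding(lr)
        summary = np.tile(_protein_summary(protein), (lr, 1))

        orient = _orientation_features(protein)
        mapped = _mapped_protein_index(lr, lp)
        prev_m = np.maximum(mapped - 1, 0)
        next_m = np.minimum(mapped + 1, lp - 1)
        orient_feats = np.hstack(
            [orient[prev_m], orient[mapped], orient[next_m]])  # (Lr, 12)

        graph = build_complex_graph(protein, rna_coords,
                                    k=min(self.config.k_neighbors, lr + lp - 1))
        rna_node_offset = lp
        local = np.zeros((lr, 3))
        for i in range(lr):
            mask = graph.edges[:, 0] == rna_node_offset + i
            dst = graph.edges[mask, 1]
            dist = graph.edge_dist[mask]
            to_protein = graph.node_is_protein[dst]
            local[i, 0] = dist[to_protein].mean() / 10.0 if to_protein.any() else 1.0
            local[i, 1] = to_protein.mean() if len(dst) else 0.0
            local[i, 2] = dist[~to_protein].mean() / 10.0 if (~to_protein).any() else 1.0
        return np.hstack([pe, summary, orient_feats, local])

    # -- forward / backward ------------------------------------------------
    def __call__(self, rna_coords, protein: CGProteinStructure) -> np.ndarray:
        feats = self.featurize(rna_coords, protein)
        logits, cache = self.net.forward(feats)
        self._cache = cache
        return logits

    def backward(self, grad_logits: np.ndarray):
        """Parameter gradients for the most recent forward pass."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        param_grads, _ = self.net.backward(grad_logits, self._cache)
        return param_grads

    @property
    def parameters(self):
        return self.net.parameters


def toy_sequence_denoiser(config: ModelConfig | None = None,
                          seed: int = 0) -> SequenceDenoiser:
    return SequenceDenoiser(config=config, seed=seed)


# ---------------------------------------------------------------------------
# structure predictor
# ---------------------------------------------------------------------------

class StructurePredictor:
    """Residual per-residue coordinate refinement head.

    ``__call__(seq_soft, protein, coords) -> coords + delta`` where delta is
    an MLP over features of the current coordinates, the (soft) sequence and
    the protein context.  With a zero-initialized output head the map is
    exactly the identity.  ``backward`` returns gradients with respect to
    parameters, input coordinates and the soft sequence, enabling
    backpropagation through iterated self-application.
    """

    #: seq(4) + own beads(9) + prev(9) + next(9) + centroid diff(3)
    #: + mapped CA diff(3) + posenc(11) + protein summary(2)
    #: + mapped CA positions, prev/self/next (9) — protein-only anchors that
    #: let the head synthesize a backbone even from pure-noise input
    N_FEATURES = 4 + 9 + 9 + 9 + 3 + 3 + 11 + 2 + 9
    #: coordinate features enter unscaled so the linear skip can realize
    #: exact affine corrections such as "subtract the input coordinates"
    COORD_SCALE = 1.0

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = seed
        sizes = [self.N_FEATURES] + \
            [self.config.hidden] * self.config.n_hidden_layers + [9]
        self.net = MLP(sizes, seed=seed,
                       out_init_scale=self.config.init_scale,
                       linear_skip=True)
        self._cache = None

    def _features(self, seq_soft, protein, coords):
        coords = np.asarray(coords, dtype=float)
        lr = coords.shape[0]
        lp = len(protein)
        c4 = coords[:, 1]
        ca = protein.coords[:, 1]
        centroid = ca.mean(axis=0)
        mapped = _mapped_protein_index(lr, lp)

        own = coords.reshape(lr, 9) / self.COORD_SCALE
        prev = np.zeros((lr, 9))
        nxt = np.zeros((lr, 9))
        prev[1:] = coords[:-1].reshape(lr - 1, 9) / self.COORD_SCALE
        nxt[:-1] = coords[1:].reshape(lr - 1, 9) / self.COORD_SCALE
        cdiff = (centroid[None, :] - c4) / self.COORD_SCALE
        madiff = (ca[mapped] - c4) / self.COORD_SCALE
        pe = _positional_encoding(lr)
        summary = np.tile(_protein_summary(protein)[:2], (lr, 1))
        prev_m = np.maximum(mapped - 1, 0)
        next_m = np.minimum(mapped + 1, lp - 1)
        anchors = np.hstack([ca[prev_m], ca[mapped], ca[next_m]]) / self.COORD_SCALE
        seq_soft = np.asarray(seq_soft, dtype=float)
        if seq_soft.shape != (lr, 4):
            raise ValueError(f"seq encoding shape {seq_soft.shape} != ({lr}, 4)")
        return np.hstack([seq_soft, own, prev, nxt, cdiff, madiff, pe, summary,
                          anchors])

    def __call__(self, seq_soft, protein: CGProteinStructure,
                 coords) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        feats = self._features(seq_soft, protein, coords)
        delta, cache = self.net.forward(feats)
        self._cache = cache
        return coords + delta.reshape(coords.shape)

    def pop_cache(self):
        """Detach and return the cache of the most recent forward pass, for
        later use with :meth:`backward_from` (needed when the predictor is
        applied several times before backprop, as in iterated refinement)."""
        cache, self._cache = self._cache, None
        return cache

    def backward(self, grad_out: np.ndarray):
        """Backprop through the most recent forward pass.

        ``grad_out`` has the coords shape (Lr, 3, 3).  Returns
        (param_grads, grad_coords, grad_seq_soft).
        """
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        return self.backward_from(self._cache, grad_out)

    def backward_from(self, cache, grad_out: np.ndarray):
        """Backprop ``grad_out`` through a specific cached forward pass."""
        grad_out = np.asarray(grad_out, dtype=float)
        lr = grad_out.shape[0]
        g_delta = grad_out.reshape(lr, 9)
        param_grads, g_feats = self.net.backward(g_delta, cache)

        s = self.COORD_SCALE
        grad_coords = grad_out.copy()  # residual path
        g_seq = g_feats[:, 0:4].copy()
        # own coordinates (feature cols 4:13)
        grad_coords += g_feats[:, 4:13].reshape(lr, 3, 3) / s
        # prev-residue coords (cols 13:22): feature row i reads coords[i-1]
        grad_coords[:-1] += g_feats[1:, 13:22].reshape(lr - 1, 3, 3) / s
        # next-residue coords (cols 22:31): feature row i reads coords[i+1]
        grad_coords[1:] += g_feats[:-1, 22:31].reshape(lr - 1, 3, 3) / s
        # centroid diff (cols 31:34) and mapped-CA diff (34:37): both are
        # (protein - C4'), so d/dC4' = -1/s on the C4' bead only
        grad_coords[:, 1] -= g_feats[:, 31:34] / s
        grad_coords[:, 1] -= g_feats[:, 34:37] / s
        return param_grads, grad_coords, g_seq

    @property
    def parameters(self):
        return self.net.parameters


def toy_structure_predictor(config: ModelConfig | None = None,
                            seed: int = 0) -> StructurePredictor:
    return StructurePredictor(config=config, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, seq_model: SequenceDenoiser,
                    struct_model: StructurePredictor, extra: dict | None = None):
    """Serialize both models to a single .npz with config and seed records."""
    payload = {}
    for prefix, model in (("seq", seq_model), ("struct", struct_model)):
        for i, p in enumerate(model.parameters):
            payload[f"{prefix}_{i}"] = p
    meta = {
        "seq_config": asdict(seq_model.config), "seq_seed": seq_model.seed,
        "struct_config": asdict(struct_model.config),
        "struct_seed": struct_model.seed,
        "extra": extra or {},
    }
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns (seq_model, struct_model,
    extra_metadata)."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    seq = SequenceDenoiser(ModelConfig(**meta["seq_config"]),
                           seed=meta["seq_seed"])
    struct = StructurePredictor(ModelConfig(**meta["struct_config"]),
                                seed=meta["struct_seed"])
    for prefix, model in (("seq", seq), ("struct", struct)):
        params = [data[f"{prefix}_{i}"] for i in range(len(model.parameters))]
        model.net.set_parameters(params)
    return seq, struct, meta["extra"]
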