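"""Biophysical energy stack for CG RNA structures.

Three layers:

* a Lennard-Jones (LJ) excluded-volume/attraction term over non-bonded bead
  pairs, ``U_LJ(d) = 4*eps*[(sigma/d)^12 - (sigma/d)^6]``, zero at
  ``d = sigma`` and minimal (``-eps``) at ``d = sigma * 2^(1/6)``;
* a sequence-derived free energy (SDFE): a differentiable surrogate fitted to
  a folding free-energy oracle.  The default oracle is a deterministic
  nearest-neighbor proxy — a published dinucleotide stacking table plus a GC
  composition term — so the whole stack runs with no external tools.  Any
  callable ``sequence -> kcal/mol`` can be substituted as the training
  target;
* the combined refinement energy
  ``E = ||pred - target||^2 / (2*sigma_gauss^2) + alpha * U(pred, seq)``
  with the quadratic term evaluated after Kabsch alignment of the prediction
  onto the target, and its analytic gradient (exact at the optimal
  superposition by the envelope theorem; the LJ force is closed-form).

Energies are in kcal/mol by convention of the stacking table; the LJ well
depth default 0.2 and sigma 3.5 A follow the CG parameterization used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import kabsch_align

RNA_TOKENS = "ACGU"
_TOKEN_INDEX = {t: i for i, t in enumerate(RNA_TOKENS)}


@dataclass
class EnergyParams:
    """Parameters of the energy stack.

    epsilon : LJ well depth (kcal/mol), default 0.2.
    sigma_lj : LJ zero-crossing distance (A), default 3.5.
    sigma_gauss : width of the Gaussian structural term (A), default 1.0.
    alpha : weight on U inside the refinement energy E, default 0.1.
    beta : weight on U inside the training refinement loss, default 0.1.
    exclusion : minimum residue-index separation for LJ pairs, default 2
        (adjacent/bonded residues never contribute).
    cutoff : LJ distance cutoff (A), default 12.
    """

    epsilon: float = 0.2
    sigma_lj: float = 3.5
    sigma_gauss: float = 1.0
    alpha: float = 0.1
    beta: float = 0.1
    exclusion: int = 2
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma_lj <= 0 or self.sigma_gauss <= 0:
            raise ValueError("epsilon, sigma_lj, sigma_gauss must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.exclusion < 1:
            raise ValueError("exclusion must be >= 1")
        if self.cutoff <= self.sigma_lj:
            raise ValueError("cutoff must exceed sigma_lj")


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------

def lj_pair(d, params: EnergyParams):
    """LJ energy of a bead pair at distance ``d`` (scalar or array, A)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    s = params.sigma_lj / d
    s6 = s ** 6
    out = 4.0 * params.epsilon * (s6 * s6 - s6)
    return float(out) if out.ndim == 0 else out


def _lj_pair_force(d, params: EnergyParams):
    """dU/dd for the LJ pair term."""
    s6 = (params.sigma_lj / d) ** 6
    return 4.0 * params.epsilon * (-12.0 * s6 * s6 + 6.0 * s6) / d


def _bead_cloud(rna) -> tuple[np.ndarray, np.ndarray]:
    coords = np.asarray(getattr(rna, "coords", rna), dtype=float)
    if coords.ndim != 3 or coords.shape[1:] != (3, 3):
        raise ValueError("expected (L, 3, 3) bead coordinates")
    residue_index = np.repeat(np.arange(coords.shape[0]), 3)
    return coords.reshape(-1, 3), residue_index


def _qualifying_pairs(cloud, residue_index, params):
    d = cdist(cloud, cloud)
    i, j = np.triu_indices(cloud.shape[0], k=1)
    keep = (np.abs(residue_index[i] - residue_index[j]) >= params.exclusion) \
        & (d[i, j] <= params.cutoff)
    return i[keep], j[keep], d[i[keep], j[keep]]


def lj_total(rna, params: EnergyParams = EnergyParams()) -> float:
    """Sum of LJ pair energies over all bead pairs whose residues are at
    least ``exclusion`` apart and whose distance is within ``cutoff``."""
    cloud, residx = _bead_cloud(rna)
    if cloud.shape[0] < 6:
        raise ValueError("need at least 2 residues")
    i, j, d = _qualifying_pairs(cloud, residx, params)
    if len(d) == 0:
        return 0.0
    return float(np.sum(lj_pair(d, params)))


def lj_total_gradient(coords, params: EnergyParams = EnergyParams()) -> np.ndarray:
    """Analytic gradient of :func:`lj_total` with respect to the bead
    coordinates; same shape as ``coords``."""
    cloud, residx = _bead_cloud(coords)
    grad = np.zeros_like(cloud)
    i, j, d = _qualifying_pairs(cloud, residx, params)
    if len(d) > 0:
        force = _lj_pair_force(d, params)  # dU/dd per pair
        unit = (cloud[i] - cloud[j]) / d[:, None]
        np.add.at(grad, i, force[:, None] * unit)
        np.add.at(grad, j, -force[:, None] * unit)
    return grad.reshape(np.asarray(getattr(coords, "coords", coords)).shape)


# ---------------------------------------------------------------------------
# Sequence-derived free energy
# ---------------------------------------------------------------------------

def load_stacking_table() -> dict[str, float]:
    """The shipped dinucleotide stacking free-energy table (kcal/mol)."""
    table = {}
    text = resources.files("rnacodesign.data").joinpath(
        "stacking_energies.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dinuc, value = line.split("\t")
        table[dinuc] = float(value)
    return table


_STACKING = None


def _stacking_table() -> dict[str, float]:
    global _STACKING
    if _STACKING is None:
        _STACKING = load_stacking_table()
    return _STACKING


#: kcal/mol added per G or C nucleotide by the default oracle; a mild
#: composition bonus on top of the stacking sum (GC-rich = more stable).
GC_COMPOSITION_COEFF = -0.1


def nn_free_energy_oracle(sequence: str,
                          gc_coeff: float = GC_COMPOSITION_COEFF) -> float:
    """Deterministic nearest-neighbor free-energy proxy (kcal/mol).

    Sum of the stacking-table entries over adjacent dinucleotides plus
    ``gc_coeff`` per G/C nucleotide.  More negative = more stable; GC-rich
    sequences score lower than AU-rich ones of the same length.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = [c for c in sequence if c not in _TOKEN_INDEX]
    if bad:
        raise ValueError(f"illegal RNA tokens {bad!r}")
    table = _stacking_table()
    stack = sum(table[sequence[i:i + 2]] for i in range(len(sequence) - 1))
    gc = sum(1 for c in sequence if c in "GC")
    return stack + gc_coeff * gc


def sequence_to_soft(sequence: str) -> np.ndarray:
    """Exact one-hot (L, 4) encoding of a hard sequence, token order ACGU."""
    soft = np.zeros((len(sequence), 4))
    for i, c in enumerate(sequence):
        soft[i, _TOKEN_INDEX[c]] = 1.0
    return soft


def _soft_features(soft: np.ndarray) -> np.ndarray:
    """17 composition features of a soft encoding: 16 expected dinucleotide
    counts (outer products of adjacent position probabilities) + expected
    G/C count.  Linear-quadratic in the encoding, hence differentiable."""
    soft = np.asarray(soft, dtype=float)
    di = np.einsum("ia,ib->ab", soft[:-1], soft[1:]).reshape(16)
    gc = soft[:, 1].sum() + soft[:, 2].sum()  # C and G columns
    return np.concatenate([di, [gc]])


@dataclass
class SDFEModel:
    """Differentiable sequence -> free-energy surrogate.

    A linear regressor over dinucleotide/GC composition features, fitted by
    least squares against a folding free-energy oracle.  Because the feature
    map is polynomial in the soft one-hot encoding, predictions and their
    gradients with respect to the encoding are closed-form, which lets the
    surrogate participate in the refinement loss gradient.
    """

    weights: np.ndarray
    bias: float
    oracle_name: str = "nn_free_energy_oracle"
    heldout_rmse: float = float("nan")

    def predict_soft(self, soft: np.ndarray) -> float:
        if soft.shape[0] < 2:
            raise ValueError("sequence must have length >= 2")
        return float(self._soft_value(soft))

    def _soft_value(self, soft):
        return _soft_features(soft) @ self.weights + self.bias

    def predict(self, sequence) -> float:
        """Accepts a hard token string or a soft (L, 4) encoding."""
        if isinstance(sequence, str):
            return self.predict_soft(sequence_to_soft(sequence))
        return self.predict_soft(np.asarray(sequence, dtype=float))

    __call__ = predict

    def gradient_soft(self, soft: np.ndarray) -> np.ndarray:
        """d prediction / d soft encoding, shape (L, 4)."""
        soft = np.asarray(soft, dtype=float)
        w_di = self.weights[:16].reshape(4, 4)
        w_gc = self.weights[16]
        grad = np.zeros_like(soft)
        # d(sum_i p_i^T W p_{i+1}) / dp
        grad[:-1] += soft[1:] @ w_di.T
        grad[1:] += soft[:-1] @ w_di
        grad[:, 1] += w_gc  # C
        grad[:, 2] += w_gc  # G
        return grad


def fit_sdfe(sequences, oracle=nn_free_energy_oracle, seed: int = 0,
             heldout_fraction: float = 0.2, ridge: float = 1e-8) -> SDFEModel:
    """Fit the SDFE surrogate to ``oracle`` on ``sequences``.

    Requires at least 100 sequences; a seeded held-out split records the
    generalization RMSE on the model.  The fit itself is deterministic
    (regularized least squares), so identical seeds give identical models.
    """
    sequences = list(sequences)
    if len(sequences) < 100:
        raise ValueError("need at least 100 training sequences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequences))
    n_hold = max(1, int(round(heldout_fraction * len(sequences))))
    hold_idx = set(order[:n_hold].tolist())

    feats = np.array([_soft_features(sequence_to_soft(s)) for s in sequences])
    y = np.array([oracle(s) for s in sequences])
    train = np.array([i not in hold_idx for i in range(len(sequences))])

    x = np.hstack([feats[train], np.ones((train.sum(), 1))])
    a = x.T @ x + ridge * np.eye(x.shape[1])
    b = x.T @ y[train]
    sol = np.linalg.solve(a, b)
    weights, bias = sol[:-1], float(sol[-1])

    x_hold = np.hstack([feats[~train], np.ones(((~train).sum(), 1))])
    resid = x_hold @ sol - y[~train]
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return SDFEModel(weights=weights, bias=bias,
                     oracle_name=getattr(oracle, "__name__", "oracle"),
                     heldout_rmse=rmse)


# ---------------------------------------------------------------------------
# Combined energy and gradient
# ---------------------------------------------------------------------------

def total_physical_energy(rna, sequence, sdfe: SDFEModel,
                          params: EnergyParams = EnergyParams()) -> float:
    """U(structure, sequence) = LJ total + SDFE prediction (unit weights;
    alpha/beta scale U externally)."""
    return lj_total(rna, params) + sdfe.predict(sequence)


def energy_E(pred, target, sequence, sdfe: SDFEModel,
             params: EnergyParams = EnergyParams()) -> float:
    """Refinement energy of a predicted structure against its target.

    ``E = ||K(pred->target) - target||^2 / (2*sigma_gauss^2)
    + alpha * U(pred, sequence)`` where the norm is the plain sum of squared
    coordinate differences after Kabsch alignment of the prediction onto the
    target.
    """
    pc = np.asarray(getattr(pred, "coords", pred), dtype=float)
    tc = np.asarray(getattr(target, "coords", target), dtype=float)
    if pc.shape != tc.shape:
        raise ValueError(f"shape mismatch: {pc.shape} vs {tc.shape}")
    _, aligned = kabsch_align(pc.reshape(-1, 3), tc.reshape(-1, 3))
    quad = np.sum((aligned - tc.reshape(-1, 3)) ** 2)
    u = total_physical_energy(pc, sequence, sdfe, params)
    return float(quad / (2.0 * params.sigma_gauss ** 2) + params.alpha * u)


def energy_gradient(pred, target, sequence, sdfe: SDFEModel,
                    params: EnergyParams = EnergyParams()) -> np.ndarray:
    """Analytic gradient of :func:`energy_E` w.r.t. the predicted bead
    coordinates, in the prediction's own frame; shape equals ``pred``.

    The quadratic term's gradient is the aligned-frame residual rotated back
    by the optimal Kabsch rotation — exact despite the alignment's dependence
    on the prediction, because the superposition is optimal (envelope
    theorem).  The SDFE term does not depend on coordinates, so the U part of
    the gradient is the closed-form LJ force alone.
    """
    pc = np.asarray(getattr(pred, "coords", pred), dtype=float)
    tc = np.asarray(getattr(target, "coords", target), dtype=float)
    if pc.shape != tc.shape:
        raise ValueError(f"shape mismatch: {pc.shape} vs {tc.shape}")
    sup, aligned = kabsch_align(pc.reshape(-1, 3), tc.reshape(-1, 3))
    diff = aligned - tc.reshape(-1, 3)
    quad_grad = (diff @ sup.rotation) / params.sigma_gauss ** 2
    lj_grad = lj_total_gradient(pc, params)
    return quad_grad.reshape(pc.shape) + params.alpha * lj_grad
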