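"""Flow-matching machinery on CG RNA backbones.

A standard-Gaussian prior over bead coordinates is transported to the data
distribution along Kabsch-aligned linear interpolation paths
``Rt = (1 - t) * R0* + t * R1`` with ``R0* = K(R0, R1)`` the prior aligned
onto the target.  The training signal is the discrepancy between the true
vector field ``(R1 - Rt) / (1 - t)`` and the field implied by a denoiser's
endpoint prediction; after marginalizing over t this reduces to a
rigid-motion-invariant mean squared error between prediction and
Kabsch-aligned target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_align

#: guard against the 1/(1-t) singularity when sampling t during training
DEFAULT_T_MAX = 1.0 - 1e-3


@dataclass
class FlowState:
    """One point on an interpolation path.

    ``interpolant == (1 - t) * aligned_prior + t * target`` within 1e-6;
    all blocks share the (Lr, 3, 3) shape.
    """

    t: float
    prior: np.ndarray
    aligned_prior: np.ndarray
    interpolant: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        shapes = {x.shape for x in
                  (self.prior, self.aligned_prior, self.interpolant, self.target)}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent block shapes: {shapes}")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"t={self.t} outside [0, 1]")
        expected = (1.0 - self.t) * self.aligned_prior + self.t * self.target
        if not np.allclose(self.interpolant, expected, atol=1e-6):
            raise ValueError("interpolant is off the linear path")


def sample_prior(lr: int, seed) -> np.ndarray:
    """(Lr, 3, 3) i.i.d. standard-normal bead coordinates.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if lr < 1:
        raise ValueError("Lr must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.standard_normal((lr, 3, 3))


def make_flow_state(r0: np.ndarray, r1: np.ndarray, t: float) -> FlowState:
    """Align the prior draw onto the target and interpolate at time ``t``."""
    r0 = np.asarray(r0, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if r0.shape != r1.shape:
        raise ValueError(f"shape mismatch: {r0.shape} vs {r1.shape}")
    _, aligned = kabsch_align(r0.reshape(-1, 3), r1.reshape(-1, 3))
    aligned = aligned.reshape(r0.shape)
    interpolant = (1.0 - t) * aligned + t * r1
    return FlowState(t=float(t), prior=r0, aligned_prior=aligned,
                     interpolant=interpolant, target=r1)


def true_vector_field(state: FlowState) -> np.ndarray:
    """The conditional velocity ``(R1 - Rt) / (1 - t)``; on the linear path
    this is ``R1 - R0*`` independent of t.  Undefined at t == 1."""
    if state.t >= 1.0:
        raise ValueError("vector field undefined at t == 1")
    return (state.target - state.interpolant) / (1.0 - state.t)


def predicted_vector_field(f_out: np.ndarray, state: FlowState) -> np.ndarray:
    """Velocity implied by a denoiser's endpoint prediction ``f_out``."""
    if state.t >= 1.0:
        raise ValueError("vector field undefined at t == 1")
    f_out = np.asarray(f_out, dtype=float)
    if f_out.shape != state.interpolant.shape:
        raise ValueError("prediction shape mismatch")
    return (f_out - state.interpolant) / (1.0 - state.t)


def fm_loss(pred: np.ndarray, target: np.ndarray,
            align: str = "target_onto_pred") -> float:
    """Rigid-motion-invariant flow-matching loss.

    Mean squared coordinate error after Kabsch alignment; by default the
    target is aligned onto the prediction (``align="pred_onto_target"``
    swaps the roles — the value is identical either way, since the optimal
    superposition residual is symmetric).  Mean is over all Lr*3*3 entries,
    making the scale length-independent.
    """
    p = np.asarray(pred, dtype=float).reshape(-1, 3)
    q = np.asarray(target, dtype=float).reshape(-1, 3)
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    if align == "target_onto_pred":
        _, aligned = kabsch_align(q, p)
        diff = p - aligned
    elif align == "pred_onto_target":
        _, aligned = kabsch_align(p, q)
        diff = aligned - q
    else:
        raise ValueError(f"unknown align mode {align!r}")
    return float(np.mean(diff ** 2))


def fm_loss_gradient(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Gradient of :func:`fm_loss` (default alignment) w.r.t. ``pred``.

    With the target aligned onto the prediction, the optimal-superposition
    residual makes the gradient simply ``2 * (pred - aligned_target) / n``
    (envelope theorem); shape equals ``pred``.
    """
    p = np.asarray(pred, dtype=float)
    q = np.asarray(target, dtype=float)
    flat_p = p.reshape(-1, 3)
    _, aligned = kabsch_align(q.reshape(-1, 3), flat_p)
    n = flat_p.size
    return (2.0 * (flat_p - aligned) / n).reshape(p.shape)
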