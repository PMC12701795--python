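"""End-to-end training and inference.

Training alternates stochastically between two phases, decided by a coin
flip with probability ``phase_ratio`` each step:

* **flow-matching phase** — sample a Gaussian prior backbone, Kabsch-align
  it to the target, interpolate at a uniform t, predict sequence logits and
  an endpoint structure, and minimize the aligned MSE plus sequence
  cross-entropy;
* **refinement phase** — additionally feed the predicted structure back
  through the structure predictor k ~ randint(1, Kmax) times, and minimize
  the mean aligned MSE over the whole refinement list plus
  ``beta * U(final iterate, soft sequence)`` plus cross-entropy.  This
  drives the predictor toward an idempotent map whose fixed point sits at a
  low-energy structure.

Inference is a single forward pass: prior noise -> sequence denoiser ->
argmax tokens -> structure predictor; no refinement iterations.  An optional
gradient-descent polish on the refinement energy is available but off by
default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .cg_io import CGProteinStructure, CGRNAStructure
from .energy import (EnergyParams, SDFEModel, fit_sdfe, lj_total_gradient,
                     nn_free_energy_oracle, sequence_to_soft,
                     total_physical_energy)
from .flow_matching import (DEFAULT_T_MAX, fm_loss, fm_loss_gradient,
                            make_flow_state, sample_prior)
from .geometry import aligned_rmsd
from .models import (SequenceDenoiser, StructurePredictor, cross_entropy_grad,
                     cross_entropy_seq, softmax)
from .nnet import Adam

RNA_TOKENS = "ACGU"


@dataclass
class TrainingConfig:
    kmax: int = 4
    phase_ratio: float = 0.5  # probability of taking the refinement branch
    alpha: float = 0.1
    beta: float = 0.1
    sigma_gauss: float = 1.0
    learning_rate: float = 0.01
    lr_decay: str = "cosine"  # "cosine" anneal to ~0 over the run, or "none"
    epochs: int = 10
    batch_size: int = 4
    seed: int = 0
    t_max: float = DEFAULT_T_MAX
    bptt_window: int = 2  # refinement applications to backprop through
    include_initial: bool = True  # initial prediction enters the refinement list
    refine_tolerance: float = 0.01
    grad_clip: float = 10.0  # max global gradient norm per model per step
                             # (the LJ r^-12 wall makes raw gradients
                             # unbounded on clashing iterates)
    lj_force_cap: float = 1.0  # per-bead cap on the LJ force entering the
                               # refinement gradient; keeps the r^-12 wall
                               # from drowning the structural signal while
                               # preserving its push-apart direction
    energy_on: str = "final"  # "final": beta*U on the last iterate only;
                              # "all": beta * mean of U over the refinement
                              # list (exposed alternative reading)
    loss_alignment: str = "none"  # structural-term frame during training:
    # "none" = plain squared error in the example frame (the prior is already
    # Kabsch-aligned onto the target, so the whole example shares one frame;
    # this is the literal per-step objective and pins refinement iterates to
    # the target's frame, which is what makes idempotency learnable);
    # "kabsch" = re-align the target onto each prediction (the marginalized,
    # rigid-invariant form).

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_ratio <= 1.0:
            raise ValueError("phase_ratio must be in [0, 1]")
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.t_max < 1.0:
            raise ValueError("t_max must be in (0, 1)")

    def energy_params(self) -> EnergyParams:
        return EnergyParams(alpha=self.alpha, beta=self.beta,
                            sigma_gauss=self.sigma_gauss)

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class StepRecord:
    phase: str  # "fm" or "refine"
    loss: float
    cross_entropy: float
    energy_term: float
    k: int


@dataclass
class TrainLog:
    steps: list = field(default_factory=list)
    epochs: list = field(default_factory=list)  # dicts with val metrics

    @property
    def refine_fraction(self) -> float:
        if not self.steps:
            return float("nan")
        return float(np.mean([s.phase == "refine" for s in self.steps]))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tphase\tloss\tcross_entropy\tenergy_term\tk\n")
            for i, s in enumerate(self.steps):
                fh.write(f"{i}\t{s.phase}\t{s.loss:.6f}\t{s.cross_entropy:.6f}"
                         f"\t{s.energy_term:.6f}\t{s.k}\n")


def _softmax_vjp(soft: np.ndarray, grad_soft: np.ndarray) -> np.ndarray:
    """Pull a gradient on softmax outputs back to the logits."""
    inner = np.sum(grad_soft * soft, axis=1, keepdims=True)
    return soft * (grad_soft - inner)


def _clip(grads, max_norm: float):
    if max_norm <= 0:
        return grads
    norm = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads))
    if norm > max_norm:
        scale = max_norm / norm
        grads = [g * scale for g in grads]
    return grads


def _zero_like_params(model):
    return [np.zeros_like(p) for p in model.parameters]


def _structural_term(pred, target, mode: str):
    """Mean squared structural error and its gradient w.r.t. ``pred``."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if mode == "kabsch":
        return fm_loss(pred, target), fm_loss_gradient(pred, target)
    if mode == "none":
        diff = pred - target
        return float(np.mean(diff ** 2)), 2.0 * diff / diff.size
    raise ValueError(f"unknown loss_alignment {mode!r}")


def _accumulate(acc, grads, scale=1.0):
    for a, g in zip(acc, grads):
        a += scale * g


def train_step(batch, seq_model: SequenceDenoiser,
               struct_model: StructurePredictor, sdfe: SDFEModel,
               config: TrainingConfig, rng: np.random.Generator,
               seq_opt: Adam, struct_opt: Adam) -> StepRecord:
    """One alternating-phase update on a batch of complexes.

    The phase coin and (in the refinement phase) the step count k are drawn
    once per step; losses and gradients are averaged over the batch before a
    single optimizer update per model.
    """
    if not batch:
        raise ValueError("empty batch")
    params = config.energy_params()
    m = rng.uniform()
    refine_phase = m <= config.phase_ratio
    k = int(rng.integers(1, config.kmax + 1)) if refine_phase else 0

    seq_grads = _zero_like_params(seq_model)
    struct_grads = _zero_like_params(struct_model)
    total_loss = total_ce = total_energy = 0.0

    for cplx in batch:
        r1 = cplx.rna.coords
        lr = len(cplx.rna)
        r0 = sample_prior(lr, rng)
        t = rng.uniform(0.0, config.t_max)
        state = make_flow_state(r0, r1, t)

        logits = seq_model(state.interpolant, cplx.protein)
        soft = softmax(logits)
        pred = struct_model(soft, cplx.protein, state.interpolant)
        cache0 = struct_model.pop_cache()

        ce = cross_entropy_seq(logits, cplx.rna.sequence)
        g_logits = cross_entropy_grad(logits, cplx.rna.sequence)
        g_soft = np.zeros_like(soft)

        if not refine_phase:
            sval, g_pred = _structural_term(pred, r1, config.loss_alignment)
            loss = sval + ce
            energy_term = 0.0
            pg, _, g_seq = struct_model.backward_from(cache0, g_pred)
            _accumulate(struct_grads, pg)
            g_soft += g_seq
        else:
            iterates = [pred]
            caches = [cache0]
            x = pred
            for _ in range(k):
                x = struct_model(soft, cplx.protein, x)
                caches.append(struct_model.pop_cache())
                iterates.append(x)
            listed = iterates if config.include_initial else iterates[1:]
            n_list = len(listed)
            offset = 0 if config.include_initial else 1
            energy_term = params.beta * total_physical_energy(
                iterates[-1], soft, sdfe, params)
            structural = 0.0
            # gradient injections at each listed iterate, truncated backprop
            for pos, it in enumerate(listed):
                j = pos + offset  # iterate index (0 = initial prediction)
                sval, g_struct = _structural_term(it, r1,
                                                  config.loss_alignment)
                structural += sval / n_list
                inject = g_struct / n_list
                on_all = config.energy_on == "all"
                if j == k or on_all:  # iterate(s) carrying the LJ force
                    lj_g = lj_total_gradient(it, params)
                    if config.lj_force_cap > 0:
                        norms = np.linalg.norm(lj_g.reshape(-1, 3),
                                               axis=1).reshape(-1, 1)
                        scale = np.minimum(1.0, config.lj_force_cap /
                                           np.maximum(norms, 1e-12))
                        lj_g = (lj_g.reshape(-1, 3) * scale).reshape(lj_g.shape)
                    inject = inject + params.beta * lj_g / (n_list if on_all
                                                            else 1)
                carry = inject
                lowest = max(j - config.bptt_window + 1, 0)
                for jj in range(j, lowest - 1, -1):
                    pg, carry, g_seq = struct_model.backward_from(
                        caches[jj], carry)
                    _accumulate(struct_grads, pg)
                    g_soft += g_seq
            # final iterate energy also depends on the soft sequence via SDFE
            g_soft += params.beta * sdfe.gradient_soft(soft)
            loss = structural + energy_term + ce

        g_logits = g_logits + _softmax_vjp(soft, g_soft)
        _accumulate(seq_grads, seq_model.backward(g_logits))

        total_loss += loss
        total_ce += ce
        total_energy += energy_term

    n = len(batch)
    if not np.isfinite(total_loss):
        raise FloatingPointError(
            f"non-finite loss {total_loss}; phase="
            f"{'refine' if refine_phase else 'fm'}, k={k}")
    seq_opt.step(_clip([g / n for g in seq_grads], config.grad_clip))
    struct_opt.step(_clip([g / n for g in struct_grads], config.grad_clip))
    return StepRecord(phase="refine" if refine_phase else "fm",
                      loss=total_loss / n, cross_entropy=total_ce / n,
                      energy_term=total_energy / n, k=k)


def _validate(seq_model, struct_model, complexes, seed: int):
    """Mean aligned RMSD and recovery of single-pass designs."""
    rmsds, recs = [], []
    for i, cplx in enumerate(complexes):
        tokens, structure = design(cplx.protein, len(cplx.rna),
                                   seq_model, struct_model,
                                   seed=(seed * 31 + i) % (2 ** 31))
        rmsds.append(aligned_rmsd(structure.coords, cplx.rna.coords))
        recs.append(np.mean([a == b for a, b in
                             zip(tokens, cplx.rna.sequence)]))
    return float(np.mean(rmsds)), float(np.mean(recs))


def train(train_set, val_set, config: TrainingConfig,
          sdfe: SDFEModel | None = None,
          seq_model: SequenceDenoiser | None = None,
          struct_model: StructurePredictor | None = None):
    """Run the alternating-phase loop over epochs of the training set.

    Returns (seq_model, struct_model, TrainLog) with the models restored to
    the parameters of the best validation aligned-RMSD epoch.  Everything is
    driven by ``config.seed`` and fully reproducible.
    """
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    seq_model = seq_model or SequenceDenoiser(seed=config.seed)
    struct_model = struct_model or StructurePredictor(seed=config.seed + 1)
    if sdfe is None:
        sdfe = default_sdfe(seed=config.seed)
    seq_opt = Adam(seq_model.parameters, lr=config.learning_rate)
    struct_opt = Adam(struct_model.parameters, lr=config.learning_rate)

    log = TrainLog()
    best = None
    order = np.arange(len(train_set))
    steps_per_epoch = int(np.ceil(len(train_set) / config.batch_size))
    total_steps = max(1, config.epochs * steps_per_epoch)
    step = 0
    for epoch in range(config.epochs):
        rng.shuffle(order)
        for start in range(0, len(order), config.batch_size):
            if config.lr_decay == "cosine":
                lr_now = config.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step / total_steps))
                seq_opt.lr = struct_opt.lr = max(lr_now,
                                                 1e-4 * config.learning_rate)
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            log.steps.append(train_step(batch, seq_model, struct_model, sdfe,
                                        config, rng, seq_opt, struct_opt))
            step += 1
        if val_set:
            val_rmsd, val_rec = _validate(seq_model, struct_model, val_set,
                                          seed=config.seed + epoch)
            log.epochs.append({"epoch": epoch, "val_rmsd": val_rmsd,
                               "val_recovery": val_rec})
            if best is None or val_rmsd < best[0]:
                best = (val_rmsd,
                        [p.copy() for p in seq_model.parameters],
                        [p.copy() for p in struct_model.parameters])
    if best is not None:
        seq_model.net.set_parameters(best[1])
        struct_model.net.set_parameters(best[2])
    return seq_model, struct_model, log


def default_sdfe(seed: int = 0, n_sequences: int = 500) -> SDFEModel:
    """SDFE surrogate fitted to the nearest-neighbor oracle on seeded random
    sequences of length 10-30."""
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list(RNA_TOKENS),
                               size=rng.integers(10, 31)))
            for _ in range(n_sequences)]
    return fit_sdfe(seqs, nn_free_energy_oracle, seed=seed)


def design(protein: CGProteinStructure, target_length: int,
           seq_model: SequenceDenoiser, struct_model: StructurePredictor,
           seed: int = 0, polish_steps: int = 0,
           polish_lr: float = 0.0) -> tuple[str, CGRNAStructure]:
    """Single-forward-pass protein-conditioned design.

    Prior noise -> sequence logits -> argmax tokens -> structure predictor.
    No refinement iterations.  ``polish_steps > 0`` optionally descends the
    LJ energy gradient on the output coordinates (off by default).
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    rng = np.random.default_rng(seed)
    r0 = sample_prior(target_length, rng)
    logits = seq_model(r0, protein)
    tokens = "".join(RNA_TOKENS[i] for i in np.argmax(logits, axis=1))
    coords = struct_model(sequence_to_soft(tokens), protein, r0)
    struct_model.pop_cache()
    if polish_steps > 0:
        for _ in range(polish_steps):
            coords = coords - polish_lr * lj_total_gradient(coords)
    return tokens, CGRNAStructure(sequence=tokens, coords=coords,
                                  id=f"design_{protein.id}")


def sample_designs(protein: CGProteinStructure, target_length: int,
                   seq_model: SequenceDenoiser,
                   struct_model: StructurePredictor,
                   n: int = 50, seed: int = 0):
    """``n`` independent designs with distinct sub-seeds (only the prior
    noise varies between samples)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for child in children:
        sub = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(design(protein, target_length, seq_model, struct_model,
                          seed=sub))
    return out
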