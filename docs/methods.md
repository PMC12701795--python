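# Methods

`rnacodesign` implements protein-conditioned RNA sequence–structure
co-design by combining flow matching over coarse-grained backbone
coordinates with an energy-guided, idempotent refinement objective. This
note describes the model, the numerical choices, what the synthetic data
emulates, and the limits of what the desk-scale experiments demonstrate.

## Representation

Both molecules are reduced to three backbone beads per monomer: RNA
nucleotides to (P, C4′, N1/N9) — N9 for purines, N1 for pyrimidines — and
protein residues to (N, Cα, C). A structure is an `(L, 3, 3)` array of
Cartesian coordinates in Å. All predictions and metrics operate in this
space; full-atom reconstruction is out of scope.

## Flow matching

A prior backbone `R0` is drawn from a standard Gaussian over bead
coordinates and Kabsch-aligned onto the target `R1`, giving `R0*`.
Training states are linear interpolants `Rt = (1−t) R0* + t R1` with
`t ~ U(0, 1−δ)`, δ = 1e−3 (the conditional velocity `(R1 − Rt)/(1−t)`
diverges at `t = 1`, so the endpoint is excluded). On the linear path the
conditional velocity is constant and equals `R1 − R0*`; marginalizing the
squared velocity discrepancy over `t` reduces the objective to a mean
squared error between the prediction and the Kabsch-aligned target. The
library exposes this rigid-invariant form as `fm_loss` (MSE over all
`L×3×3` entries, so the scale is length-independent; the alignment
direction — target-onto-prediction vs prediction-onto-target — is
configurable and provably yields the same value).

During *training* the structural term is, by default, the plain squared
error in the example's own frame (`loss_alignment="none"`): because the
prior is pre-aligned onto the target, the whole training example already
shares one frame, and this is the literal per-step objective of the
training algorithm. The distinction matters for idempotency: with
per-iterate re-alignment, rigid drift between successive refinement
iterates costs nothing and the learned map can translate/rotate structures
freely at its "fixed point"; the plain-frame loss pins iterates to the
target frame, which is what makes a measurable fixed point emerge.
`loss_alignment="kabsch"` selects the re-aligned form.

## Energy stack

`U(R, r) = U_LJ(R) + SDFE(r)`:

* **Lennard-Jones**, `U_LJ = Σ 4ε[(σ/d)^12 − (σ/d)^6]` over bead pairs with
  residue separation ≥ 2 within a 12 Å cutoff; ε = 0.2, σ = 3.5 Å. Zero at
  `d = σ`, minimum −ε at `d = σ·2^(1/6) ≈ 3.93 Å`. Bonded/adjacent residues
  are excluded so covalent geometry is never penalized.
* **Sequence-derived free energy (SDFE)**: a differentiable surrogate of an
  RNA folding free-energy oracle. The shipped oracle is a deterministic
  nearest-neighbor proxy — a published dinucleotide stacking ΔG°37 table
  (16 entries, TSV resource) plus −0.1 kcal/mol per G/C nucleotide — and
  the surrogate is a least-squares regressor over soft dinucleotide/GC
  composition counts. Because those counts are polynomial in the soft
  one-hot encoding, predictions and gradients w.r.t. the encoding are
  closed-form, which is what lets sequence logits receive energy gradients.
  Any callable `sequence → kcal/mol` can replace the oracle at fit time.
  (The proxy oracle is itself linear in the features, so the surrogate fits
  it essentially exactly; with a richer oracle the held-out RMSE recorded
  on the model becomes informative.)

The refinement energy is
`E = ‖K(R̂→R1) − R1‖² / (2σ_g²) + α·U(R̂, r̂)` with the quadratic term
evaluated after Kabsch alignment of the prediction onto the target. Its
gradient is analytic: the aligned-frame residual rotated back through the
optimal rotation (exact despite the alignment's dependence on `R̂`, by the
envelope theorem) plus the closed-form LJ force; the SDFE term carries no
coordinate dependence. The gradient is verified against central finite
differences in the tests. Defaults σ_g = 1 Å, α = β = 0.1 are package
choices, exposed in `EnergyParams`.

## Idempotent refinement

Training alternates two phases, chosen by a coin flip with probability
`phase_ratio` (default 0.5) per step:

* **flow-matching phase**: structural MSE of the one-shot prediction plus
  sequence cross-entropy;
* **refinement phase**: the structure predictor is re-applied to its own
  output `k ~ randint(1, Kmax)` times (inclusive; Kmax default 4). The loss
  averages the structural MSE over the refinement list — by default the
  initial prediction is included, giving `k+1` list entries
  (`include_initial=False` selects the alternative reading) — plus
  `β·U` on the final iterate only (`energy_on="all"` spreads it across the
  list) plus cross-entropy once.

This pushes the predictor toward a map whose fixed point sits at the
low-energy, target-like structure: once an iterate is right, re-applying
the predictor should leave it unchanged. The package measures this
directly as the `fixed_point_residual` — the RMS displacement a structure
suffers under one predictor application.

Backpropagation through the iterated predictor is truncated to the last
two applications per loss term by default (`bptt_window`; full
backpropagation is available). Three further numerical safeguards keep the
loop stable, all configurable: a per-bead cap (default 1.0) on the LJ
force entering the refinement gradient (the `r^−12` wall is unbounded on
clashing iterates and would otherwise drown the structural signal), a
global per-model gradient-norm clip (default 10), and cosine learning-rate
decay over the run.

Inference is a single forward pass — prior noise → sequence denoiser →
argmax tokens → structure predictor — with no refinement iterations. An
optional restrained energy descent (`gradient_refine`: steepest descent on
`E` with a per-step trust radius of 0.2 Å/bead) is available as a polish
and as the instrument for the clash analysis below; it is off by default.

## Networks

The learned components are deliberately small numpy MLPs with hand-written
backprop — the goal is to exercise the training framework on a CPU in
seconds, not to reach the capacity of a full geometric network; both honor
shape contracts (`(Rt, protein) → L×4 logits`;
`(soft sequence, protein, coords) → coords`) so heavier architectures can
be dropped in.

* The **sequence denoiser** is a per-RNA-node feed-forward network over
  features of the protein–RNA k-nearest-neighbor graph (protein Cα and RNA
  C4′ nodes): positional encodings, global pocket summary statistics,
  backbone-orientation descriptors of the pocket residues tracking each
  RNA position, and local graph distances. Decoding is per-position
  independent (argmax), not autoregressive.
* The **structure predictor** is residual (`coords + Δ`), with a linear
  input→output skip path so exact affine corrections — in particular
  "subtract the input noise" — are representable outside the saturating
  tanh layers; with a zero-initialized output head it is exactly the
  identity map. Coordinate features enter unscaled for the same reason.
  Its feature set includes the mapped pocket Cα anchor positions,
  protein-only information that lets a one-shot prediction synthesize a
  backbone even from pure-noise input.

## Synthetic data

The generator stands in for a database of experimental protein–RNA
complexes. Each RNA is an idealized A-form-like helix (rise 2.8 Å, radius
9 Å, twist 32°/nt — toy values chosen for chain regularity, not realism),
with the glycosidic-nitrogen bead placed deeper for purines than
pyrimidines, plus isotropic Gaussian noise (default sd 0.25 Å). The
protein pocket is a 3.8 Å-spaced Cα arc at a clash-free standoff; each
pocket residue tracks one RNA position in register, and the orientation of
its N/C beads about the chain axis encodes the identity of the tracked
nucleotide. That last channel is a deliberate design choice emulating
sequence-specific recognition: at inference the designer sees only noise
plus the protein, so without *some* protein-borne sequence signal no
method could beat the 0.25 random-recovery floor and conditional design
would be untestable. Complexes are centered at the origin (the prior and
the models both live near the origin; absolute placement is meaningless).

Consequences for interpretation: passing the learnability tests shows the
training loop, gradients, conditioning pathway and metrics work — it does
not show that the toy networks would recover sequences from real
interfaces, where recognition is vastly subtler, backbones are irregular,
and the sequence signal is weaker than this generator's. Recovery near 1.0
on held-out synthetic pockets reflects the generator's clean encoding, not
an expectation for real data (where state-of-the-art recovery is ~0.4).

The dataset split emulates identity-based clustering: greedy centroid
clustering at 80% positional identity (matches over the shorter length,
maximized over full-overlap offsets), with whole clusters dealt to
train/validation/test at 8:1:1. A split that would require splitting a
cluster raises instead.

## Metrics

Aligned RMSD (Kabsch, all beads), lDDT (superposition-free; 15 Å inclusion
radius, thresholds {0.5, 1, 2, 4} Å, all three beads, same-residue pairs
excluded — community-standard settings), sequence recovery, Levenshtein
distance (via `edlib`, cross-checked against exhaustive recursion),
TM-score on C4′ beads with the nucleic-acid normalization
`d0 = 0.6√(L−0.5) − 2.5` floored at 0.5 Å and identity residue mapping,
and sequence/structure novelty (one minus the maximum recovery/TM-score
against the training corpus).

The **binding-energy proxy** is the inter-molecular LJ sum over
protein-bead × RNA-bead pairs within the cutoff; under rigid separation
the intra-molecular terms cancel in a bound-vs-unbound difference. IMP is
the percentage of designs with *strictly* lower proxy energy than the
native complex (ties not improved). This scorer deliberately replaces
full-atom scoring functions; absolute IMP values are not comparable to
published full-atom numbers — only the metric's mechanics and within-run
comparisons are meaningful.

The **clash report** counts non-bonded bead pairs (residue separation ≥ 2,
the LJ convention) closer than 2.0 Å. The LJ term's practical effect is
demonstrated through restrained energy refinement: descending `E` with the
design itself as the restraint target is a no-op at α = 0 and relieves
clashes at α > 0, isolating exactly what the LJ term contributes. The
alternative experiment — comparing clash counts of one-shot designs from
models *trained* with β = 0 vs β = 0.1 — is not statistically stable at
this scale: converged toy models design clash-free helices either way, and
in undertrained regimes run-to-run variance dominates.

## Problem sizes

The shipped experiments use corpora of 20 complexes (RNA 10–16 nt, pockets
20–30 residues), 500-step training runs for learnability, 120-epoch runs
for the idempotency comparison, 8-epoch (deliberately undertrained) runs
for the clash study, and 50 designs per pocket for IMP. These sizes make
every stage reproducible on one CPU core in seconds while leaving each
effect measurable.

## Known limitations

* The toy networks are not rotation-equivariant; they rely on the
  generator's canonical centering. Real-data use would substitute
  SE(3)-aware modules behind the same contracts.
* The SDFE oracle is a dinucleotide proxy, not a folding algorithm; it has
  no notion of base pairing or secondary structure.
* Novelty with unequal lengths compares sliding full-overlap windows
  normalized by the shorter length — a convention, not an alignment.
* The chain-selection question for multi-chain PDB inputs is punted to the
  caller: `read_cg_complex` requires explicit chain identifiers.
* Checkpoints (`.npz`) store parameters, configs and seeds but no
  optimizer state; training cannot be resumed mid-run.
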