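# rnacodesign

Protein-conditioned RNA sequence–structure co-design with energy-guided,
idempotent flow matching on a 3-bead coarse-grained backbone.

Designing an RNA that binds a given protein requires producing a sequence
*and* a 3D backbone that are jointly compatible with the target pocket.
Purely geometric generators can emit backbones that are well aligned yet
physically implausible — steric clashes, unstable sequences. This package
implements a co-design framework that addresses both failure modes at
once, for researchers studying generative models of biomolecular
structure who want every moving part runnable and testable on one CPU.

Both molecules live in a coarse-grained space: each RNA nucleotide is the
bead triple (P, C4′, N1/N9) and each protein residue (N, Cα, C), so a
structure is an `(L, 3, 3)` coordinate array.

Three ingredients:

* **Flow matching.** A Gaussian prior backbone `R0` is Kabsch-aligned onto
  the target `R1` and interpolated, `Rt = (1−t)R0* + tR1`. Regressing the
  conditional velocity `(R1 − Rt)/(1−t)` marginalizes to a
  rigid-motion-invariant MSE between prediction and aligned target,
  `L_FM = MSE(R̂1, K(R1, R̂1))`.
* **Energy guidance.** A physical term
  `U(R, r) = Σ 4ε[(σ/d)¹² − (σ/d)⁶] + SDFE(r)` combines a bead-level
  Lennard-Jones potential (ε = 0.2, σ = 3.5 Å) with a differentiable
  sequence-derived free-energy surrogate fitted to a nearest-neighbor
  stacking oracle. The refinement energy
  `E = ‖R̂1 − R1‖²/(2σ_g²) + αU` has an analytic gradient used for
  iterative structure refinement.
* **Idempotent refinement.** Half of the training steps re-apply the
  structure predictor to its own output k times and penalize every iterate
  (`L_ID = mean‖R̂1⁽ⁱ⁾ − R1‖² + βU(R̂1⁽ᵏ⁾, r̂) + CE(r, r̂)`), driving the
  predictor toward a fixed point `R̂1* = f(R̂1*)` located at a low-energy,
  target-like structure.

The learned modules are small, seeded numpy networks behind clean
contracts — sufficient to exercise and test the framework end to end; the
synthetic-data module generates helical CG RNAs paired with clash-free
protein pockets so that no external database is needed. Inference is a
single forward pass: noise → sequence denoiser → argmax tokens → structure
predictor.

## Worked example

```bash
python examples/04_train_and_design.py
```

```
trained 500 steps (refinement branch taken 48% of them)
validation aligned RMSD: untrained 13.20 A -> trained 3.34 A
validation recovery:     untrained 0.38   -> trained 1.00
test designs (2 pockets, mean +- SEM):
  aligned RMSD 2.76 +- 0.56 A, lDDT 0.58 +- 0.09
  recovery 1.00 +- 0.00, Levenshtein 0.0
  IMP 5% of 50 designs/pocket beat the native binding-energy proxy
  sequence novelty vs training set 0.47 (1 = unlike anything seen in training)
```

A 500-step run on 20 synthetic complexes: designs for held-out pockets drop
from the 13 Å random-noise floor to ~3 Å aligned RMSD, and the designed
sequences match the native ones because the synthetic pockets encode their
partner's sequence (see `docs/methods.md` for why held-out recovery near
1.0 is a property of the generator, not a real-data expectation). The
other example scripts walk through corpus generation, the energy stack,
flow/refinement mechanics, and LJ clash relief:

```bash
python examples/05_clash_relief.py
```

```
40 undertrained designs: mean clash count 0.50
after 50 refinement steps without LJ (alpha=0.0): mean clash count 0.50, min inter-bead distance 0.68 A
after 50 refinement steps with LJ    (alpha=0.1): mean clash count 0.00, min inter-bead distance 3.06 A
```

## Command line

A thin CLI wraps the library for shell use:

```bash
rnacodesign generate-data --out corpus --n 20 --seed 3
rnacodesign train --data corpus --checkpoint ckpt.npz --log train.tsv
rnacodesign design --checkpoint ckpt.npz --pdb corpus/syn0000.pdb --out designed.pdb
rnacodesign evaluate --checkpoint ckpt.npz --data corpus --report report.tsv
rnacodesign score-energy --pdb corpus/syn0000.pdb
```

Structures are exchanged as plain PDB (ATOM records, one line per bead),
sequences as FASTA, configuration as YAML, reports as TSV.

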