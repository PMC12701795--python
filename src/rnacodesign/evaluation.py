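"""Metric suite for designed protein-RNA complexes.

Structure accuracy (Kabsch-aligned RMSD, lDDT), sequence accuracy (recovery,
Levenshtein distance), thermodynamic comparison (improved-binding percentage
under an internal CG inter-molecular LJ binding-energy proxy), novelty
against a training corpus, and a steric-clash report.

The binding-energy scorer is a deliberate internal proxy: the LJ sum over
protein-bead x RNA-bead pairs within the cutoff.  Under rigid separation the
intra-molecular terms cancel in a bound-vs-unbound difference, so the
inter-molecular sum plays the role of a ΔG surrogate.  Absolute values are
not comparable to full-atom scoring functions; only within-run comparisons
(native vs designs) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cg_io import CGRNAStructure, ProteinRNAComplex
from .energy import EnergyParams, lj_pair
from .geometry import aligned_rmsd, lddt, tm_score
from .synthetic_data import pairwise_identity


def sequence_recovery(pred: str, truth: str) -> float:
    """Fraction of positions with the correct nucleotide."""
    if len(pred) == 0 or len(truth) == 0:
        raise ValueError("empty sequence")
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch {len(pred)} vs {len(truth)}")
    return sum(1 for a, b in zip(pred, truth) if a == b) / len(truth)


def levenshtein(pred: str, truth: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if len(pred) == 0 or len(truth) == 0:
        return max(len(pred), len(truth))
    return int(edlib.align(pred, truth, task="distance")["editDistance"])


def binding_energy(cplx: ProteinRNAComplex,
                   params: EnergyParams = EnergyParams()) -> float:
    """CG binding free-energy proxy: LJ sum over inter-molecular bead pairs
    within the cutoff (lower = better binding)."""
    p = cplx.protein.coords.reshape(-1, 3)
    r = cplx.rna.coords.reshape(-1, 3)
    if len(p) == 0 or len(r) == 0:
        raise ValueError("empty molecule")
    d = cdist(p, r)
    within = d <= params.cutoff
    if not np.any(within):
        return 0.0
    return float(np.sum(lj_pair(d[within], params)))


def imp(native: ProteinRNAComplex, designs,
        params: EnergyParams = EnergyParams()) -> float:
    """Improved-binding percentage: share of designs whose binding-energy
    proxy is *strictly* lower than the native complex's (ties do not
    count), as a percentage."""
    designs = list(designs)
    if not designs:
        raise ValueError("need at least one design")
    native_e = binding_energy(native, params)
    improved = sum(1 for d in designs if binding_energy(d, params) < native_e)
    return 100.0 * improved / len(designs)


def sequence_novelty(design: str, training_sequences) -> float:
    """1 - max positional recovery against the training corpus; unequal
    lengths are compared over sliding windows normalized by the shorter
    length."""
    training_sequences = list(training_sequences)
    if not training_sequences:
        raise ValueError("empty training set")
    best = max(pairwise_identity(design, t) for t in training_sequences)
    return 1.0 - best


def structure_novelty(design, training_structures) -> float:
    """1 - max TM-score against the training structures."""
    training_structures = list(training_structures)
    if not training_structures:
        raise ValueError("empty training set")
    best = max(tm_score(design, t) for t in training_structures)
    return 1.0 - best


@dataclass
class ClashReport:
    min_distances: list[float]
    clash_counts: list[int]
    fraction_with_clash: float
    threshold: float
    distances: np.ndarray  # all non-bonded inter-bead distances, pooled

    @property
    def mean_clash_count(self) -> float:
        return float(np.mean(self.clash_counts))


def clash_analysis(structures, clash_threshold: float = 2.0,
                   min_separation: int = 2) -> ClashReport:
    """Non-bonded inter-bead distance analysis over CG RNA structures.

    Non-bonded pairs are bead pairs whose residues are at least
    ``min_separation`` apart (the same convention as the LJ pair set, so
    chemically bonded/adjacent geometry is never counted as a clash).
    """
    if clash_threshold <= 0:
        raise ValueError("threshold must be positive")
    mins, counts, pooled = [], [], []
    for s in structures:
        coords = np.asarray(getattr(s, "coords", s), dtype=float)
        cloud = coords.reshape(-1, 3)
        residx = np.repeat(np.arange(coords.shape[0]), 3)
        d = cdist(cloud, cloud)
        i, j = np.triu_indices(len(cloud), k=1)
        keep = np.abs(residx[i] - residx[j]) >= min_separation
        dist = d[i[keep], j[keep]]
        mins.append(float(dist.min()) if len(dist) else float("inf"))
        counts.append(int(np.sum(dist < clash_threshold)))
        pooled.append(dist)
    frac = float(np.mean([c > 0 for c in counts])) if counts else 0.0
    return ClashReport(min_distances=mins, clash_counts=counts,
                       fraction_with_clash=frac, threshold=clash_threshold,
                       distances=np.concatenate(pooled) if pooled else np.array([]))


@dataclass
class EvaluationReport:
    """Aggregate metrics (mean and standard error of the mean) plus the
    per-complex breakdown."""

    means: dict
    sems: dict
    table: pd.DataFrame

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _mean_sem(values):
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return mean, sem


def evaluate(models, test_complexes, params: EnergyParams = EnergyParams(),
             seed: int = 0, n_imp_designs: int = 10,
             training_sequences=None, training_structures=None,
             designer=None) -> EvaluationReport:
    """Design one RNA per test complex and score the full metric suite.

    ``models`` is a (sequence_denoiser, structure_predictor) pair;
    ``designer`` may override the design call (signature
    ``(protein, Lr, seq_model, struct_model, seed) -> (tokens, structure)``)
    — the default is the single-forward-pass pipeline design op.
    ``n_imp_designs`` extra stochastic designs per complex feed the IMP
    statistic.
    """
    from .pipeline import design as default_design, sample_designs

    test_complexes = list(test_complexes)
    if not test_complexes:
        raise ValueError("empty test set")
    designer = designer or default_design
    seq_model, struct_model = models

    rows = []
    for idx, cplx in enumerate(test_complexes):
        lr = len(cplx.rna)
        tokens, structure = designer(cplx.protein, lr, seq_model,
                                     struct_model, seed=seed * 100003 + idx)
        row = {
            "id": cplx.id,
            "aligned_rmsd": aligned_rmsd(structure.coords, cplx.rna.coords),
            "lddt": lddt(structure.coords, cplx.rna.coords),
            "recovery": sequence_recovery(tokens, cplx.rna.sequence),
            "levenshtein": levenshtein(tokens, cplx.rna.sequence),
        }
        design_complexes = [
            ProteinRNAComplex(protein=cplx.protein, rna=s, id=f"{cplx.id}_d{i}")
            for i, (_, s) in enumerate(
                sample_designs(cplx.protein, lr, seq_model, struct_model,
                               n=n_imp_designs, seed=seed * 7 + idx))
        ]
        row["imp"] = imp(cplx, design_complexes, params)
        clash = clash_analysis([structure])
        row["clash_count"] = clash.clash_counts[0]
        if training_sequences:
            row["sequence_novelty"] = sequence_novelty(tokens, training_sequences)
        if training_structures:
            row["structure_novelty"] = structure_novelty(
                structure, training_structures)
        rows.append(row)

    table = pd.DataFrame(rows)
    means, sems = {}, {}
    for col in table.columns:
        if col == "id":
            continue
        means[col], sems[col] = _mean_sem(table[col].to_numpy())
    means["clash_fraction"] = float((table["clash_count"] > 0).mean())
    return EvaluationReport(means=means, sems=sems, table=table)
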