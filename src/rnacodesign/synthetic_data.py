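"""Synthetic CG protein-RNA complexes for desk-scale training and testing.

The generator emulates the statistical shape of protein-bound RNA at the
coarse-grained level, not its chemistry:

* RNA backbones are idealized A-form-like helices — C4' beads on a regular
  helix (configurable rise/radius/twist), with the P bead at a fixed
  outward/axial offset and the glycosidic nitrogen pointing inward, its
  depth differing between purines and pyrimidines so the backbone geometry
  carries base-class information, plus isotropic Gaussian coordinate noise;
* protein "pockets" are bead chains arcing around the RNA at a clash-free
  standoff with physical 3.8 A CA-CA spacing.  Each pocket residue tracks
  one RNA position along the interface and the orientation of its N/C beads
  about the chain axis encodes the identity of that nucleotide — a toy
  stand-in for sequence-specific recognition that makes protein-conditioned
  sequence design learnable in principle (without some such signal the task
  would be information-free at inference time).

Dataset splitting emulates sequence-identity-based clustering: a greedy
centroid clustering at a configurable identity threshold, with whole
clusters (never individual sequences) assigned to train/validation/test.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .cg_io import (CGProteinStructure, CGRNAStructure, ProteinRNAComplex,
                    read_cg_complex, write_cg_complex, write_fasta,
                    SequenceRecord)

RNA_TOKENS = "ACGU"
PROTEIN_TOKENS = "ACDEFGHIKLMNPQRSTVWY"

#: CA-CA virtual bond length (A)
CA_SPACING = 3.8
#: token -> N/C bead orientation angle about the pocket chain axis
TOKEN_ANGLE = {t: i * 2.0 * np.pi / 5.0 for i, t in enumerate(RNA_TOKENS)}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Helix parameters approximate A-form RNA bead geometry (toy values);
    ``coordinate_noise_sd`` perturbs every bead isotropically; ``gc_bias``
    is the probability that a sampled nucleotide is G or C (0.5 = uniform
    composition).
    """

    n_complexes: int = 20
    rna_length_range: tuple = (10, 16)
    protein_length_range: tuple = (20, 30)
    helix_rise: float = 2.8
    helix_radius: float = 9.0
    helix_twist: float = 32.0  # degrees per nucleotide
    coordinate_noise_sd: float = 0.25
    gc_bias: float = 0.5
    pocket_standoff: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rng_ in (self.rna_length_range, self.protein_length_range):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValueError(f"bad length range {rng_}")
        if self.coordinate_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must be in [0, 1]")
        if min(self.helix_rise, self.helix_radius, self.helix_twist,
               self.pocket_standoff) <= 0:
            raise ValueError("helix/pocket parameters must be positive")


def _sample_rna_sequence(length: int, gc_bias: float, rng) -> str:
    tokens = []
    for _ in range(length):
        if rng.uniform() < gc_bias:
            tokens.append("G" if rng.uniform() < 0.5 else "C")
        else:
            tokens.append("A" if rng.uniform() < 0.5 else "U")
    return "".join(tokens)


def generate_rna(config: GeneratorConfig, rng,
                 length: int | None = None) -> CGRNAStructure:
    """One helical CG RNA with sequence drawn under the GC bias.

    At zero noise consecutive C4'-C4' distances are exactly equal and the
    structure is clash-free by construction (all bead pairs at residue
    separation >= 2 sit far beyond the LJ zero-crossing).
    """
    lr = int(length if length is not None
             else rng.integers(config.rna_length_range[0],
                               config.rna_length_range[1] + 1))
    sequence = _sample_rna_sequence(lr, config.gc_bias, rng)
    twist = np.deg2rad(config.helix_twist)
    theta = np.arange(lr) * twist
    radial = np.stack([np.cos(theta), np.sin(theta),
                       np.zeros(lr)], axis=1)
    axis = np.array([0.0, 0.0, 1.0])
    c4 = config.helix_radius * radial + np.outer(
        np.arange(lr) * config.helix_rise, axis)
    # P: slightly outside the C4' helix and displaced along the axis
    p = c4 + 0.8 * radial + 1.6 * axis
    # glycosidic nitrogen: inward, deeper for purines (N9) than pyrimidines
    depth = np.array([4.5 if s in "AG" else 3.5 for s in sequence])
    n = c4 - depth[:, None] * radial + 0.4 * axis
    coords = np.stack([p, c4, n], axis=1)
    coords = coords + rng.normal(0.0, config.coordinate_noise_sd, coords.shape)
    return CGRNAStructure(sequence=sequence, coords=coords)


def generate_protein_pocket(rna: CGRNAStructure, config: GeneratorConfig,
                            rng, length: int | None = None) -> CGProteinStructure:
    """A CA-spaced bead chain arcing around the RNA helix.

    Pocket residue j tracks RNA residue i(j) (linear register along the
    interface); its N/C bead orientation about the chain encodes the
    identity of that nucleotide.  Raises ``ValueError`` when no clash-free
    arc with 3.8 A spacing can span the RNA (RNA too long for the pocket
    length range).
    """
    lp = int(length if length is not None
             else rng.integers(config.protein_length_range[0],
                               config.protein_length_range[1] + 1))
    lr = len(rna)
    radius = config.helix_radius + config.pocket_standoff
    z_span = (lr - 1) * config.helix_rise
    rise_p = z_span / (lp - 1) if lp > 1 else 0.0
    chord_sq = CA_SPACING ** 2 - rise_p ** 2
    if chord_sq <= 0:
        raise ValueError(
            f"cannot place pocket: RNA z-span {z_span:.1f} A needs more than "
            f"{lp} residues at {CA_SPACING} A spacing")
    dphi = 2.0 * np.arcsin(np.sqrt(chord_sq) / (2.0 * radius))

    phi = np.arange(lp) * dphi
    z = np.arange(lp) * rise_p
    ca = np.stack([radius * np.cos(phi), radius * np.sin(phi), z], axis=1)

    # orientation encoding of the tracked nucleotide
    mapped = (np.round(np.arange(lp) * (lr - 1) / max(lp - 1, 1))
              .astype(int) if lr > 1 else np.zeros(lp, dtype=int))
    angles = np.array([TOKEN_ANGLE[rna.sequence[i]] for i in mapped])
    angles = angles + rng.normal(0.0, 0.05, lp)

    prev_idx = np.maximum(np.arange(lp) - 1, 0)
    next_idx = np.minimum(np.arange(lp) + 1, lp - 1)
    tangent = ca[next_idx] - ca[prev_idx]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    centroid = ca.mean(axis=0)
    radial_dir = ca - centroid
    radial_dir /= np.linalg.norm(radial_dir, axis=1, keepdims=True)

    n_dir = np.cos(angles)[:, None] * tangent + np.sin(angles)[:, None] * radial_dir
    c_dir = -np.cos(angles)[:, None] * tangent + np.sin(angles)[:, None] * radial_dir
    n_bead = ca + 1.46 * n_dir
    c_bead = ca + 1.52 * c_dir
    coords = np.stack([n_bead, ca, c_bead], axis=1)
    coords = coords + rng.normal(0.0, config.coordinate_noise_sd, coords.shape)

    min_dist = cdist(coords.reshape(-1, 3), rna.coords.reshape(-1, 3)).min()
    if min_dist <= 3.5 * 2 ** (1.0 / 6.0):
        raise ValueError(
            f"pocket placement clashed with the RNA (min distance "
            f"{min_dist:.2f} A); increase pocket_standoff or reduce noise")

    sequence = "".join(rng.choice(list(PROTEIN_TOKENS)) for _ in range(lp))
    return CGProteinStructure(sequence=sequence, coords=coords)


def generate_complex(config: GeneratorConfig, rng,
                     ident: str = "") -> ProteinRNAComplex:
    rna = generate_rna(config, rng)
    protein = generate_protein_pocket(rna, config, rng)
    # center the complex at the origin (models and the Gaussian prior both
    # live near the origin; absolute placement is meaningless for the task)
    center = np.vstack([rna.coords.reshape(-1, 3),
                        protein.coords.reshape(-1, 3)]).mean(axis=0)
    rna.coords = rna.coords - center
    protein.coords = protein.coords - center
    rna.id = f"{ident}_rna" if ident else "rna"
    protein.id = f"{ident}_protein" if ident else "protein"
    return ProteinRNAComplex(protein=protein, rna=rna, id=ident or "complex")


def complex_seed(master_seed: int, index: int) -> int:
    """Deterministic per-complex sub-seed, kept below 2**31."""
    return int((master_seed * 1000003 + 7919 * index + 1) % (2 ** 31))


def generate_dataset(config: GeneratorConfig) -> list[ProteinRNAComplex]:
    """``n_complexes`` independent seeded draws; every complex passes the
    shared CG validators (enforced by the dataclass constructors)."""
    dataset = []
    for i in range(config.n_complexes):
        rng = np.random.default_rng(complex_seed(config.seed, i))
        dataset.append(generate_complex(config, rng, ident=f"syn{i:04d}"))
    return dataset


def write_dataset(dataset, out_dir, config: GeneratorConfig | None = None,
                  splits: dict | None = None) -> None:
    """Materialize a dataset as CG-PDB files + FASTA + a TSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("id\tseed\tsplit\tLr\tLp\n")
        for i, cplx in enumerate(dataset):
            write_cg_complex(cplx, out / f"{cplx.id}.pdb")
            records.append(SequenceRecord(id=cplx.id, sequence=cplx.rna.sequence))
            seed = complex_seed(config.seed, i) if config is not None else -1
            split = (splits or {}).get(cplx.id, "unsplit")
            fh.write(f"{cplx.id}\t{seed}\t{split}\t{len(cplx.rna)}"
                     f"\t{len(cplx.protein)}\n")
    write_fasta(out / "rna_sequences.fasta", records)


def load_dataset(in_dir) -> list[ProteinRNAComplex]:
    in_dir = Path(in_dir)
    dataset = []
    with open(in_dir / "manifest.tsv") as fh:
        next(fh)
        for line in fh:
            ident = line.split("\t")[0]
            dataset.append(read_cg_complex(in_dir / f"{ident}.pdb", "A", "B"))
    return dataset


# ---------------------------------------------------------------------------
# similarity split
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Positional identity between two sequences: matches over the shorter
    length, maximized over all offsets that keep the shorter sequence fully
    inside the longer one."""
    if len(a) > len(b):
        a, b = b, a
    ls, ll = len(a), len(b)
    best = 0
    for off in range(ll - ls + 1):
        matches = sum(1 for i in range(ls) if a[i] == b[off + i])
        best = max(best, matches)
    return best / ls


SplitDataset = namedtuple("SplitDataset", ["train", "val", "test"])


def similarity_split(dataset, identity_threshold: float = 0.8,
                     ratios=(0.8, 0.1, 0.1), seed: int = 0,
                     allow_empty: bool = False) -> SplitDataset:
    """Greedy centroid clustering of RNA sequences followed by a
    cluster-level partition.

    Each sequence joins the first existing cluster whose centroid (founder)
    identity is >= the threshold, else founds a new cluster.  Whole clusters
    are then dealt to train/validation/test to approximate the requested
    ratios, so no cluster ever spans two subsets.  With fewer than 3
    clusters three non-empty subsets are impossible: that raises unless
    ``allow_empty`` is set, in which case whole clusters are still assigned
    indivisibly and some subsets come back empty.
    """
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError("identity_threshold must be in (0, 1)")
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ValueError("ratios must be three values summing to 1")

    clusters: list[list[int]] = []
    centroids: list[str] = []
    for idx, cplx in enumerate(dataset):
        seq = cplx.rna.sequence
        for c, centroid in enumerate(centroids):
            if pairwise_identity(seq, centroid) >= identity_threshold:
                clusters[c].append(idx)
                break
        else:
            centroids.append(seq)
            clusters.append([idx])
    if len(clusters) < 3 and not allow_empty:
        raise ValueError(
            f"only {len(clusters)} clusters; cannot form three disjoint splits")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    n_total = len(dataset)
    targets = [r * n_total for r in ratios]
    counts = [0, 0, 0]
    assignment: dict[int, int] = {}
    for c in order:
        deficits = [t - n for t, n in zip(targets, counts)]
        subset = int(np.argmax(deficits))
        for idx in clusters[c]:
            assignment[idx] = subset
        counts[subset] += len(clusters[c])
    # guarantee non-empty val/test by moving whole clusters out of donors
    # that can spare one (donors keeping at least one cluster)
    for subset in (2, 1):
        if counts[subset] > 0:
            continue
        donors = {}
        for c, members in enumerate(clusters):
            donors.setdefault(assignment[members[0]], []).append(c)
        candidates = [(len(clusters[c]), c) for d, cs in donors.items()
                      if d != subset and len(cs) > 1 for c in cs]
        if not candidates:
            continue  # indivisible; only reachable with allow_empty
        _, smallest = min(candidates)
        donor = assignment[clusters[smallest][0]]
        for idx in clusters[smallest]:
            assignment[idx] = subset
        counts[subset] += len(clusters[smallest])
        counts[donor] -= len(clusters[smallest])

    members = ([], [], [])
    for idx, cplx in enumerate(dataset):
        members[assignment[idx]].append(cplx)
    return SplitDataset(train=members[0], val=members[1], test=members[2])
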