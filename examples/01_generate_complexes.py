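"""Generate a synthetic protein-RNA complex corpus and inspect it.

The generator builds idealized helical CG RNA backbones paired with
clash-free protein "pocket" chains, then clusters the RNA sequences and
splits whole clusters into train/validation/test.
"""

import numpy as np

from rnacodesign import (GeneratorConfig, generate_dataset, similarity_split,
                         clash_analysis, lj_total)

config = GeneratorConfig(n_complexes=20, seed=0)
dataset = generate_dataset(config)
split = similarity_split(dataset, identity_threshold=0.8, seed=0)

lengths = [len(c.rna) for c in dataset]
report = clash_analysis([c.rna for c in dataset])
print(f"complexes: {len(dataset)}  RNA lengths {min(lengths)}-{max(lengths)}")
print(f"split sizes train/val/test: {len(split.train)}/{len(split.val)}/"
      f"{len(split.test)}")
print(f"structures with steric clashes: "
      f"{report.fraction_with_clash * 100:.0f}%  (generator guarantee: none "
      f"at zero noise; mild coordinate noise can create rare contacts)")
print(f"mean LJ energy per structure: "
      f"{np.mean([lj_total(c.rna) for c in dataset]):.3f} kcal/mol "
      f"(negative = no repulsive contacts)")
example = dataset[0]
print(f"example '{example.id}': RNA {example.rna.sequence} with a "
      f"{len(example.protein)}-residue pocket")
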