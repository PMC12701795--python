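"""The biophysical energy stack: LJ potential, the nearest-neighbor
free-energy oracle, and its differentiable surrogate (SDFE).

Prints the analytic landmarks of the LJ pair potential, compares stabilities
of GC- vs AU-rich sequences, and fits the SDFE surrogate to the oracle.
"""

import numpy as np

from rnacodesign import EnergyParams, lj_pair, nn_free_energy_oracle
from rnacodesign.pipeline import default_sdfe

params = EnergyParams()  # epsilon=0.2, sigma=3.5 A
d_min = params.sigma_lj * 2 ** (1 / 6)
print(f"LJ zero crossing at sigma = {params.sigma_lj} A: "
      f"U = {lj_pair(params.sigma_lj, params):.3f}")
print(f"LJ minimum at sigma*2^(1/6) = {d_min:.3f} A: "
      f"U = {lj_pair(d_min, params):.3f}  (equals -epsilon)")
print(f"LJ at 3.0 A (repulsive wall): U = {lj_pair(3.0, params):+.3f}")

for seq in ("GCGCGC", "AUAUAU", "GAUCGA"):
    print(f"free-energy proxy of {seq}: "
          f"{nn_free_energy_oracle(seq):+.2f} kcal/mol")
print("(lower = more stable; GC stacks are the strongest)")

sdfe = default_sdfe(seed=0)
print(f"SDFE surrogate held-out RMSE: {sdfe.heldout_rmse:.2e} kcal/mol")
rng = np.random.default_rng(1)
seq = "".join(rng.choice(list("ACGU"), size=20))
print(f"oracle vs surrogate on {seq}: "
      f"{nn_free_energy_oracle(seq):+.3f} vs {sdfe.predict(seq):+.3f}")
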