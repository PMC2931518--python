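"""Estimate dummy-atom form factors from reference curves.

Generates 20 synthetic training proteins with designed composition
contrast, produces reference curves from a known one-body generating
table, and re-estimates the table by per-bin Metropolis-Hastings sampling
of the posterior followed by medoid point estimation — then reports how
well the generating values were recovered.
"""

import warnings

import numpy as np

import cgsaxs as cg
from cgsaxs.experiments import build_training_set

grid = cg.QGrid()
truth = cg.generate_table(cg.BeadAlphabet.one_body(), grid, seed=13)
train = build_training_set(n_structures=20, n_residues=30, granularity="one",
                           grid=grid, table=truth, noise_level=0.0, seed=0)

config = cg.MCMCConfig(iterations=300_000, burn_in=150_000, thinning=100,
                       seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    table, samples, diag = cg.estimate_table(train, config=config,
                                             sigma_scale=0.0, anneal=True)

rel = np.abs(table.values - truth.values) / truth.values
print(f"estimated {table.values.shape[0]} form factors on "
      f"{grid.n_bins} q-bins from {len(train)} structures")
print(f"median relative error vs generating table: {np.median(rel):.2e}")
print("ALA form factor (true vs estimated) at selected bins:")
ia = table.alphabet.index("ALA")
for b in (0, 20, 50):
    print(f"  q = {grid.q[b]:.3f}:  {truth.values[ia, b]:7.3f}  vs  "
          f"{table.values[ia, b]:7.3f}")
# With noiseless reference data the per-bin posteriors collapse onto exact
# fits and the medoids reproduce the generating table to a fraction of a
# percent; with noisy data the posterior width tracks the assumed error.
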