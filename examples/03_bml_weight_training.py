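"""Recover FragMap weighting factors from noisy affinities by MCSA.

LGFE is linear in the per-map-type weights, so fixed docked poses reduce to
a table g[ligand, type]. The optimizer walks weight space with simulated
annealing, maximizing Pearson R against experimental pIC50 under a
flat-bottom restraint keeping weights in [0.05, 2.0].
"""

from fragdock import BMLConfig, WeightVector, mcsa_optimize, pearson_r
from fragdock.synthetic import SyntheticSpec, make_bml_dataset

spec = SyntheticSpec(n_ligands=50, noise_sigma=0.3, rng_seed=0)
table, true_weights = make_bml_dataset(spec)
print("true generating weights:", true_weights)

r_unit = pearson_r(table.predicted_pic50(WeightVector()), table.exp_pic50)
print("training R at unit weights:     %.3f" % r_unit)

weights = mcsa_optimize(table, BMLConfig(n_mcsa_steps=20_000, rng_seed=0))
r_opt = pearson_r(table.predicted_pic50(weights), table.exp_pic50)
print("training R at trained weights:  %.3f" % r_opt)
print("trained weights:", {k: round(v, 3) for k, v in sorted(weights.items())})
# The trained weights track the generating ones up to an overall scale
# (Pearson R is scale-invariant, so only weight ratios are identifiable).
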