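"""Henderson-Hasselbalch state weighting and the consensus affinity model.

Ionizable blockers bind differently in their neutral and charged forms; the
package mixes the two state scores by their populations at pH 7.4. The
consensus model then regresses experimental pIC50 on five physicochemical
descriptors plus the structure-based predicted pIC50.
"""

import numpy as np
import pandas as pd

from fragdock import fit_mlr, hh_weighted_lgfe, pearson_r, predict
from fragdock.ppm import build_feature_matrix
from fragdock.synthetic import SyntheticSpec, make_descriptor_table, two_signal_affinities

# --- HH weighting: an amine base with pKa 9.4 at pH 7.4 is 99% charged ----
mixed = hh_weighted_lgfe(lgfe_neutral=-6.0, lgfe_charged=-8.0, pKa=9.4, pH=7.4, kind="base")
print("HH-weighted LGFE: %.3f kcal/mol (99%% charged + 1%% neutral)" % mixed)

# --- consensus model on a two-signal synthetic study ----------------------
rng = np.random.default_rng(1)
spec = SyntheticSpec(noise_sigma=0.3)
desc = make_descriptor_table([f"c{i}" for i in range(120)], rng).set_index("compound")
struct_pic50 = rng.normal(5.0, 1.2, size=120)  # structure-based predictions
exp = two_signal_affinities(struct_pic50, desc, spec, rng)

train, test = slice(0, 60), slice(60, 120)
Xp = build_feature_matrix(desc, mode="ppm_only")
Xc = build_feature_matrix(desc, silcs_pic50=pd.Series(struct_pic50, index=desc.index),
                          mode="consensus")
r_ppm = pearson_r(predict(fit_mlr(Xp.iloc[train], exp[train]), Xp.iloc[test]), exp[test])
r_struct = pearson_r(struct_pic50[test], exp[test])
r_cons = pearson_r(predict(fit_mlr(Xc.iloc[train], exp[train]), Xc.iloc[test]), exp[test])
print("holdout R — descriptors only: %.3f" % r_ppm)
print("holdout R — structure only:   %.3f" % r_struct)
print("holdout R — consensus:        %.3f" % r_cons)
# The affinities carry both a descriptor and a structure signal, so the
# joint regression beats either single source.
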