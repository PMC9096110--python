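"""Train the weighted-voting ensemble on synthetic data and screen peptides.

The pipeline: ReliefF relevance filter -> RFE feature subset for the SVM ->
RF/XGB/SVM base models -> six-weight probability voting, with the weights
chosen by grid search on an internal validation split.
"""
import numpy as np

from ahtpscreen import (Peptide, SimConfig, extract_matrix, frozen_composites,
                        generate_dataset, train_ensemble)
from ahtpscreen.composite import augment_matrix
from ahtpscreen.ensemble import PipelineConfig

data, _ = generate_dataset(SimConfig(n_pos=300, n_neg=300, seed=8))
matrix = augment_matrix(extract_matrix(data),
                        list(frozen_composites().values()))

cfg = PipelineConfig(relieff_n_samples=150, rfe_step=32,
                     weight_resolution=0.25)  # light settings for the demo
model = train_ensemble(matrix.X, matrix.y, feature_names=matrix.schema.names,
                       schema_hash=matrix.schema.hash, config=cfg, seed=8)
print("voting weights (w1..w6, RF/XGB/SVM x AHTP/non):",
      np.round(model.weights.w, 2))

queries = ["YLYELR", "LVPPHA", "IPPAYTK", "AAKLGE", "DEGSSAK"]
qm = augment_matrix(extract_matrix([Peptide(s, s) for s in queries]),
                    list(frozen_composites().values()))
res = model.predict_matrix(qm.X)
print(f"\n{'peptide':>10} {'P_RF':>6} {'P_XGB':>6} {'P_SVM':>6} "
      f"{'P_ens':>6}  call")
for i, s in enumerate(queries):
    print(f"{s:>10} {res['P_RF'][i]:6.2f} {res['P_XGB'][i]:6.2f} "
          f"{res['P_SVM'][i]:6.2f} {res['P_ensemble'][i]:6.2f}  "
          f"{res['label'][i]}")
# P_ens is the renormalised weighted vote; a peptide is called AHTP when it
# reaches 0.5. Proline-rich peptides score high, acidic ones low.
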