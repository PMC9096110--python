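"""Evaluate the frozen logistic composite features and fit a new one.

comF and comF2 are linear predictors (logits) over a handful of named
descriptors, shipped with their published intercepts and coefficients. A
higher comF2 indicates a more AHTP-like descriptor profile.
"""
from ahtpscreen import (Peptide, SimConfig, extract_features, extract_matrix,
                        evaluate_composite, fit_composite, frozen_composites,
                        generate_dataset)

fr = frozen_composites()
for seq in ("YLYELR", "LVPPHA", "AAKLGE"):
    fv = extract_features(Peptide(seq, seq))
    print(f"{seq}: comF = {evaluate_composite(fr['comF'], fv):+.4f}  "
          f"comF2 = {evaluate_composite(fr['comF2'], fv):+.4f}")

# fit a fresh composite on synthetic data over two schema features
data, _ = generate_dataset(SimConfig(n_pos=300, n_neg=300, seed=2))
matrix = extract_matrix(data)
fit = fit_composite(matrix, ["AAC13", "QSO19"], name="proline_tyrosine_logit")
print(f"\nfitted composite: intercept {fit.spec.intercept:+.3f}, "
      f"coefficients {{'AAC13': {fit.spec.coefficients['AAC13']:+.3f}, "
      f"'QSO19': {fit.spec.coefficients['QSO19']:+.3f}}} "
      f"(converged={fit.converged})")
# AAC13 is the proline fraction: its positive coefficient reflects the
# proline enrichment the generator plants in the positive class.
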