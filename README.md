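# ahtpscreen

Screening toolkit for **antihypertensive peptides (AHTPs)** — short food- or
venom-derived peptides that lower blood pressure, typically by inhibiting
angiotensin-converting enzyme (ACE). Wet-lab validation of candidate
peptides is slow and expensive; `ahtpscreen` ranks candidates first by
machine learning on sequence-derived descriptors.

The package provides, as an importable library with a thin CLI:

* **Descriptor engine** — every peptide is encoded as a named
  431-component vector: amino-acid composition (AAC, 20), Chou-style
  pseudo-compositions in four variants (PAAC 23, parallel/series
  correlation 22/26, two amphiphilic blocks 23+23),
  composition/transition/distribution descriptors over seven
  physicochemical three-group partitions (C/T/D, 21+21+105),
  quasi-sequence-order descriptors from two 20×20 residue distance
  matrices (QSO 46, coupling numbers SOCN 6), 76 physicochemical scale
  projections and global indices (z-scales, aliphatic/instability index,
  net charge, pI, hydrophobic moments, Geary autocorrelations, ...),
  counts of 13 selected enriched motifs, and 6 secondary-structure/
  aggregation propensities from a pluggable provider.
* **Composite features** — scalar logits
  `comF = β₀ + Σ βⱼ·featureⱼ` fitted by logistic regression over selected
  descriptors. The two frozen composites ship with their published
  coefficients, e.g.
  `comF2 = 0.1786 + 0.1522·APAAC1_15 − 2.2951·CTDC10 − 0.6069·CTDC19
  − 0.0065·CTDD49 + 0.2176·QSO19 + 0.9747·fasgai4 + 0.3691·protFP3
  + 2.0823·Pse_PC13`.
* **Feature selection** — ReliefF relevance filtering and recursive
  feature elimination (RFE) for the SVM input subset.
* **Ensemble classifier** — a random forest, an RBF-kernel SVM and
  gradient-boosted trees combined by six-weight class-wise probability
  voting:
  `score(AHTP) = w₁·P_RF + w₃·P_XGB + w₅·P_SVM`,
  `score(non) = w₂·(1−P_RF) + w₄·(1−P_XGB) + w₆·(1−P_SVM)`,
  `P_ens = score(AHTP) / (score(AHTP)+score(non))`, with the weights found
  by exhaustive grid search on held-out data.
* **Motif & composition analytics** — pseudo-counted log₂-odds k-mer
  enrichment, terminal positional residue analysis, physicochemical
  composition profiling.
* **Synthetic data generator** — reproducible AHTP-like/background
  datasets (proline/tyrosine enrichment, planted YP/VP/PP-style motifs)
  so the whole pipeline is testable without external downloads.

## Worked example

```python
from ahtpscreen import Peptide, extract_features, frozen_composites
from ahtpscreen.composite import evaluate_composite

fv = extract_features(Peptide("q1", "YLYELR"))   # a scorpion-venom AHTP
print(fv.schema.dimension)                        # 431
print(round(fv["AAC20"], 3))                      # 0.333  (Tyr fraction)
print(round(fv["QSO19"], 3))                      # 0.241  (Tyr QSO slot)
comF2 = frozen_composites()["comF2"]
print(round(evaluate_composite(comF2, fv), 4))    # -0.0211
```

`extract_features` returns the full named vector; `comF2` is the frozen
logistic composite — higher values indicate a more AHTP-like profile (for
comparison, the acidic background peptide `AAKLGE` scores −1.78).

Training and screening end to end (see `examples/04_train_and_predict.py`
for the complete script):

```python
from ahtpscreen import SimConfig, generate_dataset, extract_matrix, train_ensemble
from ahtpscreen.composite import augment_matrix
from ahtpscreen import frozen_composites

data, _ = generate_dataset(SimConfig(n_pos=300, n_neg=300, seed=8))
m = augment_matrix(extract_matrix(data), list(frozen_composites().values()))
model = train_ensemble(m.X, m.y, feature_names=m.schema.names,
                       schema_hash=m.schema.hash, seed=8)
```

The `examples/` directory holds one short narrative script per capability
(feature extraction, motif enrichment, composite features, training and
prediction, simulation). A thin CLI mirrors the main flows:
`ahtpscreen extract|train|predict|cv|simulate --help`.

## Documentation

`docs/methods.md` describes the descriptor definitions and conventions,
the voting model, the selection procedures, the synthetic generator's
assumptions, and known limitations (including which packaged residue
tables are constructed stand-ins rather than published values).
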