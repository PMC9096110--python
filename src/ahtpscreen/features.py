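"""The named 431-component feature schema, vectors and matrices.

Block layout (total 431):

====================  ====  =========================================
block                 dims  component names
====================  ====  =========================================
AAC                     20  AAC1..AAC20 (A..Y order)
PAAC                    23  PAAC1..PAAC23
Pse_PC                  22  Pse_PC1..Pse_PC22
Pse_SC                  26  Pse_SC1..Pse_SC26
APAAC1 (hydrophob.)     23  APAAC1_1..APAAC1_23
APAAC2 (hydrophil.)     23  APAAC2_1..APAAC2_23
CTDC                    21  CTDC1..CTDC21
CTDT                    21  CTDT1..CTDT21
CTDD                   105  CTDD1..CTDD105
QSO                     46  QSO1..QSO46
SOCN                     6  SOCN1..SOCN6
scales+indices          76  Crucian1.. .. pI
motifs                  13  motif_YP .. motif_YPF
propensities             6  tango1..tango6
====================  ====  =========================================

Index-semantics anchors: APAAC1_15 is the Arg component of the
hydrophobicity amphiphilic block, Pse_PC13 the Pro parallel-correlation
component, QSO19 the Tyr occurrence under the first distance matrix,
CTDC10 polarizability group 1 (G,A,S,D,T), CTDC19 the buried
solvent-accessibility group (A,L,F,C,G,I,V,W), and CTDD49 polarizability
group 1 at the 75% distribution point.

The schema is versioned and hashed; model bundles record the hash and
prediction refuses mismatched schemas.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import descriptors as desc
from . import physchem as pc
from .motifs import SelectedMotifs, motif_features
from .peptide_io import LabeledDataset, Peptide
from .physchem import PropensityProvider, SurrogatePropensityProvider

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

_PHYSCHEM_NAMES = (
    [f"Crucian{i}" for i in range(1, 4)]
    + [f"zscales{i}" for i in range(1, 6)]
    + [f"fasgai{i}" for i in range(1, 7)]
    + [f"tscales{i}" for i in range(1, 6)]
    + [f"vhsescales{i}" for i in range(1, 9)]
    + [f"protFP{i}" for i in range(1, 9)]
    + [f"stscales{i}" for i in range(1, 9)]
    + [f"mswhimscore{i}" for i in range(1, 4)]
    + ["aIndex"] + [f"geary{i}" for i in range(1, 13)]
    + ["autocov", "Boman", "Charge", "Crosscov1", "Crosscov2",
       "Instaindex", "Hmoment1", "Hmoment2"]
    + [f"Blosum{i}" for i in range(1, 9)] + ["pI"]
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named component layout of the descriptor vector."""

    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    version: str = SCHEMA_VERSION

    @classmethod
    def default(cls, motifs: SelectedMotifs = SelectedMotifs()) -> "FeatureSchema":
        blocks = [
            ("AAC", tuple(f"AAC{i}" for i in range(1, 21))),
            ("PAAC", tuple(f"PAAC{i}" for i in range(1, 24))),
            ("Pse_PC", tuple(f"Pse_PC{i}" for i in range(1, 23))),
            ("Pse_SC", tuple(f"Pse_SC{i}" for i in range(1, 27))),
            ("APAAC1", tuple(f"APAAC1_{i}" for i in range(1, 24))),
            ("APAAC2", tuple(f"APAAC2_{i}" for i in range(1, 24))),
            ("CTDC", tuple(f"CTDC{i}" for i in range(1, 22))),
            ("CTDT", tuple(f"CTDT{i}" for i in range(1, 22))),
            ("CTDD", tuple(f"CTDD{i}" for i in range(1, 106))),
            ("QSO", tuple(f"QSO{i}" for i in range(1, 47))),
            ("SOCN", tuple(f"SOCN{i}" for i in range(1, 7))),
            ("physchem", tuple(_PHYSCHEM_NAMES)),
            ("motifs", tuple(f"motif_{m}" for m in motifs)),
            ("propensities", tuple(f"tango{i}" for i in range(1, 7))),
        ]
        return cls(blocks=tuple(blocks))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, block in self.blocks for n in block)

    @property
    def dimension(self) -> int:
        return len(self.names)

    def block_dims(self) -> dict[str, int]:
        return {name: len(block) for name, block in self.blocks}

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.version.encode())
        for n in self.names:
            h.update(n.encode())
        return h.hexdigest()[:16]

    def __post_init__(self):
        names = self.names
        if len(names) != len(set(names)):
            raise ValueError("component names must be unique")


@dataclass
class FeatureVector:
    """One peptide's values under a schema, with named lookup."""

    schema: FeatureSchema
    values: np.ndarray
    peptide_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schema.dimension,):
            raise ValueError(
                f"value length {self.values.shape} != schema dimension "
                f"{self.schema.dimension}")
        if not np.all(np.isfinite(self.values)):
            bad = np.array(self.schema.names)[~np.isfinite(self.values)]
            raise ValueError(f"non-finite features: {bad[:5]}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.index_of(name)])


def extract_features(p: Peptide,
                     params: desc.DescriptorParams = desc.DescriptorParams(),
                     motifs: SelectedMotifs = SelectedMotifs(),
                     provider: PropensityProvider | None = None,
                     schema: FeatureSchema | None = None) -> FeatureVector:
    """Compute the full descriptor vector of one peptide in schema order."""
    schema = schema or FeatureSchema.default(motifs)
    provider = provider or SurrogatePropensityProvider()
    values: dict[str, float] = {}
    try:
        values.update(desc.compute_aac(p))
        for mode in desc.PSEAAC_MODES:
            values.update(desc.compute_pseaac(p, mode, params))
        values.update(desc.compute_ctd(p))
        values.update(desc.compute_qso(p, params))
        values.update(pc.physchem_block(p))
        values.update(motif_features(p, motifs))
        values.update(pc.ss_propensities(p, provider))
    except Exception as exc:
        raise type(exc)(f"feature extraction failed for {p.id!r}: {exc}") from exc
    vec = np.array([values[n] for n in schema.names], dtype=float)
    return FeatureVector(schema=schema, values=vec, peptide_id=p.id)


@dataclass
class FeatureMatrix:
    """Stacked feature vectors with ids and an optional label column."""

    schema: FeatureSchema
    frame: pd.DataFrame  # index: peptide id; columns: schema names (+ 'label')

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.schema.names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray | None:
        if "label" not in self.frame.columns:
            return None
        return self.frame["label"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "id", out.index)
        cols = ["id"] + (["label"] if "label" in out.columns else [])
        out = out[cols + list(self.schema.names)]
        # %.17g keeps the round trip bitwise-lossless for float64
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, schema: FeatureSchema) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        df = df.set_index("id")
        missing = set(schema.names) - set(df.columns)
        if missing:
            raise ValueError(f"feature CSV missing columns: {sorted(missing)[:5]}")
        return cls(schema=schema, frame=df)


def extract_matrix(data: LabeledDataset | list[Peptide],
                   params: desc.DescriptorParams = desc.DescriptorParams(),
                   motifs: SelectedMotifs = SelectedMotifs(),
                   provider: PropensityProvider | None = None,
                   strict: bool = True) -> FeatureMatrix:
    """Feature matrix for a dataset; rows align with input order.

    In permissive mode peptides whose extraction fails (e.g. too short for
    a lag) are skipped with a log message; strict mode re-raises.
    """
    if isinstance(data, LabeledDataset):
        items = list(data.records)
    else:
        items = [(p, None) for p in data]
    if not items:
        raise ValueError("empty dataset")
    schema = FeatureSchema.default(motifs)
    rows, ids, labels = [], [], []
    for p, y in items:
        try:
            fv = extract_features(p, params, motifs, provider, schema)
        except Exception as exc:
            if strict:
                raise
            log.warning("skipping %r: %s", p.id, exc)
            continue
        rows.append(fv.values)
        ids.append(p.id)
        labels.append(y)
    frame = pd.DataFrame(np.vstack(rows), index=ids, columns=list(schema.names))
    frame.index.name = "id"
    if any(y is not None for y in labels):
        frame["label"] = labels
    return FeatureMatrix(schema=schema, frame=frame)
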