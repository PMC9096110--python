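"""Packaged residue property tables, distance matrices and scale families.

All tables are defined over the 20 standard amino acids only. Two residue
orderings are used in this package and exposed here:

* ``AA`` — alphabetical one-letter order (A, C, D, ... Y), used by every
  composition-like descriptor block, and
* ``AA3`` — alphabetical three-letter order (Ala, Arg, Asn, ... Val), used
  only by the quasi-sequence-order block, which places Tyr at index 19.

Files marked ``synthetic`` in their name are constructed stand-ins for
published tables that could not be redistributed; see the file headers and
``docs/methods.md``.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
#: three-letter alphabetical order (Ala Arg Asn Asp Cys Gln Glu Gly His Ile
#: Leu Lys Met Phe Pro Ser Thr Trp Tyr Val) expressed in one-letter codes
AA3: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")
AA_SET = frozenset(AA)

CTD_PROPERTY_ORDER = (
    "hydrophobicity", "normwaalsvolume", "polarity", "polarizability",
    "charge", "secondarystruct", "solventaccess",
)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files("ahtpscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col=0)


@lru_cache(maxsize=None)
def paac_properties() -> pd.DataFrame:
    """Chou property triple (hydrophobicity, hydrophilicity, side-chain mass)."""
    return _read_tsv("paac_properties.tsv").loc[list(AA)]


@lru_cache(maxsize=None)
def ctd_groups() -> dict[str, tuple[frozenset, frozenset, frozenset]]:
    """Three-group partitions of the alphabet for the seven CTD properties."""
    df = _read_tsv("ctd_groups.tsv").reset_index()
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        out.setdefault(row["property"], []).append(frozenset(row["residues"]))
    return {p: tuple(out[p]) for p in CTD_PROPERTY_ORDER}


@lru_cache(maxsize=None)
def distance_matrix(name: str) -> pd.DataFrame:
    """20x20 amino-acid distance matrix: ``physchem`` or ``grantham``."""
    fname = {"physchem": "distance_physchem_synthetic.tsv",
             "grantham": "distance_grantham.tsv"}[name]
    return _read_tsv(fname)


@lru_cache(maxsize=None)
def zscales() -> pd.DataFrame:
    """Sandberg z-scales z1..z5 (published values)."""
    return _read_tsv("zscales.tsv").loc[list(AA)]


@lru_cache(maxsize=None)
def scale_families() -> dict[str, pd.DataFrame]:
    """All residue-level scale tables, keyed by family name.

    ``Crucian``/``fasgai``/``tscales``/``vhsescales``/``protFP``/``stscales``/
    ``mswhimscore`` are constructed synthetic stand-ins (see data file header);
    ``zscales`` is the published Sandberg table; ``Blosum`` is computed here by
    principal-component analysis of BLOSUM62 (first 8 of 10 components).
    """
    synth = _read_tsv("scales_synthetic.tsv").loc[list(AA)]
    fams: dict[str, pd.DataFrame] = {}
    for fam in ("Crucian", "fasgai", "tscales", "vhsescales", "protFP",
                "stscales", "mswhimscore"):
        cols = [c for c in synth.columns if c.startswith(fam)]
        fams[fam] = synth[cols]
    fams["zscales"] = zscales().copy()
    fams["zscales"].columns = [f"zscales{i}" for i in range(1, 6)]
    fams["Blosum"] = _blosum_descriptors()
    return fams


def _blosum_descriptors() -> pd.DataFrame:
    """First 8 PCA score components of the BLOSUM62 substitution matrix."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    idx = [m.alphabet.index(a) for a in AA]
    b = np.array(m)[np.ix_(idx, idx)].astype(float)
    bz = (b - b.mean(0)) / b.std(0)
    u, s, _ = np.linalg.svd(bz, full_matrices=False)
    scores = u * s
    for j in range(scores.shape[1]):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores[:, :8], index=list(AA),
                        columns=[f"Blosum{i}" for i in range(1, 9)])


# ---------------------------------------------------------------------------
# Small, well-known residue scales kept inline.
# ---------------------------------------------------------------------------

#: Eisenberg consensus hydrophobicity (also the ``hydrophobicity`` alias
#: bound into the comF composite feature, and the moment scale).
EISENBERG = dict(zip(AA, [0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38,
                          -1.50, 1.06, 0.64, -0.78, 0.12, -0.85, -2.53, -0.18,
                          -0.05, 1.08, 0.81, 0.26]))

#: Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE = dict(zip(AA, [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5,
                               -3.9, 3.8, 1.9, -3.5, -1.6, -3.5, -4.5, -0.8,
                               -0.7, 4.2, -0.9, -1.3]))

#: Chou-Fasman conformational preferences.
CHOU_FASMAN_HELIX = dict(zip(AA, [1.42, 0.70, 1.01, 1.51, 1.13, 0.57, 1.00,
                                  1.08, 1.16, 1.21, 1.45, 0.67, 0.57, 1.11,
                                  0.98, 0.77, 0.83, 1.06, 1.08, 0.69]))
CHOU_FASMAN_STRAND = dict(zip(AA, [0.83, 1.19, 0.54, 0.37, 1.38, 0.75, 0.87,
                                   1.60, 0.74, 1.30, 1.05, 0.89, 0.55, 1.10,
                                   0.93, 0.75, 1.19, 1.70, 1.37, 1.47]))
CHOU_FASMAN_TURN = dict(zip(AA, [0.66, 1.19, 1.46, 0.74, 0.60, 1.56, 0.95,
                                 0.47, 1.01, 0.59, 0.60, 1.56, 1.52, 0.98,
                                 0.95, 1.43, 0.96, 0.50, 0.96, 1.14]))

#: Grantham polarity values (used as the polarity scale of the Geary block).
GRANTHAM_POLARITY = dict(zip(AA, [8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2,
                                  11.3, 4.9, 5.7, 11.6, 8.0, 10.5, 10.5, 9.2,
                                  8.6, 5.9, 5.4, 6.2]))

#: Radzicka-Wolfenden style water->cyclohexane transfer free energies used
#: for the Boman (protein-interaction) index. Proline has no published value
#: in this series and is set to 0.
BOMAN_SCALE = dict(zip(AA, [1.81, 1.28, -8.72, -6.81, 2.98, 0.94, -4.66, 4.92,
                            -5.55, 4.92, 2.35, -6.64, 0.0, -5.54, -14.92,
                            -3.40, -2.57, 4.04, 2.33, -0.14]))

#: Lehninger pKa values for ionizable groups.
PKA_NTERM = 9.69
PKA_CTERM = 2.34
PKA_POSITIVE = {"K": 10.53, "R": 12.48, "H": 6.00}
PKA_NEGATIVE = {"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07}

#: Average amino-acid frequencies of globular proteins (Swiss-Prot style
#: background), used by the synthetic generator's negative class.
BACKGROUND_FREQS = dict(zip(AA, [0.0825, 0.0137, 0.0545, 0.0675, 0.0386,
                                 0.0707, 0.0227, 0.0596, 0.0584, 0.0966,
                                 0.0242, 0.0406, 0.0470, 0.0393, 0.0553,
                                 0.0656, 0.0534, 0.0687, 0.0108, 0.0292]))


def zscore_over_alphabet(scale: dict[str, float]) -> dict[str, float]:
    """Zero-mean, unit-variance normalisation of a residue scale over the 20 residues."""
    vals = np.array([scale[a] for a in AA])
    z = (vals - vals.mean()) / vals.std()
    return dict(zip(AA, z))
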