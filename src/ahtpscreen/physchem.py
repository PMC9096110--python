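"""Scale projections, global physicochemical indices, and the pluggable
secondary-structure propensity block.

The 76-component physicochemical block of the feature schema is assembled
here: nine residue-scale families projected by residue-averaging, a set of
whole-peptide indices (aliphatic index, Boman interaction potential, net
charge and isoelectric point, instability index, hydrophobic moments,
Geary autocorrelations, z-scale auto/cross-covariances), and six secondary
structure/aggregation propensities from a provider.

The propensity provider is an interface: the built-in ``surrogate`` scores
aggregation and conformation tendencies from packaged residue preference
tables (Chou-Fasman helix/strand/turn, Kyte-Doolittle windows). It emulates
the role of an external statistical-mechanics propensity program without
reproducing its model; a ``zero`` provider ablates the block.
"""
from __future__ import annotations

import math
from typing import Callable, Protocol

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .peptide_io import Peptide
from .tables import (AA, BOMAN_SCALE, CHOU_FASMAN_HELIX, CHOU_FASMAN_STRAND,
                     CHOU_FASMAN_TURN, EISENBERG, GRANTHAM_POLARITY,
                     KYTE_DOOLITTLE, PKA_CTERM, PKA_NEGATIVE, PKA_NTERM,
                     PKA_POSITIVE, paac_properties, scale_families, zscales)

PROPENSITY_NAMES = ("tango1", "tango2", "tango3", "tango4", "tango5", "tango6")

#: family order of the scale-projection part of the physchem block
SCALE_FAMILY_ORDER = ("Crucian", "zscales", "fasgai", "tscales", "vhsescales",
                      "protFP", "stscales", "mswhimscore")


def scale_projection(p: Peptide, table) -> dict[str, float]:
    """Residue-averaged projection onto a scale table.

    ``table`` is a family name (e.g. ``"zscales"``) or a DataFrame indexed
    by residue with one column per component.
    """
    if isinstance(table, str):
        fams = scale_families()
        if table not in fams:
            raise KeyError(f"unknown scale table {table!r}; "
                           f"known: {sorted(fams)}")
        table = fams[table]
    rows = table.loc[list(p.seq)]
    return {col: float(rows[col].mean()) for col in table.columns}


def net_charge(seq: str, pH: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge at a given pH, termini included."""
    charge = 1.0 / (1.0 + 10 ** (pH - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - pH))
    for res, pka in PKA_POSITIVE.items():
        charge += seq.count(res) / (1.0 + 10 ** (pH - pka))
    for res, pka in PKA_NEGATIVE.items():
        charge -= seq.count(res) / (1.0 + 10 ** (pka - pH))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def hydrophobic_moment(seq: str, angle_deg: float) -> float:
    """Eisenberg hydrophobic moment per residue at a given window angle."""
    delta = math.radians(angle_deg)
    h = [EISENBERG[a] for a in seq]
    s = sum(v * math.sin(k * delta) for k, v in enumerate(h, start=1))
    c = sum(v * math.cos(k * delta) for k, v in enumerate(h, start=1))
    return math.sqrt(s * s + c * c) / len(seq)


def _geary(vals: np.ndarray, d: int) -> float:
    """Geary autocorrelation at lag d; 0 for a zero-variance sequence."""
    n = len(vals)
    var = ((vals - vals.mean()) ** 2).sum()
    if var == 0 or n <= d:
        return 0.0
    num = ((vals[:-d] - vals[d:]) ** 2).sum()
    return float((n - 1) * num / (2.0 * (n - d) * var))


#: the four residue scales behind geary1..geary12 (x lags 1..3)
GEARY_SCALES = ("hydrophobicity", "hydrophilicity", "sidechainmass", "polarity")


def global_indices(p: Peptide, pH: float = 7.0) -> dict[str, float]:
    """Whole-peptide physicochemical indices.

    Returns aIndex, Boman, Charge, pI, Instaindex, Hmoment1/2 (window angles
    100 and 160 degrees), autocov and Crosscov1/2 (lag-1 z-scale
    covariances), and geary1..geary12 (four scales x lags 1..3).
    """
    seq, L = p.seq, len(p)
    out: dict[str, float] = {}

    # aliphatic index on mole-percent composition
    mp = {a: 100.0 * seq.count(a) / L for a in AA}
    out["aIndex"] = mp["A"] + 2.9 * mp["V"] + 3.9 * (mp["I"] + mp["L"])

    out["Boman"] = -sum(BOMAN_SCALE[a] for a in seq) / L
    out["Charge"] = net_charge(seq, pH)
    out["pI"] = isoelectric_point(seq)
    out["Instaindex"] = float(ProteinAnalysis(seq).instability_index())
    out["Hmoment1"] = hydrophobic_moment(seq, 100.0)
    out["Hmoment2"] = hydrophobic_moment(seq, 160.0)

    zs = zscales()
    z1 = zs["z1"].loc[list(seq)].to_numpy()
    z2 = zs["z2"].loc[list(seq)].to_numpy()
    out["autocov"] = float((z1[:-1] * z1[1:]).mean())
    out["Crosscov1"] = float((z1[:-1] * z2[1:]).mean())
    out["Crosscov2"] = float((z2[:-1] * z1[1:]).mean())

    props = paac_properties()
    scale_lookup = {
        "hydrophobicity": props["hydrophobicity"].to_dict(),
        "hydrophilicity": props["hydrophilicity"].to_dict(),
        "sidechainmass": props["sidechainmass"].to_dict(),
        "polarity": GRANTHAM_POLARITY,
    }
    k = 0
    for scale_name in GEARY_SCALES:
        vals = np.array([scale_lookup[scale_name][a] for a in seq])
        for d in (1, 2, 3):
            k += 1
            out[f"geary{k}"] = _geary(vals, d)
    return out


class PropensityProvider(Protocol):
    name: str

    def __call__(self, p: Peptide) -> dict[str, float]: ...


class SurrogatePropensityProvider:
    """Deterministic aggregation/conformation propensity scorer.

    Six non-negative values per peptide:

    * ``tango1`` aggregation — mean over length-5 windows of
      max(0, mean Kyte-Doolittle hydropathy of the window)
    * ``tango2`` amyloid — aggregation x mean strand preference
    * ``tango3`` turn — mean Chou-Fasman turn preference
    * ``tango4`` alpha-helix — mean Chou-Fasman helix preference
    * ``tango5`` helical aggregation — aggregation x mean helix preference
    * ``tango6`` beta-strand — mean Chou-Fasman strand preference
    """

    name = "surrogate"
    window = 5

    def __call__(self, p: Peptide) -> dict[str, float]:
        seq = p.seq
        win = min(self.window, len(seq))
        kd = [KYTE_DOOLITTLE[a] for a in seq]
        windows = [sum(kd[i:i + win]) / win for i in range(len(seq) - win + 1)]
        agg = sum(max(0.0, wv) for wv in windows) / len(windows)
        helix = sum(CHOU_FASMAN_HELIX[a] for a in seq) / len(seq)
        strand = sum(CHOU_FASMAN_STRAND[a] for a in seq) / len(seq)
        turn = sum(CHOU_FASMAN_TURN[a] for a in seq) / len(seq)
        vals = (agg, agg * strand, turn, helix, agg * helix, strand)
        return dict(zip(PROPENSITY_NAMES, vals))


class ZeroPropensityProvider:
    """Ablation provider: all six propensities are zero."""

    name = "zero"

    def __call__(self, p: Peptide) -> dict[str, float]:
        return dict.fromkeys(PROPENSITY_NAMES, 0.0)


def get_provider(name: str) -> PropensityProvider:
    if name == "surrogate":
        return SurrogatePropensityProvider()
    if name == "zero":
        return ZeroPropensityProvider()
    raise KeyError(f"unknown propensity provider {name!r}")


def ss_propensities(p: Peptide,
                    provider: PropensityProvider | None = None) -> dict[str, float]:
    """Six named propensity values from the given provider (default surrogate)."""
    provider = provider or SurrogatePropensityProvider()
    try:
        vals = provider(p)
    except Exception as exc:  # surface provider failures with context
        raise RuntimeError(
            f"propensity provider {getattr(provider, 'name', provider)!r} "
            f"failed on {p.id!r}: {exc}") from exc
    out = {k: float(vals[k]) for k in PROPENSITY_NAMES}
    if any(not math.isfinite(v) for v in out.values()):
        raise ValueError(f"provider {provider.name!r} returned non-finite values")
    return out


def physchem_block(p: Peptide, pH: float = 7.0) -> dict[str, float]:
    """The 70 scale/index components (everything except the propensities).

    Order: Crucian, zscales, fasgai, tscales, vhsescales, protFP, stscales,
    mswhimscore, aIndex, geary1-12, autocov, Boman, Charge, Crosscov1-2,
    Instaindex, Hmoment1, Hmoment2, Blosum1-8, pI.
    """
    out: dict[str, float] = {}
    for fam in SCALE_FAMILY_ORDER:
        out.update(scale_projection(p, fam))
    gi = global_indices(p, pH)
    out["aIndex"] = gi["aIndex"]
    for k in range(1, 13):
        out[f"geary{k}"] = gi[f"geary{k}"]
    out["autocov"] = gi["autocov"]
    out["Boman"] = gi["Boman"]
    out["Charge"] = gi["Charge"]
    out["Crosscov1"] = gi["Crosscov1"]
    out["Crosscov2"] = gi["Crosscov2"]
    out["Instaindex"] = gi["Instaindex"]
    out["Hmoment1"] = gi["Hmoment1"]
    out["Hmoment2"] = gi["Hmoment2"]
    out.update(scale_projection(p, "Blosum"))
    out["pI"] = gi["pI"]
    return out
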