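"""Sequence-order-aware descriptor blocks: AAC, PseAAC variants, CTD, QSO.

Residue ordering conventions
----------------------------
All composition-like blocks (AAC, the PseAAC first-20 components, CTD) use
alphabetical one-letter order A, C, D, ... Y; the quasi-sequence-order block
uses alphabetical three-letter order (Ala ... Val), which places Tyr at
index 19. This mixed convention is fixed by the feature schema.

PseAAC correlation functions
----------------------------
Every pseudo-composition mode here — including the two amphiphilic blocks
and the series-correlation block — uses squared differences of normalised
residue properties as its correlation function, so all coupling terms vanish
exactly on homopolymers. For the amphiphilic blocks this replaces the
classical product-form correlation; see docs/methods.md.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .peptide_io import Peptide
from .tables import (AA, AA3, CTD_PROPERTY_ORDER, ctd_groups, distance_matrix,
                     paac_properties, zscore_over_alphabet)

PSEAAC_MODES = ("PAAC", "Pse_PC", "Pse_SC", "APAAC_hydrophobicity",
                "APAAC_hydrophilicity")

#: output dimensionality per pseudo-composition mode
PSEAAC_DIMS = {"PAAC": 23, "Pse_PC": 22, "Pse_SC": 26,
               "APAAC_hydrophobicity": 23, "APAAC_hydrophilicity": 23}


@dataclass(frozen=True)
class DescriptorParams:
    """Lags and weights of the sequence-order descriptor blocks.

    ``lambda_paac`` applies to the PAAC, series and amphiphilic modes;
    ``lambda_pc`` to the parallel-correlation mode (whose 22-dim layout
    implies lambda = 2); ``maxlag_qso`` to the quasi-sequence-order block.
    """

    lambda_paac: int = 3
    weight_paac: float = 0.05
    lambda_pc: int = 2
    maxlag_qso: int = 3
    weight_qso: float = 0.1

    def __post_init__(self):
        if min(self.lambda_paac, self.lambda_pc, self.maxlag_qso) < 1:
            raise ValueError("all lags must be >= 1")
        if self.weight_paac <= 0 or self.weight_qso <= 0:
            raise ValueError("weights must be > 0")


def compute_aac(p: Peptide) -> dict[str, float]:
    """Fractions of the 20 residue types, named AAC1..AAC20 in A..Y order."""
    L = len(p)
    counts = {a: 0 for a in AA}
    for res in p.seq:
        counts[res] += 1
    return {f"AAC{i + 1}": counts[a] / L for i, a in enumerate(AA)}


def _normalized_props(names: list[str]) -> list[dict[str, float]]:
    props = paac_properties()
    return [zscore_over_alphabet(props[n].to_dict()) for n in names]


def _theta_diff(seq: str, d: int, props: list[dict[str, float]]) -> float:
    """Mean squared-difference correlation at lag d, averaged over properties."""
    L = len(seq)
    total = 0.0
    for i in range(L - d):
        a, b = seq[i], seq[i + d]
        total += sum((pr[a] - pr[b]) ** 2 for pr in props) / len(props)
    return total / (L - d)


def compute_pseaac(p: Peptide, mode: str,
                   params: DescriptorParams = DescriptorParams()) -> dict[str, float]:
    """Pseudo amino-acid composition in one of five modes.

    Modes and layouts (first 20 components are A..Y composition-like):

    * ``PAAC`` — lambda coupling terms from the property triple (23 dims)
    * ``Pse_PC`` — parallel correlation, lambda_pc terms (22 dims)
    * ``Pse_SC`` — series correlation: per-property terms interleaved by lag
      over hydrophobicity and hydrophilicity (20 + 2*lambda = 26 dims)
    * ``APAAC_hydrophobicity`` / ``APAAC_hydrophilicity`` — amphiphilic
      blocks with a single-property correlation function (23 dims each)
    """
    if mode not in PSEAAC_MODES:
        raise ValueError(f"unknown PseAAC mode {mode!r}")
    seq, L = p.seq, len(p)
    w = params.weight_paac

    if mode == "PAAC":
        lam = params.lambda_paac
        prop_sets = [_normalized_props(["hydrophobicity", "hydrophilicity",
                                        "sidechainmass"])] * lam
        prefix = "PAAC"
    elif mode == "Pse_PC":
        lam = params.lambda_pc
        prop_sets = [_normalized_props(["hydrophobicity", "hydrophilicity",
                                        "sidechainmass"])] * lam
        prefix = "Pse_PC"
    elif mode == "Pse_SC":
        lam = params.lambda_paac
        hb, hl = _normalized_props(["hydrophobicity", "hydrophilicity"])
        # series layout: (lag1 hb, lag1 hl, lag2 hb, lag2 hl, ...)
        prop_sets = None
        prefix = "Pse_SC"
    else:
        lam = params.lambda_paac
        name = ("hydrophobicity" if mode == "APAAC_hydrophobicity"
                else "hydrophilicity")
        prop_sets = [_normalized_props([name])] * lam
        prefix = "APAAC1" if mode == "APAAC_hydrophobicity" else "APAAC2"

    if mode == "Pse_SC":
        if L <= lam:
            raise ValueError(f"peptide length {L} <= lambda {lam} for mode {mode}")
        thetas = []
        for d in range(1, lam + 1):
            thetas.append(_theta_diff(seq, d, [hb]))
            thetas.append(_theta_diff(seq, d, [hl]))
    else:
        if L <= lam:
            raise ValueError(f"peptide length {L} <= lambda {lam} for mode {mode}")
        thetas = [_theta_diff(seq, d, prop_sets[d - 1]) for d in range(1, lam + 1)]

    freqs = np.array([seq.count(a) for a in AA], dtype=float) / L
    denom = freqs.sum() + w * sum(thetas)
    values = {}
    sep = "_" if prefix.startswith("APAAC") else ""
    for i in range(20):
        values[f"{prefix}{sep}{i + 1}"] = freqs[i] / denom
    for k, th in enumerate(thetas, start=21):
        values[f"{prefix}{sep}{k}"] = w * th / denom
    return values


def _quantile_index(q: float, n: int) -> int:
    """Occurrence index of the q-quantile point: round-half-up(q*n), min 1."""
    return max(1, math.floor(q * n + 0.5))


def compute_ctd(p: Peptide) -> dict[str, float]:
    """Composition/transition/distribution descriptors (147 components).

    Per property (fixed order: hydrophobicity, van der Waals volume,
    polarity, polarizability, charge, secondary structure, solvent
    accessibility): 3 group fractions, 3 unordered cross-group adjacent-pair
    frequencies over L-1, and 5 positional percentiles (first, 25%, 50%,
    75%, last occurrence, as percent of L) for each of the 3 groups; a group
    absent from the sequence contributes zeros.
    """
    seq, L = p.seq, len(p)
    groups = ctd_groups()
    values: dict[str, float] = {}
    ic = it = idist = 0
    for prop in CTD_PROPERTY_ORDER:
        gsets = groups[prop]
        gidx = [next(k for k, g in enumerate(gsets) if res in g) for res in seq]
        # composition
        for g in range(3):
            ic += 1
            values[f"CTDC{ic}"] = gidx.count(g) / L
        # transitions: unordered pairs (0,1), (0,2), (1,2)
        pairs = [(0, 1), (0, 2), (1, 2)]
        tcounts = {pr: 0 for pr in pairs}
        for a, b in zip(gidx, gidx[1:]):
            if a != b:
                tcounts[(min(a, b), max(a, b))] += 1
        for pr in pairs:
            it += 1
            values[f"CTDT{it}"] = tcounts[pr] / (L - 1)
        # distribution
        for g in range(3):
            positions = [i + 1 for i, x in enumerate(gidx) if x == g]
            n = len(positions)
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                idist += 1
                if n == 0:
                    values[f"CTDD{idist}"] = 0.0
                else:
                    idx = 1 if q == 0.0 else _quantile_index(q, n)
                    values[f"CTDD{idist}"] = 100.0 * positions[idx - 1] / L
    return values


def compute_qso(p: Peptide,
                params: DescriptorParams = DescriptorParams()) -> dict[str, float]:
    """Quasi-sequence-order descriptors and sequence-order-coupling numbers.

    For each of the two packaged distance matrices (physicochemical, then
    Grantham): coupling numbers tau_d = sum_i d(R_i, R_{i+d})^2 for
    d = 1..maxlag (SOCN1..6), then 20 normalised residue occurrences in
    three-letter alphabetical order followed by the 3 weighted coupling
    components (QSO1..46). Each matrix's 23 QSO components sum to 1.
    """
    seq, L = p.seq, len(p)
    maxlag, w = params.maxlag_qso, params.weight_qso
    if L <= maxlag:
        raise ValueError(f"peptide length {L} <= maxlag {maxlag}")
    values: dict[str, float] = {}
    qso_vals: list[float] = []
    socn_vals: list[float] = []
    for mat_name in ("physchem", "grantham"):
        dm = distance_matrix(mat_name)
        taus = []
        for d in range(1, maxlag + 1):
            tau = sum(dm.at[seq[i], seq[i + d]] ** 2 for i in range(L - d))
            taus.append(float(tau))
        socn_vals.extend(taus)
        freqs = np.array([seq.count(a) for a in AA3], dtype=float) / L
        denom = freqs.sum() + w * sum(taus)
        qso_vals.extend(freqs / denom)
        qso_vals.extend(w * t / denom for t in taus)
    for i, v in enumerate(qso_vals, start=1):
        values[f"QSO{i}"] = float(v)
    for i, v in enumerate(socn_vals, start=1):
        values[f"SOCN{i}"] = v
    return values
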