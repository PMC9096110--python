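"""Synthetic labeled peptide datasets with controllable AHTP-like signal.

The generator emulates the shape of real AHTP screening data: short
peptides (lengths ~5-30, geometric-like with mean near 8), positives
enriched in Pro/Tyr/His/Trp and depleted in Asp/Glu/Cys/Met, with short
proline-containing motifs (YP, VP, PP, VLP) planted at random positions;
negatives are drawn from an average globular-protein background
composition, standing in for random protein fragments. It makes every
pipeline stage testable without downloads; it does not model ACE-inhibition
chemistry or IC50 values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peptide_io import (LabeledDataset, NEGATIVE_LABEL, POSITIVE_LABEL,
                         Peptide, validate_peptide)
from .tables import AA, BACKGROUND_FREQS


@dataclass
class SimConfig:
    """Generation parameters; the defaults define the standard conditions.

    ``composition_bias`` multiplies background residue frequencies for the
    positive class (then renormalises); ``plant_probability`` is the chance
    a positive receives one planted motif at a random position (interior or
    terminal).
    """

    n_pos: int = 1000
    n_neg: int = 1000
    min_length: int = 5
    max_length: int = 30
    mean_length: float = 8.0
    composition_bias: dict = field(default_factory=lambda: {
        "P": 2.0, "Y": 1.8, "H": 1.6, "W": 1.3,
        "D": 0.5, "E": 0.6, "C": 0.4, "M": 0.5})
    planted_motifs: tuple[str, ...] = ("YP", "VP", "PP", "VLP")
    plant_probability: float = 0.9
    background: dict = field(default_factory=lambda: dict(BACKGROUND_FREQS))
    seed: int = 0

    def __post_init__(self):
        if self.min_length < 5:
            raise ValueError("min_length must be >= 5")
        if any(len(m) > self.max_length for m in self.planted_motifs):
            raise ValueError("motif longer than max_length")
        if not 0.0 <= self.plant_probability <= 1.0:
            raise ValueError("plant_probability must be in [0, 1]")

    def class_frequencies(self, positive: bool) -> np.ndarray:
        f = np.array([self.background[a] for a in AA], dtype=float)
        if positive:
            for a, mult in self.composition_bias.items():
                f[AA.index(a)] *= mult
        return f / f.sum()


def _sample_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    # geometric-like with the configured mean, truncated to [min, max]
    p = 1.0 / max(cfg.mean_length - cfg.min_length + 1, 1.0)
    while True:
        L = cfg.min_length + rng.geometric(p) - 1
        if L <= cfg.max_length:
            return int(L)


def generate_dataset(cfg: SimConfig) -> tuple[LabeledDataset, dict]:
    """Sample a labeled dataset; bitwise-reproducible given ``cfg.seed``.

    Returns the dataset and a generation log (per-class counts, how many
    positives received a planted motif, which motifs were used).
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    aa = np.array(AA)
    n_planted = 0
    motif_uses: dict[str, int] = {m: 0 for m in cfg.planted_motifs}

    for label, n, positive in ((POSITIVE_LABEL, cfg.n_pos, True),
                               (NEGATIVE_LABEL, cfg.n_neg, False)):
        freqs = cfg.class_frequencies(positive)
        for i in range(n):
            L = _sample_length(cfg, rng)
            seq = "".join(rng.choice(aa, size=L, p=freqs))
            if positive and cfg.planted_motifs and \
                    rng.random() < cfg.plant_probability:
                motif = cfg.planted_motifs[rng.integers(len(cfg.planted_motifs))]
                start = int(rng.integers(0, L - len(motif) + 1))
                seq = seq[:start] + motif + seq[start + len(motif):]
                n_planted += 1
                motif_uses[motif] += 1
            ok, reason = validate_peptide(seq, cfg.min_length)
            assert ok, reason
            prefix = "pos" if positive else "neg"
            records.append((Peptide(f"{prefix}{i + 1}", seq), label))

    log = {"n_pos": cfg.n_pos, "n_neg": cfg.n_neg, "n_planted": n_planted,
           "motif_uses": motif_uses, "seed": cfg.seed}
    return LabeledDataset(records), log
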