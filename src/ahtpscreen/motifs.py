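"""k-mer enrichment, motif features, terminal positional analysis, and
physicochemical composition profiling of peptide corpora.

Enrichment of a k-mer in the positive (AHTP) corpus over the negative
corpus is scored as a pseudo-counted log-odds ratio of overlapping
sliding-window frequencies:

    score(m) = log2( (c+(m) + a) / (T+ + a*V)  /  ((c-(m) + a) / (T- + a*V)) )

with V = 20^k and pseudo-count a (default 0.5), which keeps every score
finite. The 13 default selected motifs are the top 2-mer and top 12 3-mers
found on the published training corpora.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from math import log2

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .peptide_io import Peptide
from .tables import AA, AA_SET

log = logging.getLogger(__name__)

#: default selected motifs: the top 2-mer followed by the top 12 3-mers
DEFAULT_MOTIFS = ("YP", "HLP", "IYP", "LHL", "LPP", "LRP", "VPP",
                  "PEV", "PFP", "QTP", "VLP", "VYP", "YPF")

#: Table-style physicochemical residue categories for composition profiling
COMPOSITION_CATEGORIES = {
    "charged": set("DEKHR"),
    "aliphatic": set("ILV"),
    "aromatic": set("FHWY"),
    "polar": set("DERKQN"),
    "neutral": set("AGHPSTY"),
    "hydrophobic": set("CVLIMFW"),
    "positively_charged": set("HKR"),
    "negatively_charged": set("DE"),
    "tiny": set("ACDGST"),
    "small": set("EHILKMNPQV"),
    "large": set("FRWY"),
}


@dataclass
class MotifTable:
    """Per-k-mer counts, frequencies and log-odds scores for a corpus pair."""

    k: int
    table: pd.DataFrame  # index: kmer; columns: count_pos, count_neg, Pa, Na, score

    def top(self, n: int) -> list[str]:
        """Top-n k-mers by descending score; ties broken lexicographically."""
        df = self.table.sort_values(["score"], ascending=False, kind="mergesort")
        order = sorted(df.index, key=lambda m: (-df.at[m, "score"], m))
        return order[:n]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class SelectedMotifs:
    """Ordered motif list used for the motif-count feature block."""

    motifs: tuple[str, ...] = DEFAULT_MOTIFS

    def __post_init__(self):
        self.motifs = tuple(self.motifs)
        for m in self.motifs:
            if not m or any(c not in AA_SET for c in m):
                raise ValueError(f"motif {m!r} not over the 20-letter alphabet")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)


def count_kmers(seqs: list[str], k: int) -> Counter:
    """Overlapping sliding-window k-mer counts over a corpus."""
    counts: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            counts[s[i:i + k]] += 1
    return counts


def kmer_logodds(pos: list[Peptide], neg: list[Peptide], k: int,
                 pseudo: float = 0.5) -> MotifTable:
    """Log-odds enrichment table of all observed k-mers, positives vs negatives."""
    if not pos or not neg:
        raise ValueError("both corpora must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    cpos = count_kmers([p.seq for p in pos], k)
    cneg = count_kmers([p.seq for p in neg], k)
    if not cpos and not cneg:
        raise ValueError(f"k={k} exceeds every sequence length")
    V = 20 ** k
    tpos, tneg = sum(cpos.values()), sum(cneg.values())
    rows = []
    for m in sorted(set(cpos) | set(cneg)):
        pa = (cpos[m] + pseudo) / (tpos + pseudo * V)
        na = (cneg[m] + pseudo) / (tneg + pseudo * V)
        rows.append((m, cpos[m], cneg[m], pa, na, log2(pa / na)))
    df = pd.DataFrame(rows, columns=["kmer", "count_pos", "count_neg",
                                     "Pa", "Na", "score"]).set_index("kmer")
    return MotifTable(k=k, table=df)


def select_top_motifs(table2: MotifTable, table3: MotifTable,
                      n2: int = 1, n3: int = 12) -> SelectedMotifs:
    """Top-n2 2-mers and top-n3 3-mers by descending log-odds score."""
    if n2 > len(table2.table) or n3 > len(table3.table):
        raise ValueError("requested more motifs than available k-mers")
    chosen = tuple(table2.top(n2)) + tuple(table3.top(n3))
    return SelectedMotifs(chosen) if chosen else SelectedMotifs(())


def count_overlapping(seq: str, motif: str) -> int:
    k = len(motif)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] == motif)


def motif_features(p: Peptide,
                   motifs: SelectedMotifs = SelectedMotifs()) -> dict[str, int]:
    """Overlapping occurrence count of each selected motif."""
    return {f"motif_{m}": count_overlapping(p.seq, m) for m in motifs}


def terminal_logodds(pos: list[Peptide], neg: list[Peptide], end: str,
                     span: int = 5, pseudo: float = 0.5,
                     strict: bool = False):
    """Positional residue log-odds at the N- or C-terminus.

    Returns ``(logodds, freq_pos, freq_neg)``: 20 x span DataFrames (rows
    A..Y, columns position 1..span). C-terminal positions count inward from
    the C-terminus. Sequences shorter than ``span`` are excluded with a
    warning (strict mode: error). Each frequency column is pseudo-counted
    and sums to 1.
    """
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")

    def usable(peps):
        kept = []
        for p in peps:
            if len(p) < span:
                msg = f"{p.id!r} shorter than span {span}"
                if strict:
                    raise ValueError(msg)
                log.warning("terminal analysis: skipping %s", msg)
                continue
            kept.append(p)
        return kept

    def pos_freqs(peps):
        counts = np.zeros((20, span))
        aidx = {a: i for i, a in enumerate(AA)}
        for p in peps:
            window = p.seq[:span] if end == "N" else p.seq[-span:][::-1]
            for j, res in enumerate(window):
                counts[aidx[res], j] += 1
        freqs = (counts + pseudo) / (counts.sum(0, keepdims=True) + 20 * pseudo)
        return pd.DataFrame(freqs, index=list(AA),
                            columns=[f"pos{j + 1}" for j in range(span)])

    fpos = pos_freqs(usable(pos))
    fneg = pos_freqs(usable(neg))
    return np.log2(fpos / fneg), fpos, fneg


def composition_profile(peptides: list[Peptide]) -> dict[str, float]:
    """Per-peptide mean category percentages plus mean length and mass.

    Categories follow the standard physicochemical groupings (charged,
    aliphatic, aromatic, polar, neutral, hydrophobic, positively/negatively
    charged, tiny, small, large); each value is the mean over peptides of
    the percent of residues falling in the category. Mass is the average
    molecular weight of the free peptide (Da).
    """
    if not peptides:
        raise ValueError("empty dataset")
    out: dict[str, float] = {}
    for cat, members in COMPOSITION_CATEGORIES.items():
        pcts = [100.0 * sum(1 for r in p.seq if r in members) / len(p)
                for p in peptides]
        out[f"pct_{cat}"] = float(np.mean(pcts))
    out["mean_length"] = float(np.mean([len(p) for p in peptides]))
    out["mean_molecular_weight"] = float(np.mean(
        [molecular_weight(p.seq, seq_type="protein") for p in peptides]))
    return out
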