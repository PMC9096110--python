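"""Rank k-mers enriched in AHTP-like peptides over background peptides.

Builds a synthetic corpus pair with planted proline motifs, scores every
2-mer and 3-mer with pseudo-counted log2 odds ratios, and reports the top
motifs plus terminal position preferences and the composition profile.
"""
from ahtpscreen import (SimConfig, composition_profile, generate_dataset,
                        kmer_logodds, select_top_motifs, terminal_logodds)

data, log = generate_dataset(SimConfig(n_pos=600, n_neg=600, seed=4))
pos = data.subset(["AHTP"]).peptides
neg = data.subset(["nonAHTP"]).peptides

t2 = kmer_logodds(pos, neg, k=2)
t3 = kmer_logodds(pos, neg, k=3)
print("top five 2-mers (log2 odds, positive = AHTP-enriched):")
for m in t2.top(5):
    print(f"  {m}: {t2.table.at[m, 'score']:+.2f}")
print("selected motif set:", list(select_top_motifs(t2, t3)))

lo, fp, fn = terminal_logodds(pos, neg, end="N")
print("\nN-terminal position-1 log-odds of P:",
      f"{lo.at['P', 'pos1']:+.2f}")

prof_pos = composition_profile(pos)
prof_neg = composition_profile(neg)
print(f"\nmean %% neutral residues: AHTP {prof_pos['pct_neutral']:.1f} "
      f"vs background {prof_neg['pct_neutral']:.1f}")
print(f"mean length: {prof_pos['mean_length']:.2f} vs "
      f"{prof_neg['mean_length']:.2f}")
# A positive log-odds means the k-mer (or residue at that position) is more
# frequent in the AHTP corpus; the planted YP/VP/PP motifs surface at the top.
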