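"""Compute the 431-component descriptor vector of a few known AHTPs.

Each peptide is encoded as named blocks: amino-acid composition, four
pseudo-composition variants, composition/transition/distribution, quasi-
sequence-order, physicochemical scales and indices, motif counts, and
secondary-structure propensities.
"""
from ahtpscreen import Peptide, extract_features

for seq in ("YLYELR", "AFPYYGHHLG", "LVPPHA"):
    fv = extract_features(Peptide(seq, seq))
    print(f"\n{seq}: {fv.schema.dimension} features "
          f"(schema {fv.schema.hash})")
    for name in ("AAC13", "PAAC1", "Pse_PC13", "APAAC1_15", "CTDC10",
                 "CTDC19", "CTDD49", "QSO19", "aIndex", "Charge", "pI",
                 "Instaindex", "motif_YP", "tango1"):
        print(f"  {name:>10} = {fv[name]: .4f}")

# AAC13 is the Pro fraction; Pse_PC13/QSO19/APAAC1_15 are the Pro/Tyr/Arg
# slots of their blocks; CTDC10/19 are group fractions (low-polarizability,
# buried); aIndex/Charge/pI/Instaindex are whole-peptide indices; motif_YP
# counts the top enriched 2-mer.
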