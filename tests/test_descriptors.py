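"""Descriptor-block tests, including independent straight-line oracles for
the pseudo-composition, CTD and quasi-sequence-order formulas."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ahtpscreen import DescriptorParams, Peptide, compute_aac, compute_ctd, \
    compute_pseaac, compute_qso
from ahtpscreen.descriptors import PSEAAC_DIMS, PSEAAC_MODES
from ahtpscreen.tables import AA, AA3, ctd_groups, distance_matrix, \
    paac_properties

peptide_seqs = st.text(alphabet=list(AA), min_size=5, max_size=25)


# ---------------------------------------------------------------------------
# independent oracle implementations (straight-line, no package code)
# ---------------------------------------------------------------------------

from oracles import paac_oracle, qso_oracle


def ctd_distribution_oracle(seq, prop):
    """Exhaustive positional enumeration of the 15 distribution values."""
    gsets = ctd_groups()[prop]
    L = len(seq)
    out = []
    for g in gsets:
        positions = [i + 1 for i, r in enumerate(seq) if r in g]
        n = len(positions)
        if n == 0:
            out.extend([0.0] * 5)
            continue
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            idx = 1 if q == 0.0 else max(1, math.floor(q * n + 0.5))
            out.append(100.0 * positions[idx - 1] / L)
    return out


# ---------------------------------------------------------------------------
# AAC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seq,expected", [
    ("AAAAA", {"A": 1.0}),
    ("ACDEF", {"A": 0.2, "C": 0.2, "D": 0.2, "E": 0.2, "F": 0.2}),
    ("YLYELR", {"Y": 2 / 6, "L": 2 / 6, "E": 1 / 6, "R": 1 / 6}),
])
def test_aac_hand_counts(seq, expected):
    aac = compute_aac(Peptide("p", seq))
    for i, a in enumerate(AA):
        assert aac[f"AAC{i + 1}"] == pytest.approx(expected.get(a, 0.0))
    assert sum(aac.values()) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=40)
@given(peptide_seqs, st.randoms(use_true_random=False))
def test_aac_and_ctdc_shuffle_invariant(seq, rnd):
    shuffled = list(seq)
    rnd.shuffle(shuffled)
    q = "".join(shuffled)
    assert compute_aac(Peptide("a", seq)) == compute_aac(Peptide("b", q))
    c1 = compute_ctd(Peptide("a", seq))
    c2 = compute_ctd(Peptide("b", q))
    for k in c1:
        if k.startswith("CTDC"):
            assert c1[k] == pytest.approx(c2[k])


def test_socn_is_order_sensitive():
    # a shuffle that changes residue adjacency must change the coupling numbers
    a = compute_qso(Peptide("a", "YLYELR"))
    b = compute_qso(Peptide("b", "RYLYEL"[::-1]))  # LEYLYR
    assert any(a[f"SOCN{i}"] != pytest.approx(b[f"SOCN{i}"]) for i in range(1, 7))


# ---------------------------------------------------------------------------
# PseAAC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", PSEAAC_MODES)
def test_pseaac_dimensions_and_homopolymer(mode):
    vals = compute_pseaac(Peptide("p", "AAAAA"), mode)
    assert len(vals) == PSEAAC_DIMS[mode]
    # first block: only the A component is nonzero; all coupling terms vanish
    names = list(vals)
    first20 = names[:20]
    assert vals[first20[0]] == pytest.approx(1.0)   # A is first alphabetically
    assert all(vals[n] == 0.0 for n in first20[1:])
    assert all(vals[n] == 0.0 for n in names[20:])


@pytest.mark.parametrize("mode", ["PAAC", "APAAC_hydrophobicity",
                                  "APAAC_hydrophilicity", "Pse_PC", "Pse_SC"])
def test_pseaac_components_sum_to_one(mode, ylyelr):
    vals = compute_pseaac(ylyelr, mode)
    assert sum(vals.values()) == pytest.approx(1.0, abs=1e-12)


def test_paac_matches_straight_line_oracle(ylyelr):
    vals = compute_pseaac(ylyelr, "PAAC")
    expected = paac_oracle(ylyelr.seq)
    got = [vals[f"PAAC{i}"] for i in range(1, 24)]
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_pseaac_length_guard():
    with pytest.raises(ValueError, match="lambda"):
        compute_pseaac(Peptide("p", "YPFVA"), "PAAC",
                       DescriptorParams(lambda_paac=5))


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def test_ctd_dimensions_and_composition_sums(ylyelr):
    vals = compute_ctd(ylyelr)
    assert len(vals) == 147
    comp = [vals[f"CTDC{i}"] for i in range(1, 22)]
    for p in range(7):
        assert sum(comp[3 * p:3 * p + 3]) == pytest.approx(1.0)


def test_ctd_single_group_sequence():
    vals = compute_ctd(Peptide("p", "GGGGG"))
    # polarizability is property 4 -> CTDC10..12; G is in group 1 (G,A,S,D,T)
    assert (vals["CTDC10"], vals["CTDC11"], vals["CTDC12"]) == (1.0, 0.0, 0.0)
    # no adjacent pair ever crosses groups
    assert all(vals[f"CTDT{i}"] == 0.0 for i in range(1, 22))


def test_ctd_buried_group_homopolymer():
    # solvent accessibility is property 7; A belongs to the buried group
    vals = compute_ctd(Peptide("p", "AAAAA"))
    assert vals["CTDC19"] == 1.0


def test_ctd_distribution_worked_example():
    vals = compute_ctd(Peptide("p", "GAGAG"))
    got = [vals[f"CTDD{k}"] for k in range(46, 51)]  # polarizability group 1
    assert got == [20.0, 20.0, 60.0, 80.0, 100.0]
    assert got == ctd_distribution_oracle("GAGAG", "polarizability")[:5]


@settings(derandomize=True, max_examples=40)
@given(peptide_seqs)
def test_ctd_distribution_matches_enumeration(seq):
    vals = compute_ctd(Peptide("p", seq))
    for p_idx, prop in enumerate(("hydrophobicity", "normwaalsvolume",
                                  "polarity", "polarizability", "charge",
                                  "secondarystruct", "solventaccess")):
        expected = ctd_distribution_oracle(seq, prop)
        got = [vals[f"CTDD{15 * p_idx + j}"] for j in range(1, 16)]
        np.testing.assert_allclose(got, expected)


def test_ctd_transitions_hand_count():
    # "GAGAG": secondary structure is property 6 -> CTDT16..18 covering the
    # unordered group pairs (1,2), (1,3), (2,3). A is helix (group 1) and G
    # is coil (group 3), so all 4 adjacent pairs cross pair (1,3): 4/4 = 1.
    vals = compute_ctd(Peptide("p", "GAGAG"))
    assert (vals["CTDT16"], vals["CTDT17"], vals["CTDT18"]) == (0.0, 1.0, 0.0)
    # polarizability (property 4): G and A share group 1 -> no crossings
    assert (vals["CTDT10"], vals["CTDT11"], vals["CTDT12"]) == (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# QSO
# ---------------------------------------------------------------------------

def test_qso_homopolymer_degeneracy():
    vals = compute_qso(Peptide("p", "AAAAA"))
    # Ala is index 1 in the three-letter ordering for both matrices
    assert vals["QSO1"] == pytest.approx(1.0)
    assert vals["QSO24"] == pytest.approx(1.0)
    assert all(vals[f"SOCN{i}"] == 0.0 for i in range(1, 7))
    assert all(vals[f"QSO{i}"] == 0.0 for i in (21, 22, 23, 44, 45, 46))


def test_qso_blocks_sum_to_one(ylyelr):
    vals = compute_qso(ylyelr)
    assert sum(vals[f"QSO{i}"] for i in range(1, 24)) == pytest.approx(1.0)
    assert sum(vals[f"QSO{i}"] for i in range(24, 47)) == pytest.approx(1.0)


def test_qso_matches_straight_line_oracle(ylyelr):
    vals = compute_qso(ylyelr)
    exp_qso, exp_socn = qso_oracle(ylyelr.seq)
    np.testing.assert_allclose([vals[f"QSO{i}"] for i in range(1, 47)],
                               exp_qso, atol=1e-10)
    np.testing.assert_allclose([vals[f"SOCN{i}"] for i in range(1, 7)],
                               exp_socn, atol=1e-10)


def test_qso_length_guard():
    with pytest.raises(ValueError, match="maxlag"):
        compute_qso(Peptide("p", "YPFVA"), DescriptorParams(maxlag_qso=5))


@settings(derandomize=True, max_examples=25)
@given(peptide_seqs)
def test_all_descriptors_finite(seq):
    p = Peptide("p", seq)
    blocks = [compute_aac(p), compute_ctd(p), compute_qso(p)]
    blocks += [compute_pseaac(p, m) for m in PSEAAC_MODES]
    for block in blocks:
        assert all(np.isfinite(v) for v in block.values())
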