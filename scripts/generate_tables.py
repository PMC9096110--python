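"""One-off generator for the TSV package data shipped under src/ahtpscreen/data/.

Run from the repo root:  python scripts/generate_tables.py
"""
import numpy as np

AA = list("ACDEFGHIKLMNPQRSTVWY")
OUT = "src/ahtpscreen/data"

# ---- Chou PseAAC standard property triple -------------------------------
# hydrophobicity: Eisenberg consensus; hydrophilicity: Hopp-Woods;
# side-chain mass: residue side-chain masses (Da).
HYDROPHOBICITY = dict(zip(AA, [0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38,
                               -1.50, 1.06, 0.64, -0.78, 0.12, -0.85, -2.53, -0.18,
                               -0.05, 1.08, 0.81, 0.26]))
HYDROPHILICITY = dict(zip(AA, [-0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8,
                               3.0, -1.8, -1.3, 0.2, 0.0, 0.2, 3.0, 0.3,
                               -0.4, -1.5, -3.4, -2.3]))
SIDECHAINMASS = dict(zip(AA, [15.0, 47.0, 59.0, 73.0, 91.0, 1.0, 82.0, 57.0,
                              73.0, 57.0, 75.0, 58.0, 42.0, 72.0, 101.0, 31.0,
                              45.0, 43.0, 130.0, 107.0]))

with open(f"{OUT}/paac_properties.tsv", "w") as fh:
    fh.write("# Chou PseAAC property triple: Eisenberg consensus hydrophobicity,\n")
    fh.write("# Hopp-Woods hydrophilicity, side-chain mass (Da). v1\n")
    fh.write("residue\thydrophobicity\thydrophilicity\tsidechainmass\n")
    for a in AA:
        fh.write(f"{a}\t{HYDROPHOBICITY[a]}\t{HYDROPHILICITY[a]}\t{SIDECHAINMASS[a]}\n")

# ---- Grantham distance matrix (computed from his c, p, v properties) ----
# D_ij = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)
# alpha=1.833, beta=0.1018, gamma=0.000399, rho chosen so mean distance = 100
# (rho ~= 50.723); values rounded to integers as published.
G_C = {"A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75, "Q": 0.89, "E": 0.92,
       "G": 0.74, "H": 0.58, "I": 0.0, "L": 0.0, "K": 0.33, "M": 0.0, "F": 0.0,
       "P": 0.39, "S": 1.42, "T": 0.71, "W": 0.13, "Y": 0.20, "V": 0.0}
G_P = {"A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3,
       "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2,
       "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9}
G_V = {"A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0, "E": 83.0,
       "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0, "M": 105.0,
       "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0, "Y": 136.0, "V": 84.0}

one2 = {k: k for k in AA}
rho = 50.723
D = np.zeros((20, 20))
for i, a in enumerate(AA):
    for j, b in enumerate(AA):
        d2 = (1.833 * (G_C[a] - G_C[b]) ** 2 + 0.1018 * (G_P[a] - G_P[b]) ** 2
              + 0.000399 * (G_V[a] - G_V[b]) ** 2)
        D[i, j] = round(rho * np.sqrt(d2))

# spot checks against well-known published entries
checks = {("R", "L"): 102, ("L", "I"): 5, ("W", "C"): 215, ("D", "E"): 45,
          ("F", "Y"): 22, ("G", "W"): 184}
for (a, b), want in checks.items():
    got = D[AA.index(a), AA.index(b)]
    print(f"Grantham {a}-{b}: computed {got}, published {want}")

with open(f"{OUT}/distance_grantham.tsv", "w") as fh:
    fh.write("# Grantham (1974) amino-acid distance matrix, computed from his\n")
    fh.write("# composition/polarity/volume residue properties and distance formula\n")
    fh.write("# (alpha=1.833, beta=0.1018, gamma=0.000399, scale 50.723). v1\n")
    fh.write("residue\t" + "\t".join(AA) + "\n")
    for i, a in enumerate(AA):
        fh.write(a + "\t" + "\t".join(f"{D[i, j]:.0f}" for j in range(20)) + "\n")

# ---- Physicochemical distance matrix (synthetic stand-in) ---------------
# Euclidean distance over the z-scored Chou property triple, normalised to max 1.
props = np.array([[HYDROPHOBICITY[a], HYDROPHILICITY[a], SIDECHAINMASS[a]] for a in AA])
z = (props - props.mean(0)) / props.std(0)
PD = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(-1))
PD /= PD.max()
with open(f"{OUT}/distance_physchem_synthetic.tsv", "w") as fh:
    fh.write("# SYNTHETIC physicochemical amino-acid distance matrix: Euclidean\n")
    fh.write("# distance over the z-scored Chou property triple (hydrophobicity,\n")
    fh.write("# hydrophilicity, side-chain mass), max-normalised. Constructed\n")
    fh.write("# stand-in for the Schneider-Wrede distance matrix. v1\n")
    fh.write("residue\t" + "\t".join(AA) + "\n")
    for i, a in enumerate(AA):
        fh.write(a + "\t" + "\t".join(f"{PD[i, j]:.4f}" for j in range(20)) + "\n")

# ---- z-scales (Sandberg et al. 1998; published values) ------------------
ZS = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30), "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75), "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62), "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09), "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31), "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98), "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00), "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17), "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40), "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59), "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
}
with open(f"{OUT}/zscales.tsv", "w") as fh:
    fh.write("# Sandberg et al. (1998) z-scales z1-z5 (published values). v1\n")
    fh.write("residue\tz1\tz2\tz3\tz4\tz5\n")
    for a in AA:
        fh.write(a + "\t" + "\t".join(str(v) for v in ZS[a]) + "\n")

# ---- Synthetic scale families -------------------------------------------
# Deterministic rotated PCA scores of a 20x10 physicochemical property
# matrix; each family gets its published dimensionality and a fixed
# family-specific orthogonal rotation so families are distinct.
KD = dict(zip(AA, [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
                   1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3]))
CF_A = dict(zip(AA, [1.42, 0.70, 1.01, 1.51, 1.13, 0.57, 1.00, 1.08, 1.16, 1.21,
                     1.45, 0.67, 0.57, 1.11, 0.98, 0.77, 0.83, 1.06, 1.08, 0.69]))
CF_B = dict(zip(AA, [0.83, 1.19, 0.54, 0.37, 1.38, 0.75, 0.87, 1.60, 0.74, 1.30,
                     1.05, 0.89, 0.55, 1.10, 0.93, 0.75, 1.19, 1.70, 1.37, 1.47]))
CF_T = dict(zip(AA, [0.66, 1.19, 1.46, 0.74, 0.60, 1.56, 0.95, 0.47, 1.01, 0.59,
                     0.60, 1.56, 1.52, 0.98, 0.95, 1.43, 0.96, 0.50, 0.96, 1.14]))

M = np.array([[HYDROPHOBICITY[a], HYDROPHILICITY[a], SIDECHAINMASS[a], G_C[a],
               G_P[a], G_V[a], KD[a], CF_A[a], CF_B[a], CF_T[a]] for a in AA])
Mz = (M - M.mean(0)) / M.std(0)
U, s, Vt = np.linalg.svd(Mz, full_matrices=False)
scores = U * s  # 20 x 10 principal-component scores
# sign convention: largest-|loading| entry of each component positive
for j in range(scores.shape[1]):
    if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
        scores[:, j] *= -1

FAMILIES = {"Crucian": 3, "fasgai": 6, "tscales": 5, "vhsescales": 8,
            "protFP": 8, "stscales": 8, "mswhimscore": 3}
rng = np.random.default_rng(20220428)
with open(f"{OUT}/scales_synthetic.tsv", "w") as fh:
    fh.write("# SYNTHETIC scale-family tables: deterministic rotated PCA scores of a\n")
    fh.write("# 20x10 physicochemical property matrix (Eisenberg hydrophobicity,\n")
    fh.write("# Hopp-Woods hydrophilicity, side-chain mass, Grantham c/p/v,\n")
    fh.write("# Kyte-Doolittle hydropathy, Chou-Fasman Pa/Pb/Pturn). Constructed\n")
    fh.write("# stand-ins matching the published dimensionalities of the Cruciani,\n")
    fh.write("# FASGAI, T-scale, VHSE, ProtFP, ST-scale and MS-WHIM families. v1\n")
    cols = []
    names = []
    for fam, k in FAMILIES.items():
        # fixed random orthogonal rotation (QR of a seeded Gaussian)
        Q, R = np.linalg.qr(rng.standard_normal((10, 10)))
        Q *= np.sign(np.diag(R))
        fam_scores = scores @ Q
        for j in range(k):
            names.append(f"{fam}{j + 1}")
            cols.append(np.round(fam_scores[:, j], 3))
    fh.write("residue\t" + "\t".join(names) + "\n")
    for i, a in enumerate(AA):
        fh.write(a + "\t" + "\t".join(str(c[i]) for c in cols) + "\n")

print("wrote data tables")
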