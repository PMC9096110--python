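"""Independent straight-line reference implementations used as test oracles.

These deliberately share no code with the package: each one evaluates the
published formula directly (loops, explicit arithmetic), reading only the
packaged property tables.
"""
import math

import numpy as np

from ahtpscreen.tables import AA, AA3, ctd_groups, distance_matrix, \
    paac_properties

CTD_PROPS = ("hydrophobicity", "normwaalsvolume", "polarity", "polarizability",
             "charge", "secondarystruct", "solventaccess")


def _znorm(col):
    vals = np.array([col[a] for a in AA])
    z = (vals - vals.mean()) / vals.std()
    return dict(zip(AA, z))


def paac_oracle(seq, lam=3, w=0.05):
    """Type-I pseudo-composition with the packaged Chou property triple."""
    props = paac_properties()
    tabs = [_znorm(props[c].to_dict())
            for c in ("hydrophobicity", "hydrophilicity", "sidechainmass")]
    L = len(seq)
    thetas = []
    for d in range(1, lam + 1):
        acc = 0.0
        for i in range(L - d):
            a, b = seq[i], seq[i + d]
            acc += sum((t[a] - t[b]) ** 2 for t in tabs) / 3.0
        thetas.append(acc / (L - d))
    f = [seq.count(a) / L for a in AA]
    denom = sum(f) + w * sum(thetas)
    return [x / denom for x in f] + [w * t / denom for t in thetas]


def qso_oracle(seq, maxlag=3, w=0.1):
    """QSO/SOCN from direct evaluation with the packaged distance matrices."""
    L = len(seq)
    qso, socn = [], []
    for mat in ("physchem", "grantham"):
        dm = distance_matrix(mat)
        taus = [sum(dm.at[seq[i], seq[i + d]] ** 2 for i in range(L - d))
                for d in range(1, maxlag + 1)]
        socn.extend(taus)
        f = [seq.count(a) / L for a in AA3]
        denom = sum(f) + w * sum(taus)
        qso.extend(x / denom for x in f)
        qso.extend(w * t / denom for t in taus)
    return qso, socn


def ctd_oracle(seq):
    """Full 147-value C/T/D vector by exhaustive enumeration."""
    groups = ctd_groups()
    L = len(seq)
    comp, trans, dist = [], [], []
    for prop in CTD_PROPS:
        gsets = groups[prop]
        gi = []
        for r in seq:
            for gnum, g in enumerate(gsets):
                if r in g:
                    gi.append(gnum)
                    break
        for g in range(3):
            comp.append(gi.count(g) / L)
        for (a, b) in ((0, 1), (0, 2), (1, 2)):
            cnt = 0
            for x, y in zip(gi, gi[1:]):
                if (x, y) == (a, b) or (x, y) == (b, a):
                    cnt += 1
            trans.append(cnt / (L - 1))
        for g in range(3):
            positions = [i + 1 for i, x in enumerate(gi) if x == g]
            n = len(positions)
            if n == 0:
                dist.extend([0.0] * 5)
                continue
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                idx = 1 if q == 0.0 else max(1, math.floor(q * n + 0.5))
                dist.append(100.0 * positions[idx - 1] / L)
    return comp + trans + dist


def brute_force_relieff(X, y, k=10):
    """O(n^2) reference ReliefF with explicit loops."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(0), X.max(0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    Xs = (X - lo) / span
    n, p = Xs.shape
    classes = np.unique(y)
    priors = {c: np.mean(y == c) for c in classes}
    D = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(-1)
    w = np.zeros(p)
    for i in range(n):
        for c in classes:
            idx = [j for j in range(n) if y[j] == c and j != i]
            idx.sort(key=lambda j: D[i, j])
            nearest = idx[:k]
            diffs = np.mean([np.abs(Xs[j] - Xs[i]) for j in nearest], axis=0)
            if c == y[i]:
                w -= diffs / n
            else:
                w += priors[c] / (1 - priors[y[i]]) * diffs / n
    return w


def mann_whitney_auc(scores, labels):
    """AUC as the tie-averaged rank statistic, by brute force."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
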