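"""Independent brute-force oracles, written loop-style straight from the
descriptor and network definitions.  Deliberately unoptimized and kept free
of any imports from the package's implementation modules (numpy only), so
they constitute a second, independent route to the same quantities."""

from __future__ import annotations

import itertools
import math

import numpy as np

ALPHA = "ACGU"
COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
NCP = {"A": [1, 1, 1], "C": [0, 1, 0], "G": [1, 0, 0], "U": [0, 0, 1]}


def revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# descriptor oracles


def bpf(seq):
    out = []
    for c in seq:
        out.extend(1.0 if c == a else 0.0 for a in ALPHA)
    return out


def ncp(seq):
    out = []
    for c in seq:
        out.extend(float(x) for x in NCP[c])
    return out


def dbe(seq):
    dinucs = ["".join(p) for p in itertools.product(ALPHA, repeat=2)]
    out = []
    for i in range(len(seq) - 1):
        d = seq[i: i + 2]
        out.extend(1.0 if d == ref else 0.0 for ref in dinucs)
    return out


def kmer(seq, k):
    kmers = ["".join(p) for p in itertools.product(ALPHA, repeat=k)]
    windows = [seq[i: i + k] for i in range(len(seq) - k + 1)]
    return [windows.count(km) / len(windows) for km in kmers]


def rckmer(seq, k):
    kmers = ["".join(p) for p in itertools.product(ALPHA, repeat=k)]
    canon = sorted({min(km, revcomp(km)) for km in kmers})
    windows = [min(seq[i: i + k], revcomp(seq[i: i + k]))
               for i in range(len(seq) - k + 1)]
    return [windows.count(c) / len(windows) for c in canon]


def pseeiip(seq, eiip):
    tris = ["".join(p) for p in itertools.product(ALPHA, repeat=3)]
    freqs = kmer(seq, 3)
    return [f * sum(eiip[c] for c in t) for f, t in zip(freqs, tris)]


def cksnap(seq, kmax):
    pairs = ["".join(p) for p in itertools.product(ALPHA, repeat=2)]
    out = []
    for g in range(kmax + 1):
        found = [seq[i] + seq[i + g + 1] for i in range(len(seq) - g - 1)]
        out.extend(found.count(p) / len(found) for p in pairs)
    return out


def enac(seq, window):
    out = []
    for i in range(len(seq) - window + 1):
        win = seq[i: i + window]
        out.extend(win.count(a) / window for a in ALPHA)
    return out


def dpcp(seq, table, variant):
    """table: dict dinucleotide -> list of property values (standardized
    upstream)."""
    dinucs = ["".join(p) for p in itertools.product(ALPHA, repeat=2)]
    found = [seq[i: i + 2] for i in range(len(seq) - 1)]
    n_prop = len(next(iter(table.values())))
    if variant == 1:
        out = []
        for j in range(n_prop):
            for d in dinucs:
                out.append(found.count(d) / len(found) * table[d][j])
        return out
    return [sum(table[d][j] for d in found) / len(found) for j in range(n_prop)]


def zcurve(seq):
    out = []
    for phase in range(3):
        starts = [i for i in range(phase, len(seq) - 2, 3)]
        tris = [seq[i: i + 3] for i in starts]
        for mn in ("".join(p) for p in itertools.product(ALPHA, repeat=2)):
            if tris:
                f = {b: tris.count(mn + b) / len(tris) for b in ALPHA}
            else:
                f = {b: 0.0 for b in ALPHA}
            out.append((f["A"] + f["G"]) - (f["C"] + f["U"]))
            out.append((f["A"] + f["C"]) - (f["G"] + f["U"]))
            out.append((f["A"] + f["U"]) - (f["G"] + f["C"]))
    return out


def aslpn(seq, max_skip=None):
    L = len(seq)
    G = max_skip if max_skip is not None else L - 1
    G = min(G, L - 1)
    pairs = ["".join(p) for p in itertools.product(ALPHA, repeat=2)]
    counts = {p: 0 for p in pairs}
    denom = 0
    for g in range(1, G + 1):
        for i in range(L - g):
            counts[seq[i] + seq[i + g]] += 1
        denom += L - g
    part_a = [counts[p] / denom for p in pairs]
    dinucs = [seq[i: i + 2] for i in range(L - 1)]
    part_b = [dinucs[: i + 1].count(dinucs[i]) / (i + 1)
              for i in range(len(dinucs))]
    return part_a + part_b


def mmnf(seq):
    L = len(seq)
    f1 = {a: seq.count(a) / L for a in ALPHA}
    di = [seq[i: i + 2] for i in range(L - 1)]
    tri = [seq[i: i + 3] for i in range(L - 2)]

    def f2(a, b):
        return sum(1 for d in di if sorted(d) == sorted(a + b)) / len(di)

    def f3(a, b, c):
        return sum(1 for t in tri if sorted(t) == sorted(a + b + c)) / len(tri)

    def xlog(x, num, den):
        if x == 0 or num == 0 or den == 0:
            return 0.0
        return x * math.log(num / den)

    def mi2(a, b):
        fab = f2(a, b)
        return xlog(fab, fab, f1[a] * f1[b])

    out = []
    for a, b in itertools.combinations_with_replacement(ALPHA, 2):
        out.append(mi2(a, b))
    for a, b, c in itertools.combinations_with_replacement(ALPHA, 3):
        fabc = f3(a, b, c)
        cond = xlog(fabc, fabc * f1[c], f2(a, c) * f2(b, c))
        out.append(mi2(a, b) - cond)
    for i in range(L):
        out.append(seq[: i + 1].count(seq[i]) / (i + 1))
    return out


# ---------------------------------------------------------------------------
# network oracles


def conv1d_loop(x, w, b, stride=1, pad=0, dilation=1):
    """Triple-loop cross-correlation; x (C_in, L), w (C_out, C_in, k)."""
    C_in, L = x.shape
    C_out, _, k = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad)))
    span = dilation * (k - 1) + 1
    L_out = (x.shape[1] - span) // stride + 1
    out = np.zeros((C_out, L_out))
    for o in range(C_out):
        for t in range(L_out):
            acc = b[o]
            for c in range(C_in):
                for j in range(k):
                    acc += w[o, c, j] * x[c, t * stride + j * dilation]
            out[o, t] = acc
    return out


def maxpool_loop(x, kernel, stride):
    C, L = x.shape
    L_out = (L - kernel) // stride + 1
    out = np.zeros((C, L_out))
    for c in range(C):
        for t in range(L_out):
            out[c, t] = max(x[c, t * stride + p] for p in range(kernel))
    return out


def gru_step_loop(x_t, h_prev, p):
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    u = sig(x_t @ p["W_iu"] + h_prev @ p["U_hu"] + p["b_iu"] + p["b_hu"])
    r = sig(x_t @ p["W_ir"] + h_prev @ p["U_hr"] + p["b_ir"] + p["b_hr"])
    n = np.tanh(x_t @ p["W_in"] + p["b_in"] + r * (h_prev @ p["U_hn"] + p["b_hn"]))
    return (1.0 - u) * n + u * h_prev


def bigru_loop(E, params):
    T = E.shape[0]
    H = params["forward"]["U_hu"].shape[0]
    hf = np.zeros(H)
    fwd = []
    for t in range(T):
        hf = gru_step_loop(E[t], hf, params["forward"])
        fwd.append(hf)
    hb = np.zeros(H)
    bwd = [None] * T
    for t in range(T - 1, -1, -1):
        hb = gru_step_loop(E[t], hb, params["backward"])
        bwd[t] = hb
    return np.array([np.concatenate([f, b]) for f, b in zip(fwd, bwd)])


def attention_loop(H, p):
    T = H.shape[0]
    scores = np.array([
        float(p["x_a"][:, 0] @ np.tanh(p["W_a"].T @ H[t] + p["b_a"]))
        for t in range(T)
    ])
    e = np.exp(scores - scores.max())
    alpha = e / e.sum()
    c = sum(alpha[t] * H[t] for t in range(T))
    return c, alpha


def auc_pairwise(labels, scores):
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
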