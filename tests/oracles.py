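"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops / enumeration straight from the
definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

# ---------------------------------------------------------------------------
# recurrence features


def brute_rqa(R: np.ndarray, theiler: int, lmin: int = 2, vmin: int = 2) -> dict:
    """All 13 recurrence measures by direct enumeration on a binary matrix.

    Conventions: Theiler-band cells are non-recurrent everywhere; vertical
    structures live on the two admissible column segments; white gaps are
    interior zero-runs; T2 = mean(gap) + 1; empty histograms give 0.
    """
    n = R.shape[0]
    R = R.astype(bool)
    adm = [(i, j) for i in range(n) for j in range(n) if abs(i - j) > theiler]
    n_adm = len(adm)
    n_rec = sum(1 for i, j in adm if R[i, j])
    rr = n_rec / n_adm if n_adm else 0.0

    # diagonal lines (both triangles)
    diag_lengths = []
    for k in list(range(-(n - 1), -theiler)) + list(range(theiler + 1, n)):
        run = 0
        line = []
        for i in range(n):
            j = i + k
            if 0 <= j < n:
                line.append(R[i, j])
        for v in line + [False]:
            if v:
                run += 1
            elif run:
                diag_lengths.append(run)
                run = 0

    # vertical lines and white gaps per admissible column segment
    vert_lengths, white_lengths = [], []
    for j in range(n):
        segments = []
        if j - theiler > 0:
            segments.append([R[i, j] for i in range(0, j - theiler)])
        if j + theiler + 1 < n:
            segments.append([R[i, j] for i in range(j + theiler + 1, n)])
        for seg in segments:
            run = 0
            for v in seg + [False]:
                if v:
                    run += 1
                elif run:
                    vert_lengths.append(run)
                    run = 0
            ones = [i for i, v in enumerate(seg) if v]
            for a, b in zip(ones, ones[1:]):
                if b - a > 1:
                    white_lengths.append(b - a - 1)

    def entropy(lengths):
        if not lengths:
            return 0.0
        counts = {}
        for l in lengths:
            counts[l] = counts.get(l, 0) + 1
        tot = sum(counts.values())
        return -sum(c / tot * math.log(c / tot) for c in counts.values())

    long_d = [l for l in diag_lengths if l >= lmin]
    det = sum(long_d) / sum(diag_lengths) if sum(diag_lengths) else 0.0
    L = sum(long_d) / len(long_d) if long_d else 0.0
    lmax = max(diag_lengths) if diag_lengths else 0
    entr = entropy(long_d)

    long_v = [l for l in vert_lengths if l >= vmin]
    lam = sum(long_v) / sum(vert_lengths) if sum(vert_lengths) else 0.0
    tt = sum(long_v) / len(long_v) if long_v else 0.0
    vmax = max(vert_lengths) if vert_lengths else 0

    rtmax = max(white_lengths) if white_lengths else 0
    t2 = sum(white_lengths) / len(white_lengths) + 1.0 if white_lengths else 0.0
    rte = entropy(white_lengths)

    G = nx.from_numpy_array(np.triu(R, theiler + 1) | np.triu(R, theiler + 1).T)
    clust = float(np.mean([nx.clustering(G, i) for i in range(n)]))
    trans = float(nx.transitivity(G))
    return {
        "RR": rr, "DET": det, "L": L, "Lmax": lmax, "ENTR": entr,
        "LAM": lam, "TT": tt, "Vmax": vmax, "RTmax": rtmax, "T2": t2,
        "RTE": rte, "Clust": clust, "Trans": trans,
    }


# ---------------------------------------------------------------------------
# graph metrics


def brute_graph_metrics(A: np.ndarray) -> dict:
    """Efficiencies, characteristic path length, clustering via networkx +
    explicit pair enumeration."""
    n = A.shape[0]
    G = nx.from_numpy_array(A)
    lengths = dict(nx.all_pairs_shortest_path_length(G))
    inv_sum, n_pairs, fin_sum, fin_pairs = 0.0, 0, 0.0, 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            n_pairs += 1
            if j in lengths[i]:
                d = lengths[i][j]
                inv_sum += 1.0 / d
                fin_sum += d
                fin_pairs += 1
    e_glob = inv_sum / n_pairs if n_pairs else 0.0
    l_char = fin_sum / fin_pairs if fin_pairs else math.inf
    clustering = nx.clustering(G)
    c_mean = sum(clustering.values()) / n
    e_loc_terms = []
    for i in range(n):
        nbrs = list(G.neighbors(i))
        if len(nbrs) < 2:
            e_loc_terms.append(0.0)
            continue
        sub = G.subgraph(nbrs)
        sub_len = dict(nx.all_pairs_shortest_path_length(sub))
        s, p = 0.0, 0
        for a in nbrs:
            for b in nbrs:
                if a == b:
                    continue
                p += 1
                if b in sub_len[a]:
                    s += 1.0 / sub_len[a][b]
        e_loc_terms.append(s / p if p else 0.0)
    return {
        "c_mean": c_mean,
        "l_char": l_char,
        "e_global": e_glob,
        "e_local": sum(e_loc_terms) / n,
        "degree": dict(G.degree()),
        "clustering": clustering,
    }


# ---------------------------------------------------------------------------
# DeLong components


def brute_delong(scores_a, scores_b, y):
    """Paired DeLong z/p with explicit placement-value loops and covariance
    sums (no numpy covariance helpers)."""
    pos = [i for i, v in enumerate(y) if v == 1]
    neg = [i for i, v in enumerate(y) if v == 0]
    m, n = len(pos), len(neg)

    def psi(x, yv):
        return 1.0 if x > yv else (0.5 if x == yv else 0.0)

    def components(s):
        v10 = [sum(psi(s[i], s[j]) for j in neg) / n for i in pos]
        v01 = [sum(psi(s[i], s[j]) for i in pos) / m for j in neg]
        auc = sum(v10) / m
        return v10, v01, auc

    va10, va01, auc_a = components(scores_a)
    vb10, vb01, auc_b = components(scores_b)

    def cov(u, v):
        mu, mv = sum(u) / len(u), sum(v) / len(v)
        return sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (len(u) - 1)

    var = (cov(va10, va10) + cov(vb10, vb10) - 2 * cov(va10, vb10)) / m \
        + (cov(va01, va01) + cov(vb01, vb01) - 2 * cov(va01, vb01)) / n
    delta = auc_a - auc_b
    if var <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = delta / math.sqrt(var)
    from scipy.stats import norm

    return auc_a, auc_b, z, 2 * norm.sf(abs(z))


# ---------------------------------------------------------------------------
# false nearest neighbors


def brute_fnn(x, tau, m, rtol, atol, theiler):
    """Kennel false-neighbor fraction for dimension m by exhaustive search."""
    x = np.asarray(x, float)
    n_next = x.size - m * tau
    pts = [[x[t + k * tau] for k in range(m)] for t in range(n_next)]
    ra = x.std()
    false = total = 0
    for i in range(n_next):
        best, bj = None, -1
        for j in range(n_next):
            if abs(i - j) <= theiler:
                continue
            d = math.dist(pts[i], pts[j])
            if best is None or d < best:
                best, bj = d, j
        if bj < 0 or best == 0:
            continue
        total += 1
        gap = abs(x[i + m * tau] - x[bj + m * tau])
        if gap / best > rtol or math.hypot(best, gap) / ra > atol:
            false += 1
    return false / total if total else 0.0
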