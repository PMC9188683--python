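"""Brute-force reference implementations of the texture features.

Everything here is written directly from the matrix definitions with
explicit Python loops and no shared code with the package, so it can
serve as an independent oracle on small windows.
"""

from __future__ import annotations

import math

import numpy as np

EPS_NGTDM = 1e-6


def oracle_quantize(window, n_levels):
    x = np.asarray(window, float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones_like(x, dtype=int)
    q = np.empty(x.shape, dtype=int)
    for idx in np.ndindex(x.shape):
        v = int(math.floor(n_levels * (x[idx] - lo) / (hi - lo))) + 1
        q[idx] = min(v, n_levels)
    return q


def oracle_global(window):
    x = np.asarray(window, float).ravel()
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    if m2 == 0:
        return {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    return {"Variance": m2, "Skewness": m3 / m2**1.5, "Kurtosis": m4 / m2**2}


_DIRS = [(0, 1), (1, 1), (1, 0), (1, -1)]          # 0, 45(down-right), 90, 135


def oracle_glcm_matrix(q, n_levels):
    h, w = q.shape
    mat = np.zeros((n_levels, n_levels))
    for dy, dx in _DIRS:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dy, c + dx
                if 0 <= r2 < h and 0 <= c2 < w:
                    mat[q[r, c] - 1, q[r2, c2] - 1] += 1
                    mat[q[r2, c2] - 1, q[r, c] - 1] += 1   # symmetric
    return mat / mat.sum()


def oracle_glcm(q, n_levels):
    p = oracle_glcm_matrix(q, n_levels)
    out = {"Energy": 0.0, "Contrast": 0.0, "Homogeneity": 0.0,
           "SumAverage": 0.0, "Entropy": 0.0, "Dissimilarity": 0.0,
           "AutoCorrelation": 0.0}
    mu = sum((i + 1) * p[i, j] for i in range(n_levels) for j in range(n_levels))
    var = sum((i + 1 - mu) ** 2 * p[i, j]
              for i in range(n_levels) for j in range(n_levels))
    for i in range(n_levels):
        for j in range(n_levels):
            v = p[i, j]
            li, lj = i + 1, j + 1
            out["Energy"] += v * v
            out["Contrast"] += (li - lj) ** 2 * v
            out["Homogeneity"] += v / (1 + abs(li - lj))
            out["SumAverage"] += (li + lj) * v
            out["Dissimilarity"] += abs(li - lj) * v
            out["AutoCorrelation"] += li * lj * v
            if v > 0:
                out["Entropy"] -= v * math.log2(v)
    out["Variance"] = var
    out["Correlation"] = (out["AutoCorrelation"] - mu**2) / var if var > 0 else 0.0
    return out


def _all_lines(q):
    h, w = q.shape
    lines = [list(q[r, :]) for r in range(h)]
    lines += [list(q[:, c]) for c in range(w)]
    for k in range(-(h - 1), w):                       # 45 deg
        lines.append([q[r, r + k] for r in range(h) if 0 <= r + k < w])
    fl = q[:, ::-1]
    for k in range(-(h - 1), w):                       # 135 deg
        lines.append([fl[r, r + k] for r in range(h) if 0 <= r + k < w])
    return lines


def oracle_glrlm_matrix(q, n_levels):
    h, w = q.shape
    mat = np.zeros((n_levels, max(h, w)))
    for line in _all_lines(q):
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            mat[line[i] - 1, (j - i) - 1] += 1
            i = j
    return mat


def _szm_style(mat, n_sites):
    n = mat.sum()
    out = {}
    pg = mat.sum(axis=1) / n
    ps = mat.sum(axis=0) / n
    mu_i = sum((i + 1) * pg[i] for i in range(mat.shape[0]))
    mu_s = sum((s + 1) * ps[s] for s in range(mat.shape[1]))
    acc = dict(se=0.0, le=0.0, lg=0.0, hg=0.0, slg=0.0, shg=0.0,
               llg=0.0, lhg=0.0, gv=0.0, sv=0.0)
    for i in range(mat.shape[0]):
        for s in range(mat.shape[1]):
            v = mat[i, s] / n
            li, ls = i + 1, s + 1
            acc["se"] += v / ls**2
            acc["le"] += v * ls**2
            acc["lg"] += v / li**2
            acc["hg"] += v * li**2
            acc["slg"] += v / (li**2 * ls**2)
            acc["shg"] += v * li**2 / ls**2
            acc["llg"] += v * ls**2 / li**2
            acc["lhg"] += v * li**2 * ls**2
            acc["gv"] += v * (li - mu_i) ** 2
            acc["sv"] += v * (ls - mu_s) ** 2
    gn = sum(mat.sum(axis=1) ** 2) / n
    sn = sum(mat.sum(axis=0) ** 2) / n
    return [acc["se"], acc["le"], gn, sn, n / n_sites, acc["lg"], acc["hg"],
            acc["slg"], acc["shg"], acc["llg"], acc["lhg"], acc["gv"], acc["sv"]]


def oracle_glrlm(q, n_levels):
    names = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
             "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV")
    vals = _szm_style(oracle_glrlm_matrix(q, n_levels), 4 * q.size)
    return dict(zip(names, vals))


def oracle_glszm_matrix(q, n_levels):
    h, w = q.shape
    seen = np.zeros((h, w), bool)
    sizes = []
    levels = []
    for r in range(h):
        for c in range(w):
            if seen[r, c]:
                continue
            # BFS flood fill over 8-connected equal-valued pixels
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        y2, x2 = y + dy, x + dx
                        if (0 <= y2 < h and 0 <= x2 < w and not seen[y2, x2]
                                and q[y2, x2] == q[r, c]):
                            seen[y2, x2] = True
                            stack.append((y2, x2))
            sizes.append(size)
            levels.append(q[r, c])
    mat = np.zeros((n_levels, max(sizes)))
    for lv, sz in zip(levels, sizes):
        mat[lv - 1, sz - 1] += 1
    return mat


def oracle_glszm(q, n_levels):
    names = ("SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
             "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV")
    vals = _szm_style(oracle_glszm_matrix(q, n_levels), q.size)
    return dict(zip(names, vals))


def oracle_ngtdm(q, n_levels):
    h, w = q.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    n_tot = 0
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            nb = [q[r + dy, c + dx] for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                  if not (dy == 0 and dx == 0)]
            a = sum(nb) / 8.0
            n_i[q[r, c] - 1] += 1
            s_i[q[r, c] - 1] += abs(q[r, c] - a)
            n_tot += 1
    p_i = n_i / n_tot
    present = [i for i in range(n_levels) if p_i[i] > 0]
    ng = len(present)
    coarse = 1.0 / (EPS_NGTDM + sum(p_i[i] * s_i[i] for i in present))
    if ng > 1:
        contrast = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (ng * (ng - 1))) * (sum(s_i) / n_tot)
        busy_den = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                       for i in present for j in present)
        busy = (sum(p_i[i] * s_i[i] for i in present) / busy_den
                if busy_den > 0 else 0.0)
        cmplx = sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                    / (n_tot * (p_i[i] + p_i[j]))
                    for i in present for j in present)
        strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                        for i in present for j in present)
                    / (EPS_NGTDM + sum(s_i)))
    else:
        contrast = busy = cmplx = strength = 0.0
    return {"Coarseness": coarse, "Contrast": contrast, "Busyness": busy,
            "Complexity": cmplx, "Strength": strength}


def oracle_texture_vector(window, n_levels):
    """All 43 features by brute force, keyed like the package output."""
    q = oracle_quantize(window, n_levels)
    out = {}
    for k, v in oracle_global(window).items():
        out[f"Global_{k}"] = v
    for k, v in oracle_glcm(q, n_levels).items():
        out[f"GLCM_{k}"] = v
    for k, v in oracle_glrlm(q, n_levels).items():
        out[f"GLRLM_{k}"] = v
    for k, v in oracle_glszm(q, n_levels).items():
        out[f"GLSZM_{k}"] = v
    for k, v in oracle_ngtdm(q, n_levels).items():
        out[f"NGTDM_{k}"] = v
    return out
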