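"""Brute-force enumeration oracles for the texture features.

Everything here is deliberately naive: pairs, runs, zones, dependencies and
neighbourhoods are enumerated pixel by pixel with python loops, and the
feature formulas are written as explicit sums.  The oracles share no code
with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def _in(mask, r, c):
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]


# ---------------------------------------------------------------------------
# matrix construction


def oracle_glcm(levels, mask, ng, direction):
    P = np.zeros((ng, ng))
    dr, dc = direction
    for r in range(levels.shape[0]):
        for c in range(levels.shape[1]):
            if not mask[r, c]:
                continue
            r2, c2 = r + dr, c + dc
            if _in(mask, r2, c2):
                P[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                P[levels[r2, c2] - 1, levels[r, c] - 1] += 1  # symmetric
    s = P.sum()
    return P / s if s else P


def oracle_runs(levels, mask, ng, direction):
    """Run-length matrix by walking every maximal line in the direction."""
    h, w = levels.shape
    dr, dc = direction
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):  # no predecessor: line start
                starts.append((r, c))
    R = np.zeros((ng, max(h, w)))
    for r, c in starts:
        cur, length = 0, 0
        while 0 <= r < h and 0 <= c < w:
            v = levels[r, c] if mask[r, c] else 0
            if v == cur and v != 0:
                length += 1
            else:
                if cur:
                    R[cur - 1, length - 1] += 1
                cur, length = v, (1 if v else 0)
            r, c = r + dr, c + dc
        if cur:
            R[cur - 1, length - 1] += 1
    return R


def oracle_zones(levels, mask, ng):
    """Size-zone matrix via BFS flood fill with 8-connectivity."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    n_pix = int(mask.sum())
    Z = np.zeros((ng, max(n_pix, 1)))
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            g = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (
                            _in(mask, r2, c2)
                            and not seen[r2, c2]
                            and levels[r2, c2] == g
                        ):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            Z[g - 1, size - 1] += 1
    return Z


def oracle_dependence(levels, mask, ng, alpha=0.0):
    D = np.zeros((ng, 9))
    for r in range(levels.shape[0]):
        for c in range(levels.shape[1]):
            if not mask[r, c]:
                continue
            k = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    if _in(mask, r + dr, c + dc) and abs(
                        int(levels[r, c]) - int(levels[r + dr, c + dc])
                    ) <= alpha:
                        k += 1
            D[levels[r, c] - 1, k] += 1  # column k means dependence k+1
    return D


def oracle_ngtdm(levels, mask, ng):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for r in range(levels.shape[0]):
        for c in range(levels.shape[1]):
            if not mask[r, c]:
                continue
            nb = [
                levels[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if not (dr == dc == 0) and _in(mask, r + dr, c + dc)
            ]
            g = int(levels[r, c])
            n_i[g - 1] += 1
            if nb:
                s_i[g - 1] += abs(g - sum(nb) / len(nb))
    return n_i, s_i


# ---------------------------------------------------------------------------
# feature formulas (explicit sums)


def oracle_glcm_features(P, ng):
    i_idx = range(1, ng + 1)
    px = [sum(P[i - 1, j - 1] for j in i_idx) for i in i_idx]
    mu = sum(i * px[i - 1] for i in i_idx)
    sigma2 = sum((i - mu) ** 2 * px[i - 1] for i in i_idx)
    sigma = math.sqrt(sigma2)

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in i_idx:
        for j in i_idx:
            p_sum[i + j] += P[i - 1, j - 1]
            p_diff[abs(i - j)] += P[i - 1, j - 1]
    da = sum(k * v for k, v in p_diff.items())
    ent = -sum(v * math.log2(v) for row in P for v in row if v > 0)
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hxy1 = -sum(
        P[i - 1, j - 1] * math.log2(px[i - 1] * px[j - 1])
        for i in i_idx
        for j in i_idx
        if P[i - 1, j - 1] > 0 and px[i - 1] * px[j - 1] > 0
    )
    hxy2 = -sum(
        px[i - 1] * px[j - 1] * math.log2(px[i - 1] * px[j - 1])
        for i in i_idx
        for j in i_idx
        if px[i - 1] * px[j - 1] > 0
    )
    active = [i for i in i_idx if px[i - 1] > 0]
    if len(active) < 2:
        mcc = 1.0
    else:
        Q = np.zeros((len(active), len(active)))
        for a, i in enumerate(active):
            for b, j in enumerate(active):
                Q[a, b] = sum(
                    P[i - 1, k - 1] * P[j - 1, k - 1] / (px[i - 1] * px[k - 1])
                    for k in active
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(0.0, min(1.0, ev[-2])))
    corr = (
        (sum(i * j * P[i - 1, j - 1] for i in i_idx for j in i_idx) - mu * mu)
        / (sigma * sigma)
        if sigma2 > 0
        else 1.0
    )
    return {
        "Autocorrelation": sum(i * j * P[i - 1, j - 1] for i in i_idx for j in i_idx),
        "JointAverage": mu,
        "ClusterProminence": sum(
            (i + j - 2 * mu) ** 4 * P[i - 1, j - 1] for i in i_idx for j in i_idx
        ),
        "ClusterShade": sum(
            (i + j - 2 * mu) ** 3 * P[i - 1, j - 1] for i in i_idx for j in i_idx
        ),
        "ClusterTendency": sum(
            (i + j - 2 * mu) ** 2 * P[i - 1, j - 1] for i in i_idx for j in i_idx
        ),
        "Contrast": sum((i - j) ** 2 * P[i - 1, j - 1] for i in i_idx for j in i_idx),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v) for v in p_diff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": sum(
            P[i - 1, j - 1] / (1 + abs(i - j)) for i in i_idx for j in i_idx
        ),
        "Idm": sum(
            P[i - 1, j - 1] / (1 + (i - j) ** 2) for i in i_idx for j in i_idx
        ),
        "Idmn": sum(
            P[i - 1, j - 1] / (1 + (i - j) ** 2 / ng**2) for i in i_idx for j in i_idx
        ),
        "Idn": sum(
            P[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in i_idx for j in i_idx
        ),
        "Imc1": (ent - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - ent)))),
        "InverseVariance": sum(
            P[i - 1, j - 1] / (i - j) ** 2 for i in i_idx for j in i_idx if i != j
        ),
        "JointEnergy": sum(v**2 for row in P for v in row),
        "JointEntropy": ent,
        "MaximumProbability": max(v for row in P for v in row),
        "MCC": mcc,
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": -sum(v * math.log2(v) for v in p_sum.values() if v > 0),
        "SumSquares": sigma2,
    }


def oracle_sized_features(P, n_pixels):
    """The 16 shared formulas for run/zone style matrices, by explicit sums."""
    ng, smax = P.shape
    ns = P.sum()
    out = {}
    out["Small"] = sum(P[i, s] / (s + 1) ** 2 for i in range(ng) for s in range(smax)) / ns
    out["Large"] = sum(P[i, s] * (s + 1) ** 2 for i in range(ng) for s in range(smax)) / ns
    out["GLN"] = sum(P[i, :].sum() ** 2 for i in range(ng)) / ns
    out["GLNN"] = out["GLN"] / ns
    out["SN"] = sum(P[:, s].sum() ** 2 for s in range(smax)) / ns
    out["SNN"] = out["SN"] / ns
    out["Pct"] = ns / n_pixels
    mu_i = sum((i + 1) * P[i, s] / ns for i in range(ng) for s in range(smax))
    mu_s = sum((s + 1) * P[i, s] / ns for i in range(ng) for s in range(smax))
    out["GLV"] = sum(
        (i + 1 - mu_i) ** 2 * P[i, s] / ns for i in range(ng) for s in range(smax)
    )
    out["SV"] = sum(
        (s + 1 - mu_s) ** 2 * P[i, s] / ns for i in range(ng) for s in range(smax)
    )
    out["Entropy"] = -sum(
        (P[i, s] / ns) * math.log2(P[i, s] / ns)
        for i in range(ng)
        for s in range(smax)
        if P[i, s] > 0
    )
    out["LGL"] = sum(P[i, s] / (i + 1) ** 2 for i in range(ng) for s in range(smax)) / ns
    out["HGL"] = sum(P[i, s] * (i + 1) ** 2 for i in range(ng) for s in range(smax)) / ns
    out["SmallLGL"] = (
        sum(P[i, s] / ((i + 1) ** 2 * (s + 1) ** 2) for i in range(ng) for s in range(smax)) / ns
    )
    out["SmallHGL"] = (
        sum(P[i, s] * (i + 1) ** 2 / (s + 1) ** 2 for i in range(ng) for s in range(smax)) / ns
    )
    out["LargeLGL"] = (
        sum(P[i, s] * (s + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for s in range(smax)) / ns
    )
    out["LargeHGL"] = (
        sum(P[i, s] * (i + 1) ** 2 * (s + 1) ** 2 for i in range(ng) for s in range(smax)) / ns
    )
    return out


def oracle_ngtdm_features(n_i, s_i, ng, cap=1e6):
    nvp = n_i.sum()
    p = n_i / nvp
    pres = [i for i in range(ng) if p[i] > 0]
    ngp = len(pres)
    denom = sum(p[i] * s_i[i] for i in range(ng))
    coarse = min(cap, 1.0 / denom) if denom > 0 else cap
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in pres for j in pres)
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in pres for j in pres
        )
        busy = denom / busy_den if busy_den > 0 else 0.0
        cplx = (
            sum(
                abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
                for i in pres
                for j in pres
            )
            / nvp
        )
        stot = s_i.sum()
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in pres for j in pres) / stot
            if stot > 0
            else 0.0
        )
    else:
        contrast = busy = cplx = strength = 0.0
    return {
        "Coarseness": coarse,
        "Contrast": contrast,
        "Busyness": busy,
        "Complexity": cplx,
        "Strength": strength,
    }
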