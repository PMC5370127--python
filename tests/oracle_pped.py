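"""Dependency-free brute-force PPED reference, used only as a test oracle.

Every stage is written as literal nested Python loops over the defining
sums, sharing nothing with the vectorized implementation except the
kernel values and the tie-break order.
"""

import math

N = 64
R = 2  # kernel radius


def bf_kernels():
    h = [[0] * 5 for _ in range(5)]
    for p in range(5):
        for q in range(5):
            if p < 2:
                h[p][q] = 1
            elif p > 2:
                h[p][q] = -1
    d45 = [[0] * 5 for _ in range(5)]
    for p in range(5):
        for q in range(5):
            s = (p - 2) + (q - 2)
            d45[p][q] = 1 if s < 0 else (-1 if s > 0 else 0)
    v = [[h[q][p] for q in range(5)] for p in range(5)]
    dm45 = [[d45[p][4 - q] for q in range(5)] for p in range(5)]
    return [h, d45, v, dm45]


def bf_responses(patch):
    ks = bf_kernels()
    out = [[[0.0] * N for _ in range(N)] for _ in range(4)]
    for d in range(4):
        for x in range(R, N - R):
            for y in range(R, N - R):
                acc = 0.0
                for p in range(-R, R + 1):
                    for q in range(-R, R + 1):
                        acc += ks[d][p + R][q + R] * float(patch[x + p][y + q])
                out[d][x][y] = abs(acc)
    return out


def bf_threshold(patch, resp, policy, floor=1.0, fraction=0.3):
    if policy == "global-fraction":
        mx = max(resp[d][x][y] for d in range(4) for x in range(N) for y in range(N))
        return [[fraction * mx] * N for _ in range(N)]
    if policy == "local-median":
        th = [[float("inf")] * N for _ in range(N)]
        for x in range(R, N - R):
            for y in range(R, N - R):
                diffs = []
                for p in range(-R, R + 1):
                    for q in range(-R, R):
                        diffs.append(abs(float(patch[x + p][y + q]) - float(patch[x + p][y + q + 1])))
                for p in range(-R, R):
                    for q in range(-R, R + 1):
                        diffs.append(abs(float(patch[x + p][y + q]) - float(patch[x + p + 1][y + q])))
                diffs.sort()
                m = len(diffs)
                med = diffs[m // 2] if m % 2 else 0.5 * (diffs[m // 2 - 1] + diffs[m // 2])
                th[x][y] = max(med, floor)
        return th
    raise ValueError(policy)


def bf_flags(resp, th):
    flags = [[[0] * N for _ in range(N)] for _ in range(4)]
    for x in range(N):
        for y in range(N):
            best, bestd = -1.0, 0
            for d in range(4):
                if resp[d][x][y] > best:
                    best, bestd = resp[d][x][y], d
            if best >= th[x][y] and best > 0:
                flags[bestd][x][y] = 1
    return flags


def bf_projections(flags):
    ph = [0.0] * N
    pv = [0.0] * N
    p45 = [0.0] * (2 * N - 1)
    pm45 = [0.0] * (2 * N - 1)
    for i in range(N):
        for j in range(N):
            ph[j] += flags[0][i][j]
            pv[i] += flags[2][i][j]
            p45[i + j] += flags[1][i][j]
            pm45[i - j + N - 1] += flags[3][i][j]
    return ph, p45, pv, pm45


def bf_reduce_diag(p):
    def get(k):
        return p[k] if 0 <= k < 127 else 0.0
    return [get(2 * m - 1) / 2.0 + get(2 * m) + get(2 * m + 1) / 2.0 for m in range(64)]


def bf_reduce16(p):
    return [sum(p[4 * j + r] for r in range(4)) for j in range(16)]


def bf_pped(patch, policy="global-fraction", floor=1.0, fraction=0.3):
    resp = bf_responses(patch)
    th = bf_threshold(patch, resp, policy, floor, fraction)
    flags = bf_flags(resp, th)
    ph, p45, pv, pm45 = bf_projections(flags)
    return (bf_reduce16(ph) + bf_reduce16(bf_reduce_diag(p45))
            + bf_reduce16(pv) + bf_reduce16(bf_reduce_diag(pm45)))


def bf_flag_count(patch, policy="global-fraction", floor=1.0, fraction=0.3):
    resp = bf_responses(patch)
    th = bf_threshold(patch, resp, policy, floor, fraction)
    flags = bf_flags(resp, th)
    return sum(flags[d][x][y] for d in range(4) for x in range(N) for y in range(N))
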