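"""Independent brute-force oracles used to cross-check the implementation.

Everything here is coded directly from textbook formulas with plain loops,
deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# classical tests, closed form
# ---------------------------------------------------------------------------


def t_pooled_oracle(a, b):
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def f_oracle(a, b):
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    va = sum((v - sum(a) / na) ** 2 for v in a) / (na - 1)
    vb = sum((v - sum(b) / nb) ** 2 for v in b) / (nb - 1)
    f = va / vb
    cdf = sps.f.cdf(f, na - 1, nb - 1)
    return f, (na - 1, nb - 1), 2 * min(cdf, 1 - cdf)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_oracle(groups):
    pooled = [float(v) for g in groups for v in g]
    n_total = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        rsum = sum(ranks[pos : pos + len(g)])
        h += rsum**2 / len(g)
        pos += len(g)
    h = 12 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    correction = 1 - sum(c**3 - c for c in counts.values()) / (n_total**3 - n_total)
    h /= correction
    df = len(groups) - 1
    return h, df, sps.chi2.sf(h, df)


def pearson_oracle(x, y):
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, n - 2, 2 * sps.t.sf(abs(t), n - 2)


def influence_oracle(x, y):
    """Leverage, standardized residual, Cook's D, DFITS for y ~ x."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    b1 = sum((a - mx) * (b - my) for a, b in zip(x, y)) / sxx
    b0 = my - b1 * mx
    resid = [yi - (b0 + b1 * xi) for xi, yi in zip(x, y)]
    sse = sum(e * e for e in resid)
    s2 = sse / (n - 2)
    lev, std_res, cooks, dfits = [], [], [], []
    for xi, e in zip(x, resid):
        h = 1 / n + (xi - mx) ** 2 / sxx
        r = e / math.sqrt(s2 * (1 - h))
        d = r * r * h / (2 * (1 - h))
        s_i2 = ((n - 2) * s2 - e * e / (1 - h)) / (n - 3)
        t = e / math.sqrt(s_i2 * (1 - h))
        lev.append(h)
        std_res.append(r)
        cooks.append(d)
        dfits.append(t * math.sqrt(h / (1 - h)))
    return (np.array(lev), np.array(std_res), np.array(cooks), np.array(dfits))


# ---------------------------------------------------------------------------
# event detection, brute force
# ---------------------------------------------------------------------------


def smooth_oracle(values, valid, window):
    """Clipped-window moving average over valid samples, naive loops."""
    n = len(values)
    half = window // 2
    out = [math.nan] * n
    for i in range(n):
        acc, cnt = 0.0, 0
        for j in range(max(0, i - half), min(n, i + half + 1)):
            if valid[j]:
                acc += values[j]
                cnt += 1
        if cnt:
            out[i] = acc / cnt
    return out


def speed_oracle(t, x, y, valid, window):
    """Per-sample speed via naive central/one-sided differences."""
    xs = smooth_oracle(x, valid, window)
    ys = smooth_oracle(y, valid, window)
    n = len(t)
    out = [math.nan] * n
    for i in range(n):
        if not valid[i]:
            continue
        left = i - 1 if i > 0 and valid[i - 1] else None
        right = i + 1 if i < n - 1 and valid[i + 1] else None
        if left is not None and right is not None:
            lo, hi = left, right
        elif right is not None:
            lo, hi = i, right
        elif left is not None:
            lo, hi = left, i
        else:
            continue
        dt = (t[hi] - t[lo]) / 1000.0
        out[i] = math.hypot(xs[hi] - xs[lo], ys[hi] - ys[lo]) / dt
    return out


def saccade_runs_oracle(t, speed, valid, threshold, min_duration_ms):
    """Sample-by-sample scan for velocity-threshold runs; (onset, offset) times."""
    n = len(t)
    runs = []
    i = 0
    while i < n:
        ok = valid[i] and not math.isnan(speed[i]) and speed[i] >= threshold
        if not ok:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1] and not math.isnan(speed[j + 1]) and speed[
            j + 1
        ] >= threshold:
            j += 1
        if t[j] - t[i] >= min_duration_ms:
            runs.append((t[i], t[j]))
        i = j + 1
    return runs
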