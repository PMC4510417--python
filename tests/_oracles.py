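"""Independent reference implementations used only as test oracles.

Everything here is deliberately written as plain, slow, loop-based code
with no shared helpers from the package, so that agreement with the
optimized implementations is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def brute_msampen(segment, M, tau, r):
    """Exhaustive multivariate sample entropy by double-loop enumeration.

    Builds every composite delay vector explicitly, compares all pairs with
    an element-wise Chebyshev max, and pools the n*(N-delta) one-sample
    channel extensions for the (m+1)-point stage.  Returns NaN when either
    match frequency is zero.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim == 1:
        segment = segment[:, None]
    n_samp, n_chan = segment.shape
    delta = max(M) * max(tau)

    def composite(i, dims):
        out = []
        for k in range(n_chan):
            for j in range(dims[k]):
                out.append(segment[i + j * tau[k], k])
        return out

    def avg_match_freq(vectors):
        n_vec = len(vectors)
        total = 0.0
        for i in range(n_vec):
            count = 0
            for j in range(n_vec):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(vectors[i], vectors[j]))
                if d <= r:
                    count += 1
            total += count / (n_vec - 1)
        return total / n_vec

    vm = [composite(i, list(M)) for i in range(n_samp - delta)]
    vm1 = []
    for k in range(n_chan):
        dims = list(M)
        dims[k] += 1
        vm1.extend(composite(i, dims) for i in range(n_samp - delta))
    b_m = avg_match_freq(vm)
    b_m1 = avg_match_freq(vm1)
    if b_m <= 0.0 or b_m1 <= 0.0:
        return math.nan
    return -math.log(b_m1 / b_m)


def brute_sampen(x, m, r):
    """Classic univariate sample entropy, counted over N-m template pairs."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    templates_m = [x[i:i + m] for i in range(n - m)]
    templates_m1 = [x[i:i + m + 1] for i in range(n - m)]

    def freq(templates):
        n_t = len(templates)
        total = 0.0
        for i in range(n_t):
            count = 0
            for j in range(n_t):
                if i == j:
                    continue
                if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r:
                    count += 1
            total += count / (n_t - 1)
        return total / n_t

    b = freq(templates_m)
    a = freq(templates_m1)
    if b <= 0.0 or a <= 0.0:
        return math.nan
    return -math.log(a / b)


def takens_embedding(x, m, tau):
    """Classic univariate delay embedding as an explicit loop."""
    x = np.asarray(x, dtype=float).ravel()
    n_vec = len(x) - m * tau
    return np.array([[x[i + j * tau] for j in range(m)] for i in range(n_vec)])


def classic_emd(x, max_modes=6, sd_threshold=0.2, max_sift=15):
    """Minimal textbook EMD: maxima/minima cubic envelopes, mean subtraction.

    Independent of the package: uses its own extremum finder and relies on
    scipy interpolation directly, with simple slope-based end handling.
    """
    from scipy.interpolate import CubicSpline

    def extrema(y):
        mx, mn = [], []
        for i in range(1, len(y) - 1):
            if y[i] > y[i - 1] and y[i] > y[i + 1]:
                mx.append(i)
            if y[i] < y[i - 1] and y[i] < y[i + 1]:
                mn.append(i)
        return np.array(mx), np.array(mn)

    def envelope_mean(y):
        mx, mn = extrema(y)
        if len(mx) < 3 or len(mn) < 3:
            return None
        t = np.arange(len(y))

        def env(idx):
            ti = np.concatenate([[-idx[1], -idx[0]], idx,
                                 [2 * (len(y) - 1) - idx[-1],
                                  2 * (len(y) - 1) - idx[-2]]])
            vi = np.concatenate([[y[idx[1]], y[idx[0]]], y[idx],
                                 [y[idx[-1]], y[idx[-2]]]])
            keep = np.concatenate([[True], np.diff(ti) > 0])
            return CubicSpline(ti[keep], vi[keep])(t)

        return (env(mx) + env(mn)) / 2.0

    imfs = []
    res = np.asarray(x, dtype=float).copy()
    for _ in range(max_modes):
        if envelope_mean(res) is None:
            break
        cur = res.copy()
        for _ in range(max_sift):
            m = envelope_mean(cur)
            if m is None:
                break
            new = cur - m
            sd = float(np.sum(m * m)) / float(np.sum(cur * cur))
            cur = new
            if sd < sd_threshold:
                break
        imfs.append(cur)
        res = res - cur
    return imfs, res
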