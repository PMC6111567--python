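"""Independent naive oracles used to cross-check the vectorized code.

Everything here is written with explicit Python loops straight from the
defining formulas, deliberately ignoring the package's implementations.
"""

from __future__ import annotations

import math


def naive_features(rho, lam=0.85, nu=3, l=1, k=1, floor=1e-12) -> dict[str, float]:
    """The 13 descriptors of an M x N surface by direct double loops."""
    M = len(rho)
    N = len(rho[0])
    MN = M * N

    total = 0.0
    for t in range(M):
        for f in range(N):
            total += rho[t][f]
    mean = total / MN

    var = sk = ku = mad = sla = 0.0
    log_sum = 0.0
    abs_sum = 0.0
    ec = 0.0
    for t in range(M):
        for f in range(N):
            d = rho[t][f] - mean
            var += d * d
            sk += d**3
            ku += d**4
            mad += abs(d)
            mag = max(abs(rho[t][f]), floor)
            sla += math.log(mag)
            log_sum += math.log(mag)
            abs_sum += abs(rho[t][f])
            ec += abs(rho[t][f]) ** 2
    var /= MN
    mad /= MN
    if var > 0:
        sk = sk / (MN * var**1.5)
        ku = ku / (MN * var**2)
    else:
        sk = ku = 0.0

    rms = math.sqrt(abs(mean))

    lo = min(max(int(math.floor((M + 1) / 4 + 0.5)), 1), M)
    hi = min(max(int(math.floor(3 * (M + 1) / 4 + 0.5)), 1), M)
    iqr = 0.0
    for f in range(N):
        column = sorted(rho[t][f] for t in range(M))
        iqr += column[hi - 1] - column[lo - 1]
    iqr /= N

    if abs_sum > 0:
        fls = math.exp(log_sum / MN) / (abs_sum / MN)
    else:
        fls = 1.0

    flx = 0.0
    for t in range(M - l):
        for f in range(N - k):
            flx += rho[t + l][f + k] - rho[t][f]

    marginal = [sum(rho[t][f] for t in range(M)) for f in range(N)]
    sro = 1.0
    cumulative = 0.0
    for f in range(N):
        cumulative += marginal[f]
        if cumulative >= lam * total:
            sro = (f + 1) / N
            break

    if total != 0:
        power = 0.0
        for t in range(M):
            for f in range(N):
                power += (rho[t][f] / total) ** nu
        power = max(power, floor)
        nre = math.log2(power) / (1 - nu)
    else:
        nre = math.log2(floor) / (1 - nu)

    return {
        "mean": mean,
        "variance": var,
        "skewness": sk,
        "kurtosis": ku,
        "sla": sla,
        "mad": mad,
        "rms": rms,
        "iqr": iqr,
        "fls": fls,
        "flx": flx,
        "sro": sro,
        "nre": nre,
        "ec": ec,
    }


def naive_mutual_information(x, y) -> float:
    """I(X; Y) in bits by direct contingency counting."""
    n = len(x)
    joint: dict[tuple, int] = {}
    px: dict[object, int] = {}
    py: dict[object, int] = {}
    for xi, yi in zip(x, y):
        joint[(xi, yi)] = joint.get((xi, yi), 0) + 1
        px[xi] = px.get(xi, 0) + 1
        py[yi] = py.get(yi, 0) + 1
    mi = 0.0
    for (xi, yi), c in joint.items():
        p_xy = c / n
        mi += p_xy * math.log2(p_xy / ((px[xi] / n) * (py[yi] / n)))
    return mi


def enumerate_windows(n_samples: int, window: int, step: int) -> int:
    """Count left-aligned full windows by explicit enumeration."""
    count = 0
    start = 0
    while start + window <= n_samples:
        count += 1
        start += step
    return count
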