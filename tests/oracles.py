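"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal way possible (scalar loops,
dictionary tallies, direct formulas) and shares no code with the package
internals it checks.
"""

import math

import numpy as np


def shannon_entropy(p):
    """-sum p ln p over nonzero entries."""
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


def shannon_jsd(p, u):
    """Classical Jensen-Shannon divergence S(M) - S(P)/2 - S(U)/2."""
    m = [(pi + ui) / 2 for pi, ui in zip(p, u)]
    return shannon_entropy(m) - 0.5 * shannon_entropy(p) - 0.5 * shannon_entropy(u)


def naive_q_log(x, q):
    if abs(q - 1.0) < 1e-9:
        return math.log(x)
    return (x ** (1.0 - q) - 1.0) / (1.0 - q)


def naive_tsallis(p, q):
    return sum(pi * naive_q_log(1.0 / pi, q) for pi in p if pi > 0)


def naive_q_jsd(p, u, q):
    """Symmetrized q-Kullback divergence against the midpoint, scalar loops."""
    m = [(pi + ui) / 2 for pi, ui in zip(p, u)]
    kpm = -sum(pi * naive_q_log(mi / pi, q) for pi, mi in zip(p, m) if pi > 0)
    kum = -sum(ui * naive_q_log(mi / ui, q) for ui, mi in zip(u, m) if ui > 0)
    return 0.5 * kpm + 0.5 * kum


def naive_pattern_distribution(x, m, tau, levels):
    """Enumerate-and-count symbolization of a raw series, dictionary tally."""
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    var = sum((xi - mu) ** 2 for xi in x) / n
    y = [0.5 * (1.0 + math.erf((xi - mu) / math.sqrt(var) / math.sqrt(2.0))) for xi in x]
    y_min, y_max = min(y), max(y)
    width = (y_max - y_min) / levels
    rows = n - (m - 1) * tau
    counts = {}
    for j in range(rows):
        window = [y[j + k * tau] for k in range(m)]
        s1 = math.floor((window[0] - y_min) / width)
        s1 = min(max(s1, 0), levels - 1)
        pattern = [s1]
        for k in range(1, m):
            raw = s1 + math.floor((window[k] - window[0]) / width)
            pattern.append(min(max(raw, 0), levels - 1))
        key = tuple(pattern)
        counts[key] = counts.get(key, 0) + 1
    probs = np.zeros(levels**m)
    for pattern, c in counts.items():
        code = 0
        for s in pattern:
            code = code * levels + s
        probs[code] = c / rows
    return probs


def yule_walker_variance(alpha):
    """Stationary variance of an AR(p) with unit innovation variance.

    Solves the autocovariance equations gamma_k = sum_i alpha_i gamma_{|k-i|}
    (+ sigma^2 for k = 0) as a dense linear system in gamma_0..gamma_p.
    """
    p = len(alpha)
    A = np.zeros((p + 1, p + 1))
    b = np.zeros(p + 1)
    b[0] = 1.0  # unit innovation variance
    for k in range(p + 1):
        A[k, k] += 1.0
        for i in range(1, p + 1):
            A[k, abs(k - i)] -= alpha[i - 1]
    return float(np.linalg.solve(A, b)[0])
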