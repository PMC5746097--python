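"""Brute-force reference implementations used by the acceptance tests.

Written with explicit python loops, independently of the library code
paths they check.
"""

import math

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def _standardized_props():
    from apoploc.pseaac import load_property_table

    raw = load_property_table()
    out = {}
    for col in raw.columns:
        vals = [raw.loc[a, col] for a in AA]
        mu = sum(vals) / 20.0
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / 20.0)
        out[col] = {a: (raw.loc[a, col] - mu) / sd for a in AA}
    return out


def brute_pseaac(seq: str, lam: int, omega: float) -> np.ndarray:
    props = _standardized_props()
    L = len(seq)
    f = [seq.count(a) / L for a in AA]

    def theta(a, b):
        return sum((props[c][b] - props[c][a]) ** 2 for c in props) / 3.0

    taus = [
        sum(theta(seq[i], seq[i + k]) for i in range(L - k)) / (L - k)
        for k in range(1, lam + 1)
    ]
    denom = sum(f) + omega * sum(taus)
    return np.array(f + [omega * t for t in taus]) / denom


def brute_psepssm(scores: np.ndarray, xi: int) -> np.ndarray:
    L = scores.shape[0]
    norm = [[1.0 / (1.0 + math.exp(-scores[i][j])) for j in range(20)]
            for i in range(L)]
    means = [sum(norm[i][j] for i in range(L)) / L for j in range(20)]
    thetas = []
    for t in range(1, xi + 1):
        for j in range(20):
            s = sum((norm[i][j] - norm[i + t][j]) ** 2 for i in range(L - t))
            thetas.append(s / (L - t))
    return np.array(means + thetas)
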