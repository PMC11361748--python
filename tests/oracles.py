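"""Independent brute-force oracles used by the acceptance tests.

Deliberately plain-Python, loop-based implementations kept separate from
the package's vectorized code paths.
"""

import numpy as np


def bh_brute_force(p):
    """O(n^2) min-over-tail Benjamini-Hochberg step-up."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    for pos in range(n):
        tail = min(p[order[k]] * n / (k + 1) for k in range(pos, n))
        q[order[pos]] = min(1.0, tail)
    return q


def tmm_two_sample_brute_force(obs, ref, trim_m=0.30, trim_a=0.05):
    """Scaling factor of `obs` against reference `ref` (two count vectors),
    by explicit enumeration of the doubly trimmed weighted mean."""
    n_obs = float(sum(obs))
    n_ref = float(sum(ref))
    entries = []
    for y_obs, y_ref in zip(obs, ref):
        if y_obs <= 0 or y_ref <= 0:
            continue
        p_obs, p_ref = y_obs / n_obs, y_ref / n_ref
        m_val = np.log2(p_obs / p_ref)
        a_val = 0.5 * np.log2(p_obs * p_ref)
        w = (n_obs - y_obs) / (n_obs * y_obs) + (n_ref - y_ref) / (n_ref * y_ref)
        entries.append((m_val, a_val, w))
    n = len(entries)
    m_sorted = sorted(e[0] for e in entries)
    a_sorted = sorted(e[1] for e in entries)
    lo_m = int(np.floor(n * trim_m))
    lo_a = int(np.floor(n * trim_a))
    num = den = 0.0
    for m_val, a_val, w in entries:
        rank_m = m_sorted.index(m_val) + 1
        rank_a = a_sorted.index(a_val) + 1
        if lo_m + 1 <= rank_m <= n - lo_m and lo_a + 1 <= rank_a <= n - lo_a:
            num += m_val / w
            den += 1.0 / w
    return 2.0 ** (num / den)
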