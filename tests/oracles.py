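"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the code paths they check: unisolvency is decided
straight from SVD singular values, and the signed-rank p-value is computed
by exhaustive enumeration over all 2^n sign assignments.
"""

import itertools

import numpy as np
from scipy.stats import rankdata

from prfthermo.rbf import monomial_matrix


def nullspace_unisolvency_oracle(nodes, degree):
    V = monomial_matrix(nodes, degree)
    s = np.linalg.svd(V, compute_uv=False)
    tol = max(V.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    return int((s > tol).sum()) == V.shape[1]


def signflip_enumeration_p(diffs):
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    w_all = np.array(
        [ranks[np.array(signs, dtype=bool)].sum() for signs in itertools.product((0, 1), repeat=n)]
    )
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))
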