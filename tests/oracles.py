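"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: subnetwork selection by
exhaustive subset enumeration with LP feasibility, and hypergeometric tail
probabilities by exhaustive draw enumeration.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import linprog


def subset_feasible(S, ub, subset, eps):
    """Can every reaction in ``subset`` carry >= eps flux simultaneously?

    Excluded reactions are pinned to zero; feasibility is an LP with
    eps <= v_i <= ub_i on the included columns and S v = 0.
    """
    if not subset:
        return True
    cols = sorted(subset)
    # necessary condition: every touched metabolite row needs both signs
    Ssub = S[:, cols]
    touched = np.abs(Ssub).sum(axis=1) > 0
    if np.any(touched & ~((Ssub > 0).any(axis=1) & (Ssub < 0).any(axis=1))):
        return False
    bounds = [(eps, ub[j]) for j in cols]
    res = linprog(np.zeros(len(cols)), A_eq=Ssub, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    return res.status == 0


def best_subnetwork_bruteforce(model, weights, eps=1e-3):
    """Max-total-weight feasible subnetwork by full subset enumeration."""
    S = model.stoichiometric_matrix()
    _, ub = model.bounds_arrays()
    n = len(model.reactions)
    w = np.array([weights[r.id] for r in model.reactions])
    best, best_set = 0.0, frozenset()
    for size in range(n + 1):
        for subset in combinations(range(n), size):
            gain = w[list(subset)].sum() if subset else 0.0
            if gain <= best:
                continue
            if subset_feasible(S, ub, set(subset), eps):
                best, best_set = gain, frozenset(subset)
    return best, {model.reactions[j].id for j in best_set}


def hypergeom_upper_tail_enumeration(N, K, n, k):
    """P(X >= k) by counting draws: X = |draw ∩ pathway|, draw of size n."""
    total = comb(N, n)
    count = 0
    for i in range(k, min(K, n) + 1):
        count += comb(K, i) * comb(N - K, n - i)
    return count / total


def hypergeom_upper_tail_full_enumeration(N, K, n, k):
    """Same tail probability by literally iterating over all C(N, n) draws."""
    pathway = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(pathway & set(draw)) >= k)
    return hits / comb(N, n)
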