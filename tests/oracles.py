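"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive everything from first principles (exhaustive
enumeration, explicit normal equations) so agreement with the package is a
two-route check, not a tautology.
"""

import itertools

import numpy as np

# state order must match the package's convention: (maternal, paternal)
STATE_ORIGINS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # 0 = line A, 1 = line B


def haldane(d_cm: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def emission(call: int, state: int, fa: float, fb: float) -> float:
    """P(observed allele-2 dosage | origin state, line frequencies)."""
    if call < 0:  # missing
        return 1.0
    om, op = STATE_ORIGINS[state]
    fm = fa if om == 0 else fb
    fp = fa if op == 0 else fb
    return [
        (1 - fm) * (1 - fp),
        fm * (1 - fp) + (1 - fm) * fp,
        fm * fp,
    ][call]


def brute_force_posterior(calls, cms, fa, fb, query_cm):
    """Posterior of the 4 origin states at `query_cm` by exhaustive
    enumeration over all gamete-origin configurations at the markers plus
    the query position (2^(2L) paths)."""
    positions = sorted(set(list(cms) + [query_cm]))
    markers_at = {
        i: [j for j, c in enumerate(cms) if c == p] for i, p in enumerate(positions)
    }
    qi = positions.index(query_cm)
    L = len(positions)
    post = np.zeros(4)
    total = 0.0
    for path in itertools.product(range(4), repeat=L):
        p = 0.25
        for i in range(1, L):
            r = haldane(positions[i] - positions[i - 1])
            m0, p0 = STATE_ORIGINS[path[i - 1]]
            m1, p1 = STATE_ORIGINS[path[i]]
            p *= (r if m0 != m1 else 1 - r) * (r if p0 != p1 else 1 - r)
        for i in range(L):
            for j in markers_at[i]:
                p *= emission(calls[j], path[i], fa[j], fb[j])
        post[path[qi]] += p
        total += p
    return post / total


def normal_equations_ols(X, y):
    """Coefficients, RSS and coefficient SEs by explicit normal equations."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = len(y) - X.shape[1]
    cov = (rss / df) * np.linalg.inv(XtX)
    return beta, rss, np.sqrt(np.diag(cov)), df
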