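"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the implementation paths they check: AUC by
exhaustive pair counting, VIP by direct evaluation of the defining
formula, and PLS weights by a literal NIPALS hand-iteration with explicit
deflation.
"""

import numpy as np


def pair_counting_auc(case_values, control_values) -> float:
    """Exhaustive Mann-Whitney AUC: count wins, half-credit ties."""
    wins = 0.0
    for c in case_values:
        for k in control_values:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case_values) * len(control_values))


def vip_formula(weights, ss_y, through: int) -> np.ndarray:
    """Direct evaluation of VIP_j = sqrt(p * sum ss*w^2 / sum ss)."""
    W = np.asarray(weights, dtype=float)
    ss = np.asarray(ss_y, dtype=float)[:through]
    p = W.shape[0]
    out = np.empty(p)
    for j in range(p):
        num = sum(ss[k] * W[j, k] ** 2 for k in range(through))
        out[j] = np.sqrt(p * num / ss.sum())
    return out


def nipals_pls1(X, y, n_components, tol=1e-12, max_iter=1000):
    """Literal sequential NIPALS for a single centered response.

    Returns (W, T, P, q, ss_y) with unit-norm weight columns.
    """
    Xa = np.array(X, dtype=float)
    y = np.asarray(y, dtype=float)
    W, T, P, Q, SS = [], [], [], [], []
    for _ in range(n_components):
        u = y.copy()
        w = None
        for _ in range(max_iter):
            w_new = Xa.T @ u
            w_new = w_new / np.linalg.norm(w_new)
            t = Xa @ w_new
            q = (y @ t) / (t @ t)
            u = y * q
            if w is not None and np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xa @ w
        p_load = Xa.T @ t / (t @ t)
        Xa = Xa - np.outer(t, p_load)
        W.append(w)
        T.append(t)
        P.append(p_load)
        Q.append(q)
        SS.append(q * q * (t @ t))
    return (
        np.column_stack(W),
        np.column_stack(T),
        np.column_stack(P),
        np.asarray(Q),
        np.asarray(SS),
    )
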