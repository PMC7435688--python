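"""Independent brute-force / closed-form oracles used only by the tests.

Each oracle re-derives a quantity from its definition, without touching the
implementation path it checks.
"""

from __future__ import annotations

import numpy as np

# Affine-gap global alignment oracle. Weights are scaled so a single DP on
# the combined value maximizes (score, matches) lexicographically: score
# steps are integers (match 1, mismatch 0, gap open 10, extend 1), so
# score*1000 + matches is exact for sequences shorter than 1000 residues.
_MATCH = 1001      # 1 * 1000 + 1 match
_MISMATCH = 0
_GAP_OPEN = -10000  # cost of the first gap residue
_GAP_EXT = -1000
_NEG = -10**9


def needleman_affine_matches(a: str, b: str) -> tuple[float, int]:
    """Optimal global affine-gap (score, matches), maximizing matches on ties.

    Returns ``(score, matches)`` under match +1 / mismatch 0 / gap open 10 /
    extend 1, with end gaps penalized.
    """
    la, lb = len(a), len(b)
    m = np.full((lb + 1,), _NEG, dtype=np.int64)   # best ending in residue pair
    ix = np.full((lb + 1,), _NEG, dtype=np.int64)  # gap in b (consume a)
    iy = np.full((lb + 1,), _NEG, dtype=np.int64)  # gap in a (consume b)
    m[0] = 0
    for j in range(1, lb + 1):
        iy[j] = _GAP_OPEN + (j - 1) * _GAP_EXT
    for i in range(1, la + 1):
        prev_m, prev_ix, prev_iy = m.copy(), ix.copy(), iy.copy()
        m[0] = _NEG
        ix[0] = _GAP_OPEN + (i - 1) * _GAP_EXT
        iy[0] = _NEG
        ai = a[i - 1]
        for j in range(1, lb + 1):
            sub = _MATCH if ai == b[j - 1] else _MISMATCH
            m[j] = sub + max(prev_m[j - 1], prev_ix[j - 1], prev_iy[j - 1])
            ix[j] = max(prev_m[j] + _GAP_OPEN, prev_ix[j] + _GAP_EXT,
                        prev_iy[j] + _GAP_OPEN)
            iy[j] = max(m[j - 1] + _GAP_OPEN, iy[j - 1] + _GAP_EXT,
                        ix[j - 1] + _GAP_OPEN)
        m[0] = _NEG
    best = int(max(m[lb], ix[lb], iy[lb]))
    matches = best % 1000
    score = (best - matches) // 1000
    return float(score), int(matches)


def oracle_identity(a: str, b: str) -> float:
    """Identity (matches over shorter length) from the DP oracle."""
    _, matches = needleman_affine_matches(a, b)
    return matches / min(len(a), len(b))


def single_linkage_components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Union-find single-linkage components over pairwise threshold edges."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def confusion_tally(detected, positive) -> tuple[int, int, int, int]:
    """Per-cell brute-force TP/FP/TN/FN tally."""
    tp = fp = tn = fn = 0
    for d, p in zip(detected, positive):
        if d and p:
            tp += 1
        elif d and not p:
            fp += 1
        elif not d and p:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values straight from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return np.minimum(q, 1.0)


def dl_pool(theta, se) -> dict:
    """DerSimonian-Laird pooling computed step by step from the formulas."""
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    k = theta.size
    w = 1.0 / se**2
    theta_fe = (w * theta).sum() / w.sum()
    q = (w * (theta - theta_fe) ** 2).sum()
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / c)
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = (w_star * theta).sum() / w_star.sum()
    se_pooled = 1.0 / np.sqrt(w_star.sum())
    return {"pooled": pooled, "tau2": tau2, "q": q, "i2": i2, "se": se_pooled}


def ols_normal_equations(y, X) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and standard errors from the normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    return beta, np.sqrt(np.diag(sigma2 * xtx_inv))


def balanced_anova_ml(y_by_group: np.ndarray) -> tuple[float, float]:
    """Closed-form ML variance components for a balanced one-way layout.

    ``y_by_group`` is (k groups, n per group). Returns (sigma2, tau2):
    sigma2 = SSW / (k n - k... ) -- precisely SSW / (k (n-1)) and
    lambda = SSB'/k with SSB' = n * sum (ybar_i - ybar)^2, tau2 =
    max(0, (lambda - sigma2)/n).
    """
    k, n = y_by_group.shape
    ybar_i = y_by_group.mean(axis=1)
    ybar = y_by_group.mean()
    ssw = ((y_by_group - ybar_i[:, None]) ** 2).sum()
    sigma2 = ssw / (k * (n - 1))
    lam = n * ((ybar_i - ybar) ** 2).sum() / k
    tau2 = max(0.0, (lam - sigma2) / n)
    return sigma2, tau2


def logistic_loglik(y, X, beta) -> float:
    """Bernoulli log-likelihood at a given coefficient vector."""
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    return float((np.asarray(y) * eta - np.log1p(np.exp(eta))).sum())
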