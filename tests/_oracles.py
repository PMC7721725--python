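"""Independent reference implementations used only to check the package.

Everything here is deliberately written as plain, loop-based "textbook"
code, sharing no internals with methorigin, so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from skbio import TreeNode


# ---------------------------------------------------------------------------
# Neighbor joining, textbook O(n^3) version
# ---------------------------------------------------------------------------

def naive_nj(labels, D):
    """Saitou-Nei agglomeration with explicit loops.

    Ties in Q are broken by the lexicographically smallest pair of
    canonical subtree labels (smallest member tip name). Returns an
    unrooted skbio TreeNode whose root has three children.
    """
    D = {
        (la, lb): float(D[i][j])
        for i, la in enumerate(labels)
        for j, lb in enumerate(labels)
    }
    nodes = {l: TreeNode(name=l) for l in labels}
    canon = {l: l for l in labels}
    active = list(labels)

    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * D[(a, b)] - r[a] - r[b]
                key = tuple(sorted((canon[a], canon[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[3]
                ):
                    best = (q, a, b, key)
        _, a, b, key = best
        la = D[(a, b)] / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = D[(a, b)] - la
        nodes[a].length = la
        nodes[b].length = lb
        parent = TreeNode(children=[nodes[a], nodes[b]])
        new = f"__internal_{len(nodes)}"
        nodes[new] = parent
        canon[new] = min(canon[a], canon[b])
        for c in active:
            if c not in (a, b):
                D[(new, c)] = D[(c, new)] = (D[(a, c)] + D[(b, c)] - D[(a, b)]) / 2.0
        D[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = active
    la = (D[(a, b)] + D[(a, c)] - D[(b, c)]) / 2.0
    lb = (D[(a, b)] + D[(b, c)] - D[(a, c)]) / 2.0
    lc = (D[(a, c)] + D[(b, c)] - D[(a, b)]) / 2.0
    nodes[a].length = la
    nodes[b].length = lb
    nodes[c].length = lc
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


# ---------------------------------------------------------------------------
# Moderated t, scalar step-by-step version
# ---------------------------------------------------------------------------

def trigamma_inverse_scalar(x):
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * abs(y):
            break
    return y


def naive_moderated_t(y1, y2):
    """Two-group moderated t per probe: plain loops over probes.

    y1, y2: probes x samples arrays for the two groups. Returns dict of
    arrays (delta, t, p, df_prior, s2_prior).
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n_probes = y1.shape[0]
    n1, n2 = y1.shape[1], y2.shape[1]
    df = n1 + n2 - 2
    s2 = np.empty(n_probes)
    delta = np.empty(n_probes)
    for i in range(n_probes):
        m1, m2 = y1[i].mean(), y2[i].mean()
        v1 = ((y1[i] - m1) ** 2).sum() / (n1 - 1)
        v2 = ((y2[i] - m2) ** 2).sum() / (n2 - 1)
        delta[i] = m1 - m2
        s2[i] = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    # moments fit of the scaled inverse-chi-square prior on log variances
    z = [np.log(v) for v in s2 if v > 0]
    e = [zz - digamma(df / 2.0) + np.log(df / 2.0) for zz in z]
    m = sum(e) / len(e)
    var = sum((ee - m) ** 2 for ee in e) / (len(e) - 1) - polygamma(1, df / 2.0)
    if var > 0:
        d0 = 2.0 * trigamma_inverse_scalar(var)
        s0 = np.exp(m + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(m)

    t_vals = np.empty(n_probes)
    p_vals = np.empty(n_probes)
    for i in range(n_probes):
        if np.isfinite(d0):
            s2_post = (d0 * s0 + df * s2[i]) / (d0 + df)
            dof = df + d0
        else:
            s2_post = s0
            dof = 1e12
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t_vals[i] = delta[i] / se if se > 0 else 0.0
        p_vals[i] = 2.0 * t_dist.sf(abs(t_vals[i]), dof)
    return {"delta": delta, "t": t_vals, "p": p_vals, "d0": d0, "s0": s0}


def naive_bh(p):
    """Benjamini-Hochberg by direct order statistics."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def naive_km(times, events):
    """Hand product-limit computation: list of (time, S) after each
    distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


def naive_logrank(times, events, groups):
    """Multi-group log-rank by direct summation over risk sets."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    k = len(levels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n_g = np.array([(at_risk & (groups == g)).sum() for g in levels], float)
        d_g = np.array(
            [((times == t) & (events == 1) & (groups == g)).sum() for g in levels],
            float,
        )
        O += d_g
        E += d * n_g / n
        if n > 1:
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    V[a, b] += (
                        d * (n - d) / (n - 1) * (n_g[a] / n) * (delta - n_g[b] / n)
                    )
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(z @ np.linalg.solve(Vsub, z))
    from scipy.stats import chi2

    return stat, float(chi2.sf(stat, k - 1))


# ---------------------------------------------------------------------------
# Constrained projection, exhaustive simplex grid
# ---------------------------------------------------------------------------

def grid_search_fractions(M, y, resolution=0.01):
    """Exhaustive search of w >= 0, sum(w) <= 1 on a grid (3 cell types)."""
    best_w, best_obj = None, np.inf
    steps = int(round(1.0 / resolution))
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            for l in range(steps + 1 - i - j):
                w = np.array([i, j, l], float) * resolution
                r = y - M @ w
                obj = float(r @ r)
                if obj < best_obj:
                    best_obj, best_w = obj, w
    return best_w, best_obj
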