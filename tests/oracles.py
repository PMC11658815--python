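"""Hand-rolled reference implementations used as independent test oracles.

Everything here is deliberately naive — direct formulas, exhaustive
enumeration, O(n^2) loops — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def km_product_limit(time, event):
    """Direct product-limit survival estimate at each distinct observed time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    times = np.unique(time)
    s = 1.0
    out = []
    for t in times:
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out.append((t, at_risk, d, s))
    return out


def logrank_statistic_2group(time, event, group):
    """Two-group log-rank chi-square by the O-E / V formula."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & (group == 1)).sum())
        if n < 2:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d1 - e1
        var += v
    return o_minus_e**2 / var if var > 0 else 0.0


def logrank_exact_permutation_p(time, event, group):
    """Exact permutation p of the two-group log-rank statistic (small n)."""
    group = np.asarray(group, dtype=int)
    n = len(group)
    n1 = int(group.sum())
    obs = logrank_statistic_2group(time, event, group)
    count = 0
    total = 0
    for ones in itertools.combinations(range(n), n1):
        g = np.zeros(n, dtype=int)
        g[list(ones)] = 1
        stat = logrank_statistic_2group(time, event, g)
        count += stat >= obs - 1e-12
        total += 1
    return count / total


def efron_partial_loglik(beta, time, event, x):
    """Efron-tie Cox partial log-likelihood for a single covariate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    eta = beta * x
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(dead.sum())
        sum_eta_dead = eta[dead].sum()
        risk_sum = np.exp(eta[at_risk]).sum()
        tied_sum = np.exp(eta[dead]).sum()
        ll += sum_eta_dead
        for j in range(d):
            ll -= np.log(risk_sum - j / d * tied_sum)
    return ll


def ward_bruteforce_labels(x, k):
    """Greedy agglomerative clustering minimizing the Ward SS increase,
    recomputed from scratch at every step."""
    x = np.asarray(x, dtype=float)
    clusters = [[i] for i in range(len(x))]

    def merge_cost(a, b):
        ca, cb = x[a].mean(axis=0), x[b].mean(axis=0)
        na, nb = len(a), len(b)
        return na * nb / (na + nb) * float(((ca - cb) ** 2).sum())

    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                c = merge_cost(clusters[i], clusters[j])
                if best is None or c < best[0]:
                    best = (c, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(x), dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


def silhouette_direct(x, labels):
    """O(n^2) silhouette mean; singleton clusters contribute 0."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n = len(x)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            scores.append(0.0)
            continue
        a = dist[i, same].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def bh_bruteforce(pvals):
    """Step-up BH from the definition (cumulative minima of m*p/rank)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        adj[idx] = running
    return adj


def hypergeom_tail(k, M, n, N):
    """P(X >= k) by direct summation of the hypergeometric PMF."""
    from math import comb

    denom = comb(M, N)
    total = 0
    for x in range(k, min(n, N) + 1):
        total += comb(n, x) * comb(M - n, N - x)
    return total / denom
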