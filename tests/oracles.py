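"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most transparent method available —
exhaustive enumeration, closed forms, or direct definitional loops — and is
deliberately kept free of the package's own code paths.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def ndcc_double_loop(disp: np.ndarray) -> np.ndarray:
    """Dynamic cross-correlation by explicit double loop over residue pairs.

    ``disp``: (F, R, 3) displacement vectors already centered per residue.
    """
    F, R, _ = disp.shape
    C = np.zeros((R, R))
    for i in range(R):
        for j in range(R):
            num = sum(float(np.dot(disp[f, i], disp[f, j])) for f in range(F)) / F
            vi = sum(float(np.dot(disp[f, i], disp[f, i])) for f in range(F)) / F
            vj = sum(float(np.dot(disp[f, j], disp[f, j])) for f in range(F)) / F
            C[i, j] = num / np.sqrt(vi * vj)
    return C


# ---------------------------------------------------------------------------
# centrality oracles on small weighted graphs
# edges: list of (i, j, weight); nodes: sorted list
# ---------------------------------------------------------------------------


def _adj(nodes, edges):
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[idx[i], idx[j]] = W[idx[j], idx[i]] = w
    return W


def degree_oracle(nodes, edges):
    W = _adj(nodes, edges)
    return dict(zip(nodes, W.sum(axis=1)))


def _all_shortest_paths(W):
    """All-pairs shortest -ln(weight) distances and path counts/through-counts
    by exhaustive simple-path enumeration (small n only)."""
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, -np.log(np.minimum(W, 1.0)), np.inf)
    np.fill_diagonal(L, np.inf)
    best = {}
    for s in range(n):
        for t in range(n):
            if s >= t:
                continue
            paths = []
            # enumerate all simple paths s -> t
            stack = [(s, (s,), 0.0)]
            while stack:
                v, path, dist = stack.pop()
                if v == t:
                    paths.append((dist, path))
                    continue
                for u in range(n):
                    if u in path or not np.isfinite(L[v, u]):
                        continue
                    stack.append((u, path + (u,), dist + L[v, u]))
            if not paths:
                continue
            dmin = min(d for d, _ in paths)
            shortest = [p for d, p in paths if d <= dmin + 1e-12]
            best[(s, t)] = (dmin, shortest)
    return best


def closeness_oracle(nodes, edges):
    """Freeman closeness with the connected-subgraph scaling networkx uses:
    for node v reachable from r others, C(v) = (r / (n-1)) * (r / sum d)."""
    W = _adj(nodes, edges)
    n = len(nodes)
    best = _all_shortest_paths(W)
    out = {}
    for v in range(n):
        dists = []
        for u in range(n):
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            if key in best:
                dists.append(best[key][0])
        r = len(dists)
        if r == 0 or sum(dists) == 0:
            out[nodes[v]] = 0.0
        else:
            out[nodes[v]] = (r / (n - 1)) * (r / sum(dists))
    return out


def betweenness_oracle(nodes, edges):
    """Normalized shortest-path betweenness by path enumeration."""
    W = _adj(nodes, edges)
    n = len(nodes)
    best = _all_shortest_paths(W)
    bt = np.zeros(n)
    for (s, t), (_, shortest) in best.items():
        sigma = len(shortest)
        for v in range(n):
            if v in (s, t):
                continue
            sigma_v = sum(1 for p in shortest if v in p)
            bt[v] += sigma_v / sigma
    if n > 2:
        bt /= (n - 1) * (n - 2) / 2
    return dict(zip(nodes, bt))


def current_flow_closeness_oracle(nodes, edges):
    """1 / (total effective resistance to all other nodes), via pinv(L)."""
    W = _adj(nodes, edges)
    n = len(nodes)
    L = np.diag(W.sum(axis=1)) - W
    Lp = np.linalg.pinv(L)
    out = {}
    for v in range(n):
        res = sum(Lp[v, v] + Lp[t, t] - 2 * Lp[v, t] for t in range(n))
        out[nodes[v]] = 1.0 / res if res > 0 else 0.0
    return out


def current_flow_betweenness_oracle(nodes, edges):
    """Normalized current-flow betweenness via Laplacian pseudoinverse.

    Throughput of v for unit current s->t is half the summed absolute edge
    currents at v (v not a terminal); normalization (n-1)(n-2)/2.
    """
    W = _adj(nodes, edges)
    n = len(nodes)
    L = np.diag(W.sum(axis=1)) - W
    Lp = np.linalg.pinv(L)
    bt = np.zeros(n)
    for s, t in combinations(range(n), 2):
        p = Lp[:, s] - Lp[:, t]
        for v in range(n):
            if v in (s, t):
                continue
            flow = 0.5 * sum(
                W[v, j] * abs(p[v] - p[j]) for j in range(n) if W[v, j] > 0
            )
            bt[v] += flow
    if n > 2:
        bt /= (n - 1) * (n - 2) / 2
    return dict(zip(nodes, bt))


def eigenvector_oracle(nodes, edges, n_iter: int = 10000):
    """Shifted power iteration on the weight matrix, scaled to unit maximum.

    The shift W + cI (c > spectral radius) makes the dominant eigenvalue
    unique and positive, so iteration converges even on bipartite graphs.
    """
    W = _adj(nodes, edges)
    shift = W.sum() + 1.0
    A = W + shift * np.eye(W.shape[0])
    x = np.ones(W.shape[0])
    for _ in range(n_iter):
        y = A @ x
        x = y / np.linalg.norm(y)
    x = np.abs(x)
    return dict(zip(nodes, x / x.max()))


# ---------------------------------------------------------------------------


def stable_windows_scan(values, window, std_max):
    """Frame coverage of passing sliding windows, as (start, end) runs."""
    n = len(values)
    covered = np.zeros(n, dtype=bool)
    for s in range(n - window + 1):
        if np.std(values[s : s + window]) <= std_max:
            covered[s : s + window] = True
    runs = []
    s = None
    for f in range(n + 1):
        inside = f < n and covered[f]
        if inside and s is None:
            s = f
        elif not inside and s is not None:
            runs.append((s, f))
            s = None
    return runs


def variant_matcher(wt_sets, mut_sets):
    """Independent reimplementation of the DSCLS variant-matching rules.

    Input: lists of residue frozensets, ids = positions. Returns
    (links, event kinds multiset) where links is a set of (wt, mut) pairs.
    """
    def jac(a, b):
        return len(a & b) / len(a | b) if a | b else 0.0

    cands = sorted(
        (
            (-jac(a, b), ia, ib)
            for ia, a in enumerate(wt_sets)
            for ib, b in enumerate(mut_sets)
            if jac(a, b) >= 0.3
        )
    )
    wl, ml = {}, {}
    links = []
    for negj, ia, ib in cands:
        if ia not in wl or ib not in ml:
            links.append((ia, ib, -negj))
            wl.setdefault(ia, []).append(ib)
            ml.setdefault(ib, []).append(ia)
    events = []
    for ib, ias in ml.items():
        if len(ias) >= 2:
            events.append(("fusion", tuple(sorted(ias)), (ib,)))
    for ia, ibs in wl.items():
        if len(ibs) >= 2:
            events.append(("fission", (ia,), tuple(sorted(ibs))))
    for ia, ib, j in links:
        if len(wl[ia]) == 1 and len(ml[ib]) == 1 and j < 0.6:
            events.append(("relocation", (ia,), (ib,)))
    for ia in range(len(wt_sets)):
        if ia not in wl:
            events.append(("loss", (ia,), ()))
    for ib in range(len(mut_sets)):
        if ib not in ml:
            events.append(("gain", (), (ib,)))
    return {(a, b) for a, b, _ in links}, sorted(events)
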