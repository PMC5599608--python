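"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most transparent method available
(explicit loops, textbook recursions, exhaustive search) without touching
the implementation under test.
"""

import numpy as np


def dijkstra_oracle(grid, sources):
    """O(V^2) Dijkstra over the 16-neighbour sea lattice with explicit loops.

    Moves: queen + knight; diagonal and knight moves require the cells they
    pass over to be sea.  Land sources are seeded through their 8-adjacent
    sea cells at zero cost.
    """
    moves = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if (dr, dc) != (0, 0):
                moves.append((dr, dc))
    moves += [(1, 2), (2, 1), (-1, 2), (-2, 1), (1, -2), (2, -1), (-1, -2), (-2, -1)]

    def intermediates(dr, dc):
        if abs(dr) + abs(dc) == 1:
            return []
        if abs(dr) == 1 and abs(dc) == 1:
            return [(dr, 0), (0, dc)]
        sr = 1 if dr > 0 else -1
        sc = 1 if dc > 0 else -1
        if abs(dc) == 2:
            return [(0, sc), (sr, sc)]
        return [(sr, 0), (sr, sc)]

    nr, nc = grid.nrows, grid.ncols
    dist = np.full((nr, nc), np.inf)
    seeds = set()
    for r, c in sources:
        if grid.sea[r, c]:
            seeds.add((r, c))
        else:
            for rr in range(r - 1, r + 2):
                for cc in range(c - 1, c + 2):
                    if 0 <= rr < nr and 0 <= cc < nc and grid.sea[rr, cc] and (rr, cc) != (r, c):
                        seeds.add((rr, cc))
    for s in seeds:
        dist[s] = 0.0
    visited = np.zeros((nr, nc), bool)
    while True:
        best, bd = None, np.inf
        for r in range(nr):
            for c in range(nc):
                if not visited[r, c] and dist[r, c] < bd:
                    best, bd = (r, c), dist[r, c]
        if best is None:
            break
        r, c = best
        visited[r, c] = True
        for dr, dc in moves:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nr and 0 <= cc < nc) or not grid.sea[rr, cc]:
                continue
            if any(
                not (0 <= r + ir < nr and 0 <= c + ic < nc) or not grid.sea[r + ir, c + ic]
                for ir, ic in intermediates(dr, dc)
            ):
                continue
            w = np.hypot(dr, dc) * grid.cell_size
            if bd + w < dist[rr, cc]:
                dist[rr, cc] = bd + w
    dist[grid.land] = np.inf
    return dist


def kde_oracle(points, H, grid):
    """Direct double-loop Gaussian KDE at sea-cell centres."""
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(H)))
    vals = np.zeros((grid.nrows, grid.ncols))
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            if grid.land[r, c]:
                continue
            x, y = grid.centre_of(r, c)
            s = 0.0
            for px, py in points:
                d = np.array([x - px, y - py])
                s += norm * np.exp(-0.5 * d @ Hinv @ d)
            vals[r, c] = s * grid.cell_area / len(points)
    return vals / vals.sum()


def logistic_newton_oracle(X, y, tol=1e-12, max_iter=100):
    """Plain Newton-Raphson for the Bernoulli logistic MLE."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def cluster_sandwich_oracle(X, y, beta, panels):
    """Panel-clustered sandwich covariance for the logistic score, no correction."""
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = p * (1 - p)
    bread = np.linalg.inv(X.T @ (X * W[:, None]))
    scores = X * (y - p)[:, None]
    meat = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(panels):
        s = scores[panels == g].sum(axis=0)
        meat += np.outer(s, s)
    return bread @ meat @ bread


def amoc_oracle(y, scales):
    """Exhaustive single-break least-squares change point."""
    y = np.asarray(y, float)
    best_tau, best = None, np.inf
    for tau in range(1, len(y)):
        a, b = y[:tau], y[tau:]
        cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if cost < best - 1e-12:
            best, best_tau = cost, tau
    return scales[best_tau]


def deboor_oracle(x, t, k, i):
    """Cox-de Boor recursion for B-spline basis function B_{i,k} at scalar x."""
    if k == 0:
        # right-closed at the final interval so the basis covers the endpoint
        if t[i] <= x < t[i + 1]:
            return 1.0
        if x == t[-1] and t[i] < t[i + 1] <= t[-1] and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    out = 0.0
    d1 = t[i + k] - t[i]
    if d1 > 0:
        out += (x - t[i]) / d1 * deboor_oracle(x, t, k - 1, i)
    d2 = t[i + k + 1] - t[i + 1]
    if d2 > 0:
        out += (t[i + k + 1] - x) / d2 * deboor_oracle(x, t, k - 1, i + 1)
    return out
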