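"""Area rebalancing after region growing.

Stochastic region growing can enclose a patch before it reaches its
target area; the leftover free cells then end up on the wrong patches.
This pass restores per-patch target areas by shifting cell ownership one
unit at a time from surplus patches to deficit patches along shortest
paths in the patch-adjacency graph, choosing donated boundary cells that
keep every donor 4-connected.  Patches isolated from any surplus (e.g.
sealed behind barriers) keep a residual deficit, which the caller
reports.
"""

from __future__ import annotations

from collections import deque

import numpy as np

__all__ = ["rebalance_areas"]

_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _neighbors(flat: int, nrows: int, ncols: int):
    r, c = divmod(flat, ncols)
    for dr, dc in _OFFSETS:
        nr, nc = r + dr, c + dc
        if 0 <= nr < nrows and 0 <= nc < ncols:
            yield nr * ncols + nc


def _is_articulation(cells: set, cell: int, nrows: int, ncols: int) -> bool:
    """Would removing ``cell`` disconnect the patch (4-connectivity)?"""
    rest = cells - {cell}
    if not rest:
        return True  # never empty a patch
    start = next(iter(rest))
    seen = {start}
    dq = deque([start])
    while dq:
        f = dq.popleft()
        for nf in _neighbors(f, nrows, ncols):
            if nf in rest and nf not in seen:
                seen.add(nf)
                dq.append(nf)
    return len(seen) != len(rest)


def _adjacency(grid: np.ndarray, habitat: np.ndarray) -> dict:
    """Patch-adjacency graph among habitat patches (4-neighbourhood)."""
    adj: dict[int, set] = {}

    def add_pairs(a, b, mask):
        for x, y in zip(a[mask].ravel(), b[mask].ravel()):
            adj.setdefault(int(x), set()).add(int(y))
            adj.setdefault(int(y), set()).add(int(x))

    g0, g1 = grid[:-1, :], grid[1:, :]
    m = (g0 != g1) & habitat[:-1, :] & habitat[1:, :]
    add_pairs(g0, g1, m)
    g0, g1 = grid[:, :-1], grid[:, 1:]
    m = (g0 != g1) & habitat[:, :-1] & habitat[:, 1:]
    add_pairs(g0, g1, m)
    return adj


def _find_path(P, adj, dist, blocked):
    """Backtracking DFS over the dist-decreasing DAG from a deficit patch
    down to any surplus patch (dist 0), avoiding blocked (recv, donor)
    edges.  Returns the patch-id path or None."""
    path = [P]

    def dfs(u):
        if dist[u] == 0:
            return True
        for q in sorted(adj.get(u, ())):
            if (
                q in dist
                and dist[q] == dist[u] - 1
                and (u, q) not in blocked
                and q not in path
            ):
                path.append(q)
                if dfs(q):
                    return True
                path.pop()
        return False

    return path if dfs(P) else None


def rebalance_areas(grid: np.ndarray, habitat: np.ndarray, targets: dict) -> dict:
    """Shift cell ownership until every patch meets its target area.

    ``grid`` (modified in place) holds patch identifiers; ``habitat``
    masks the cells that may change ownership; ``targets`` maps habitat
    patch id -> target area in cells.  Returns the residual deficit map
    (id -> target − final area), zero everywhere unless a deficit patch
    is unreachable from any surplus patch.
    """
    nrows, ncols = grid.shape
    ids = list(targets)
    cells: dict[int, set] = {p: set() for p in ids}
    flat = grid.ravel()
    for f in np.flatnonzero(habitat.ravel()):
        cells[int(flat[f])].add(int(f))
    area = {p: len(cells[p]) for p in ids}

    blocked: set = set()  # (recv, donor) pairs where donation failed
    stall = 0
    while stall < 3:
        deficit = {p: targets[p] - area[p] for p in ids}
        wanting = [p for p in ids if deficit[p] > 0]
        if not wanting:
            break
        surplus = {p for p in ids if deficit[p] < 0}
        if not surplus:
            break
        adj = _adjacency(grid, habitat)
        # multi-source BFS from surplus patches over the patch graph
        dist = {p: 0 for p in surplus}
        dq = deque(surplus)
        while dq:
            p = dq.popleft()
            for q in adj.get(p, ()):
                if q not in dist:
                    dist[q] = dist[p] + 1
                    dq.append(q)
        reachable = [p for p in wanting if p in dist]
        if not reachable:
            break
        moved_any = False
        for P in sorted(reachable, key=lambda p: dist[p]):
            for _attempt in range(8):  # explore alternate paths on failure
                path = _find_path(P, adj, dist, blocked)
                if path is None:
                    break
                S = path[-1]
                units = min(deficit[P], -min(0, targets[S] - area[S]))
                failed = False
                for _ in range(max(0, units)):
                    ok = True
                    for recv, donor in zip(path[:-1], path[1:]):
                        cand = [
                            c
                            for c in cells[donor]
                            if any(nf in cells[recv] for nf in _neighbors(c, nrows, ncols))
                        ]
                        give = next(
                            (c for c in cand if not _is_articulation(cells[donor], c, nrows, ncols)),
                            None,
                        )
                        if give is None:
                            blocked.add((recv, donor))
                            ok = False
                            failed = True
                            break
                        cells[donor].remove(give)
                        cells[recv].add(give)
                        grid.ravel()[give] = recv
                    if not ok:
                        break
                    area[P] += 1
                    area[S] -= 1
                    deficit[P] -= 1
                    moved_any = True
                if deficit[P] == 0 or not failed:
                    break
        stall = 0 if moved_any else stall + 1
        if moved_any:
            blocked.clear()  # geometry changed; previously blocked pairs may now work
    return {p: targets[p] - area[p] for p in ids}
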