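"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by the most transparent method available
(flood fill, exhaustive enumeration, closed forms) without touching the
implementation under test.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def flood_fill_components(mask: np.ndarray,
                          connectivity: int = 8) -> list[frozenset]:
    """Connected components of a boolean grid by explicit BFS flood fill.

    Returns the set of components, each a frozenset of (row, col) pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    elif connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r in range(ny):
        for c in range(nx):
            if not mask[r, c] or seen[r, c]:
                continue
            queue = [(r, c)]
            seen[r, c] = True
            comp = []
            while queue:
                rr, cc = queue.pop()
                comp.append((rr, cc))
                for dr, dc in neigh:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < ny and 0 <= c2 < nx and mask[r2, c2]
                            and not seen[r2, c2]):
                        seen[r2, c2] = True
                        queue.append((r2, c2))
            components.append(frozenset(comp))
    return components


def min_sum_assignment(xy_a: np.ndarray, xy_b: np.ndarray,
                       d_max: float) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive minimum-total-distance assignment between two point sets.

    Over all injective matchings with every link ≤ d_max, pick those of
    maximum cardinality, then minimum total distance.  Feasible only for
    tiny instances (≤ ~7 points per side).
    """
    xy_a = np.asarray(xy_a, float).reshape(-1, 2)
    xy_b = np.asarray(xy_b, float).reshape(-1, 2)
    na, nb = len(xy_a), len(xy_b)
    dist = np.linalg.norm(xy_a[:, None, :] - xy_b[None, :, :], axis=2)
    best_links: list[tuple[int, int]] = []
    best_sum = np.inf
    idx_b = list(range(nb))
    # permute the longer side over slots of the shorter side
    for perm in permutations(idx_b, min(na, nb)):
        if na <= nb:
            pairs = [(i, j) for i, j in enumerate(perm)]
        else:
            pairs = [(j, i) for i, j in enumerate(perm)]
        pairs = [(i, j) for i, j in pairs if dist[i, j] <= d_max]
        total = sum(dist[i, j] for i, j in pairs)
        if (len(pairs) > len(best_links)
                or (len(pairs) == len(best_links) and total < best_sum)):
            best_links, best_sum = pairs, total
    return best_links, (best_sum if best_links else 0.0)


def anova_f_from_scratch(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F statistic from explicit sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(allv) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def point_source_concentration(r: float, t: float, D: float,
                               M: float) -> float:
    """Direct one-line 2-D diffusion kernel evaluation."""
    return M / (4 * np.pi * D * t) * np.exp(-r ** 2 / (4 * D * t))
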