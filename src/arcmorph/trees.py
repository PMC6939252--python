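"""Neighbour-joining phenograms from group distance matrices.

Saitou–Nei neighbour joining on Mahalanobis distances between group mean
shapes.  Negative branch lengths, which NJ can produce on non-additive
distances, are clamped to zero with the deficit transferred to the sister
branch so path lengths through the joined pair are preserved.
"""

from __future__ import annotations

import numpy as np

from .classify import MahalanobisMatrix


class _Node:
    def __init__(self, label: str | None = None,
                 children: list[tuple["_Node", float]] | None = None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        parts = ",".join(f"{child.newick()}:{length:.10g}"
                         for child, length in self.children)
        return f"({parts})"


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def nj_tree(dist: MahalanobisMatrix | np.ndarray, labels: list[str] | None = None) -> str:
    """Build an unrooted neighbour-joining tree; returns a newick string.

    Accepts a :class:`MahalanobisMatrix` or a plain symmetric matrix with
    ``labels``.  Requires at least 3 taxa.  On distances that are exactly
    additive the tree topology and branch lengths are recovered exactly.
    """
    if isinstance(dist, MahalanobisMatrix):
        d = dist.distances.astype(float).copy()
        labels = list(dist.groups)
    else:
        d = np.asarray(dist, float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[_Node] = [_Node(label=lab) for lab in labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (row_sums[i_loc] - row_sums[j_loc]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        idx_new = d.shape[0] - 1
        for loc, a in enumerate(active):
            d[idx_new, a] = d[a, idx_new] = new_d[loc]
        d[idx_new, idx_new] = 0.0
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [idx_new]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    # clamp negatives pairwise against the longest sibling
    lengths = np.array([la, lb, lc])
    for idx in range(3):
        if lengths[idx] < 0:
            donor = int(np.argmax(lengths))
            lengths[donor] += lengths[idx]
            lengths[idx] = 0.0
    la, lb, lc = (max(v, 0.0) for v in lengths)
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return root.newick() + ";"
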