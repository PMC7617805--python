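"""Neighbor-joining agglomeration (Saitou-Nei) on a distance matrix.

Kept free of tree-container dependencies so both the progressive
aligner's guide tree and the phylogeny module can share it. Ties in the
Q criterion are broken on the lexicographically smallest (label_i,
label_j) pair, where a cluster's label is the smallest leaf name it
contains; negative branch lengths are clamped to zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class NJNode:
    name: str | None = None
    children: list[tuple["NJNode", float]] = field(default_factory=list)

    def leaf_names(self) -> list[str]:
        if self.name is not None and not self.children:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


def nj_tree(names: list[str], dist: np.ndarray) -> NJNode:
    """Unrooted NJ tree; the returned root is the final 3-way join."""
    n = len(names)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    if len(set(names)) != n:
        raise ValidationError("taxon names must be unique")
    D = np.asarray(dist, dtype=np.float64).copy()
    if D.shape != (n, n):
        raise ValidationError("distance matrix shape does not match names")

    nodes = [NJNode(name=nm) for nm in names]
    labels = list(names)  # smallest leaf name per active cluster
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple | None = None
        for ai in range(k):
            for aj in range(ai + 1, k):
                q = (k - 2) * sub[ai, aj] - r[ai] - r[aj]
                li, lj = labels[active[ai]], labels[active[aj]]
                key = (q, min(li, lj), max(li, lj))
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = NJNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        new = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            d = 0.5 * (D[i, a] + D[j, a] - dij)
            D[new, a] = D[a, new] = max(d, 0.0)
        active = [a for a in active if a not in (i, j)] + [new]

    a, b, c = sorted(active, key=lambda x: labels[x])
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    return NJNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
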