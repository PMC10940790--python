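"""Allele-frequency distance matrices and neighbour-joining trees.

The distance between two pools is the mean absolute allele-frequency
difference over SNPs with data in both (pairwise-complete), bounded in
[0, 1].  The tree is built by Saitou-Nei neighbour joining with the
standard Q-criterion; ties are broken deterministically by taxon-name
order, and a negative branch length is clamped to zero with the deficit
moved to its sibling edge so path lengths are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .poolfreq import AlleleFrequencyMatrix


@dataclass
class DafDistanceMatrix:
    """Symmetric pools x pools mean-|dAF| matrix with per-pair SNP counts."""

    values: np.ndarray
    n_snps: np.ndarray
    pool_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.pool_ids, columns=self.pool_ids
        )

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.pool_ids), dtype=bool)
        return bool(np.isnan(self.values[off]).any())


def daf_distance(freqs: AlleleFrequencyMatrix) -> DafDistanceMatrix:
    """Pairwise-complete mean absolute frequency difference between pools."""
    if freqs.n_pools < 2:
        raise ValueError("need >= 2 pools")
    F = freqs.freq
    n = freqs.n_pools
    values = np.zeros((n, n))
    n_snps = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(F[:, i]) | np.isnan(F[:, j]))
            m = int(ok.sum())
            n_snps[i, j] = n_snps[j, i] = m
            if m == 0:
                warnings.warn(
                    f"pools {freqs.pool_ids[i]} / {freqs.pool_ids[j]} share "
                    "no SNPs; distance missing"
                )
                values[i, j] = values[j, i] = np.nan
                continue
            d = float(np.abs(F[ok, i] - F[ok, j]).mean())
            values[i, j] = values[j, i] = d
    return DafDistanceMatrix(values=values, n_snps=n_snps,
                             pool_ids=freqs.pool_ids)


@dataclass
class TreeNode:
    """A rooted representation of the (unrooted) NJ tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(
            f"{c._newick()}:{bl:.10g}" for c, bl in self.children
        )
        return f"({inner})"

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out

    def path_lengths(self) -> pd.DataFrame:
        """Pairwise leaf-to-leaf path lengths through the tree."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node, acc):
            if node.is_leaf:
                return [(node.name, acc)]
            out = []
            for c, bl in node.children:
                out.extend(walk(c, acc + bl))
            return out

        def collect(node):
            # distances between leaves in different child subtrees
            groups = [walk(c, bl) for c, bl in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi]:
                        for b, db in groups[gj]:
                            dists.setdefault(a, {})[b] = da + db
                            dists.setdefault(b, {})[a] = da + db
            for c, _ in node.children:
                collect(c)

        collect(self)
        names = sorted(self.leaf_names())
        mat = pd.DataFrame(0.0, index=names, columns=names)
        for a in names:
            for b in names:
                if a != b:
                    mat.loc[a, b] = dists[a][b]
        return mat


def _clamp_pair(di: float, dj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to the sibling."""
    if di < 0:
        dj += di
        di = 0.0
    if dj < 0:
        di += dj
        dj = 0.0
    return max(di, 0.0), max(dj, 0.0)


def nj_tree(dist) -> TreeNode:
    """Saitou-Nei neighbour joining on a complete distance matrix.

    *dist* is a :class:`DafDistanceMatrix` or a labelled square DataFrame.
    Returns the tree rooted at the final (trifurcating) join; use
    :meth:`TreeNode.newick` for serialisation.
    """
    if isinstance(dist, DafDistanceMatrix):
        if dist.has_missing:
            raise ValueError(
                "distance matrix has missing entries; impute or subset first"
            )
        D = dist.values.astype(float).copy()
        names = list(dist.pool_ids)
    else:
        df = pd.DataFrame(dist)
        D = df.to_numpy(dtype=float).copy()
        names = [str(c) for c in df.columns]
    n = len(names)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries")

    nodes = [TreeNode(name=nm) for nm in names]
    # sort key of an active node = smallest leaf name in its subtree
    keys = list(names)

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            tuple(sorted((keys[i], keys[j]))) + (i, j)
            for i, j in zip(*np.nonzero(np.isclose(Q, qmin)))
            if i < j
        ]
        _, _, i, j = min(cands)
        dij = D[i, j]
        di = dij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        dj = dij - di
        di, dj = _clamp_pair(di, dj)
        parent = TreeNode(children=[(nodes[i], di), (nodes[j], dj)])
        d_new = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D_next = np.zeros((r - 1, r - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D = D_next
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final trifurcation via the three-point formulas
    (a, b, c) = range(3)
    da = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    db = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    dc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    da, db, dc = (max(x, 0.0) for x in (da, db, dc))
    order = np.argsort([keys[a], keys[b], keys[c]], kind="stable")
    kids = [(nodes[k], [da, db, dc][k]) for k in order]
    return TreeNode(children=kids)


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")
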