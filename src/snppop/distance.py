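"""Allele-sharing distance between individuals and neighbor-joining trees.

The pairwise similarity is the mean proportion of alleles identical by
state, ``Dst = (IBS2 + 0.5 IBS1) / N`` over the ``N`` loci called in both
individuals; genetic distance is ``1 - Dst``.  Trees are built with the
Saitou–Nei neighbor-joining algorithm and emitted as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError


@dataclass(frozen=True)
class IbsCounts:
    ibs2: int
    ibs1: int
    ibs0: int

    @property
    def n(self) -> int:
        return self.ibs0 + self.ibs1 + self.ibs2

    @property
    def dst(self) -> float:
        if self.n == 0:
            raise PanelError("zero overlapping called loci")
        return (self.ibs2 + 0.5 * self.ibs1) / self.n


def ibs_distance(
    panel: GenotypePanel, sample_a: int | str, sample_b: int | str
) -> tuple[IbsCounts, float]:
    """IBS sharing counts and distance D = 1 - Dst for one sample pair.

    Loci missing in either sample are excluded from N.
    """

    def row(s: int | str) -> np.ndarray:
        if isinstance(s, str):
            try:
                s = panel.samples.index(s)
            except ValueError:
                raise PanelError(f"unknown sample {s!r}")
        return panel.dosages[int(s)]

    a, b = row(sample_a), row(sample_b)
    both = (a != MISSING) & (b != MISSING)
    if not both.any():
        raise PanelError("zero overlapping called loci")
    diff = np.abs(a[both].astype(np.int16) - b[both])
    counts = IbsCounts(
        ibs2=int((diff == 0).sum()),
        ibs1=int((diff == 1).sum()),
        ibs0=int((diff == 2).sum()),
    )
    return counts, 1.0 - counts.dst


def distance_matrix(panel: GenotypePanel) -> pd.DataFrame:
    """Symmetric matrix of 1 - Dst over all sample pairs (pairwise-complete).

    Uses the identity ``1 - Dst = sum |g_a - g_b| / (2 N)`` to vectorize.
    """
    if panel.n_samples < 2:
        raise PanelError("need >= 2 samples for a distance matrix")
    d = panel.dosages.astype(np.float64)
    d[panel.dosages == MISSING] = np.nan
    n = panel.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[i] - d[i:])
        overlap = np.sum(~np.isnan(diff), axis=1)
        if np.any(overlap == 0):
            j = i + int(np.argmax(overlap == 0))
            raise PanelError(
                f"zero overlapping called loci for pair "
                f"({panel.samples[i]}, {panel.samples[j]})"
            )
        out[i, i:] = np.nansum(diff, axis=1) / (2.0 * overlap)
    out = out + out.T
    return pd.DataFrame(out, index=panel.samples, columns=panel.samples)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Minimal unrooted tree node: leaf label or children with branch lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = None  # (child, branch length)

    def __post_init__(self) -> None:
        if self.children is None:
            self.children = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.label or ""
        parts = [
            f"{child._newick_inner()}:{length:.10g}"
            for child, length in self.children
        ]
        return "(" + ",".join(parts) + ")"


def neighbor_joining(dist: pd.DataFrame | np.ndarray, labels=None) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    At each step the pair minimizing the Q-criterion
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` is joined; ties
    are broken by the label-sorted pair for determinism.  Negative branch
    lengths are clamped to 0 with the deficit moved to the sister branch.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        mat = dist.to_numpy(dtype=float)
    else:
        mat = np.asarray(dist, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(mat))]
    n = len(labels)
    if mat.shape != (n, n):
        raise PanelError("distance matrix shape mismatch")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise PanelError("distance matrix not symmetric")
    if np.any(mat < -1e-12):
        raise PanelError("negative distances")
    if n < 2:
        raise PanelError("need >= 2 taxa")

    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    names: list[str] = list(labels)
    D = mat.copy()

    while len(nodes) > 2:
        k = len(nodes)
        row_sum = D.sum(axis=1)
        q = (k - 2) * D - row_sum[:, None] - row_sum[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        ties = [(i, j) for i, j in ties if i < j]
        i, j = min(ties, key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))))

        li = 0.5 * D[i, j] + (row_sum[i] - row_sum[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        # clamp negatives, transferring the deficit to the sister branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)

        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (D[i] + D[j] - D[i, j])

        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], new_d[keep][None, :]])
        D = np.hstack([D, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
        names = [names[x] for x in keep] + [f"({names[i]},{names[j]})"]

    if len(nodes) == 2:
        d = max(D[0, 1], 0.0)
        a, b = nodes
        if b.is_leaf and not a.is_leaf:
            # attach the remaining leaf onto the internal node -> unrooted tree
            a.children.append((b, d))
            return a
        if a.is_leaf and not b.is_leaf:
            b.children.append((a, d))
            return b
        return TreeNode(children=[(a, d / 2.0), (b, d / 2.0)])
    return nodes[0]


def nj_newick(dist: pd.DataFrame | np.ndarray, labels=None) -> str:
    """Convenience: NJ tree as a Newick string."""
    return neighbor_joining(dist, labels).newick()
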