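"""Distance-based phylogeny and clade typing.

A Kimura-corrected p-distance matrix over an aligned protein set is fed to
classical neighbor joining (Saitou-Nei). Clade types are then assigned
against reference "anchor" proteins of known type: after midpoint rooting,
each anchor type defines the smallest clade containing all of its anchors;
family members inside exactly one anchor clade inherit its type, members
inside nested clades take the smallest, and members outside every anchor
clade form the anchor-free type I.

NJ is exact on additive distance matrices: it recovers the generating
topology and branch lengths.
"""

from __future__ import annotations

import io as _io
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass(frozen=True)
class TypedMember:
    gene_id: str
    type_label: str


def distance_matrix(msa: Mapping[str, str]) -> DistanceMatrix:
    """Kimura-corrected p-distances, d = -ln(1 - p - 0.2 p^2), over columns
    where neither sequence has a gap."""
    taxa = tuple(msa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    arr = np.array([list(msa[t]) for t in taxa])
    gaps = np.isin(arr, list(GAP_CHARS))
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~gaps[i] & ~gaps[j]
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(f"no comparable columns between {taxa[i]} and {taxa[j]}")
            p = float((arr[i][comparable] != arr[j][comparable]).sum()) / total
            arg = 1.0 - p - 0.2 * p * p
            if arg <= 0:
                raise ValueError(
                    f"p-distance {p:.3f} between {taxa[i]} and {taxa[j]} exceeds "
                    "the Kimura correction's domain"
                )
            d[i, j] = d[j, i] = -np.log(arg)
    return DistanceMatrix(taxa, d)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Classical NJ; returns an unrooted tree in Newick format.

    Ties in the Q-matrix break toward the smallest (i, j) index pair, making
    the output deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # active nodes: newick fragment per node
    labels = list(dm.taxa)
    d = dm.d.astype(float).copy()
    active = list(range(n))
    frags = {i: labels[i] for i in active}

    def fmt(x: float) -> str:
        return f"{x:.17g}"

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        frags[new] = f"({frags[i]}:{fmt(li)},{frags[j]}:{fmt(lj)})"
        active = [k for k in active if k not in (i, j)] + [new]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return f"({frags[a]}:{fmt(la)},{frags[b]}:{fmt(lb)},{frags[c]}:{fmt(lc)});"


def _read_tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick), convert_underscores=False)


def tree_tip_distances(newick: str) -> DistanceMatrix:
    """Patristic (path-length) distances between all tips of a Newick tree."""
    tree = _read_tree(newick)
    skdm = tree.tip_tip_distances()
    taxa = tuple(str(t) for t in skdm.ids)
    return DistanceMatrix(taxa, np.asarray(skdm.data))


def assign_clade_types(
    newick: str,
    anchors: Mapping[str, str],
    free_type: str = "I",
) -> list[TypedMember]:
    """Type every non-anchor tip of the tree.

    ``anchors`` maps anchor tip name -> type label. The tree is midpoint
    rooted; each anchor type claims the smallest clade spanning all of its
    anchors; members take the type of the smallest enclosing anchor clade,
    or ``free_type`` if no clade contains them.
    """
    if not anchors:
        raise ValueError("need at least one anchor type")
    tree = _read_tree(newick).root_at_midpoint()
    tip_names = {t.name for t in tree.tips()}
    missing = set(anchors) - tip_names
    if missing:
        raise ValueError(f"anchors missing from tree: {sorted(missing)}")
    by_type: dict[str, list[str]] = {}
    for a, t in anchors.items():
        by_type.setdefault(t, []).append(a)
    clade_tips: dict[str, frozenset[str]] = {}
    for t, names in by_type.items():
        node = tree.lca(names) if len(names) > 1 else tree.find(names[0])
        clade_tips[t] = frozenset(x.name for x in node.tips()) or frozenset({node.name})
    out = []
    for tip in tree.tips():
        if tip.name in anchors:
            continue
        enclosing = [t for t, tips in clade_tips.items() if tip.name in tips]
        if not enclosing:
            label = free_type
        else:
            label = min(enclosing, key=lambda t: (len(clade_tips[t]), t))
        out.append(TypedMember(gene_id=tip.name, type_label=label))
    out.sort(key=lambda m: m.gene_id)
    return out
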