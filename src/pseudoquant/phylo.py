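"""Distance-based phylogeny of a paralog family with bootstrap support.

Distances are p-distance (mismatches per comparable site) or the
Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); gap-containing columns are
dropped per pair (pairwise deletion). Trees are built by Saitou-Nei
neighbor joining with a deterministic tie rule — when several pairs
minimize the Q criterion, the lexicographically smallest pair of cluster
labels is joined — and negative branch lengths are clamped to zero with a
warning. Bootstrap support resamples alignment columns with replacement
and counts, per internal bipartition of the full-data tree, the percentage
of replicate trees containing it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class TreeNode:
    """Node of an (unrooted, stored rooted-at-center) phylogenetic tree."""

    name: str = ""
    length: float = 0.0  # branch length to parent, substitutions/site
    support: Optional[float] = None  # percent, internal nodes only
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"

    def bipartitions(self) -> List[frozenset]:
        """Leaf sets under each internal edge (non-trivial splits only)."""
        all_leaves = self.leaf_names()
        out = []

        def walk(node):
            for c in node.children:
                side = c.leaf_names()
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.append(min(side, all_leaves - side, key=sorted))
                walk(c)

        walk(self)
        return out


@dataclass
class DistanceMatrix:
    """Symmetric taxon-by-taxon distance matrix (substitutions per site)."""

    taxa: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[ia, ib])


def pairwise_distance(seq_a: str, seq_b: str, model: str = "p") -> float:
    """Evolutionary distance between two aligned sequences.

    Columns where either sequence has a gap are excluded. ``p`` is the raw
    mismatch fraction; ``jc69`` applies the Jukes-Cantor correction (error
    for p >= 0.75, where the correction diverges).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a != b:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    p = mismatches / comparable
    if model == "p":
        return p
    if model == "jc69":
        if p >= 0.75:
            raise ValueError(f"distance undefined under jc69 for p = {p:.3f} >= 0.75")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(
    alignment: Dict[str, str], model: str = "p"
) -> DistanceMatrix:
    """All-pairs distances of an aligned set of sequences."""
    taxa = tuple(alignment.keys())
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(alignment[taxa[i]], alignment[taxa[j]], model)
    return DistanceMatrix(taxa, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Returns the unrooted tree rooted at the final central (trifurcating)
    node. Ties in the Q criterion break on the lexicographically smallest
    pair of cluster labels; negative limb lengths clamp to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: Dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    # cluster label = lexicographically smallest member leaf (deterministic)
    labels = list(dm.taxa)
    d = {
        frozenset((a, b)): dm.get(a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }

    def dist(a, b):
        return d[frozenset((a, b))]

    clamped = False
    while len(labels) > 3:
        N = len(labels)
        r = {a: sum(dist(a, b) for b in labels if b != a) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (N - 2) * dist(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
        _, a, b = best[0], best[1], best[2]
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (N - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        parent.children = [na, nb]
        new_label = min(a, b)
        for c in labels:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[frozenset((new_label, c))] = max(duc, 0.0)
        labels = sorted(set(labels) - {a, b} | {new_label})
        nodes[new_label] = parent
    a, b, c = sorted(labels)
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    if min(la, lb, lc) < 0:
        clamped = True
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    if clamped:
        warnings.warn("negative neighbor-joining branch lengths clamped to zero")
    center = TreeNode()
    for label, length in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(label)
        node.length = length
        center.children.append(node)
    return center


def bootstrap_support(
    alignment: Dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "p",
) -> TreeNode:
    """NJ tree from the full alignment with column-resampling supports.

    Support = percentage of replicate trees containing each internal
    bipartition of the full-data tree. Fully reproducible given *seed*.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    taxa = list(alignment.keys())
    cols = len(next(iter(alignment.values())))
    if cols < 1:
        raise ValueError("empty alignment")
    arr = np.array([list(alignment[t]) for t in taxa])
    main = nj_tree(distance_matrix(alignment, model))
    counts: Dict[frozenset, int] = {bp: 0 for bp in main.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, cols, size=cols)
        rep_aln = {t: "".join(arr[i, idx]) for i, t in enumerate(taxa)}
        try:
            rep = nj_tree(distance_matrix(rep_aln, model))
        except ValueError:  # e.g. jc69 divergence on a bad resample
            continue
        rep_bps = set(rep.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    def annotate(node):
        for child in node.children:
            if not child.is_leaf:
                side = child.leaf_names()
                key = min(side, frozenset(alignment) - side, key=sorted)
                if key in counts:
                    child.support = 100.0 * counts[key] / n_replicates
            annotate(child)

    annotate(main)
    return main
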