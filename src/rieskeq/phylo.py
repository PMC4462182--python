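"""Pairwise evolutionary distances, neighbour-joining trees and clade
phylogenetic-diversity (PD) scoring.

The distance models are the closed forms a practitioner would use on a
nucleotide alignment of a gene family:

* ``p``        observed proportion of differing sites,
* ``jc69``     Jukes-Cantor correction, ``-(3/4) ln(1 - 4p/3)``,
* ``tn93``     Tamura-Nei correction with base frequencies pooled over
               the whole alignment (composite estimation) and per-pair
               transition/transversion proportions.

Sites where either sequence carries a gap or an ambiguity code are
excluded pairwise (pairwise deletion).  Saturated pairs, where a
logarithm argument is non-positive, are flagged; :func:`distance_matrix`
replaces them with a configurable ceiling so neighbour joining remains
runnable, and reports the affected pairs.

Clade PD is the mean (and max) pairwise distance among clade members;
a clade is considered primer-design eligible when its mean PD is below
a coherence threshold (default 0.29 substitutions/site).
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .seqcore import Alignment, normalize

DEFAULT_SATURATION_CEILING = 5.0
DEFAULT_PD_THRESHOLD = 0.29

_MODELS = ("p", "jc69", "tn93")

# nucleotide -> small integer; anything else (gap/ambiguity) -> 255
_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturationWarning(UserWarning):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise evolutionary distances."""

    labels: list[str]
    d: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], d=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _encode_codes(seqs: Sequence[str]) -> np.ndarray:
    mat = np.full((len(seqs), len(seqs[0])), 255, dtype=np.uint8)
    for i, s in enumerate(seqs):
        for j, ch in enumerate(s):
            mat[i, j] = _NT_CODE.get(ch, 255)
    return mat


def _pooled_freqs(codes: np.ndarray) -> np.ndarray:
    counts = np.array([(codes == k).sum() for k in range(4)], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous nucleotides in alignment")
    return counts / total


def _pair_proportions(x: np.ndarray, y: np.ndarray) -> tuple[int, float, float, float]:
    """Comparable-site count and (P1, P2, Q) difference proportions.

    P1 = A<->G transitions, P2 = C<->T transitions, Q = transversions.
    """
    ok = (x != 255) & (y != 255)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("zero comparable sites between sequences")
    xs, ys = x[ok], y[ok]
    diff = xs != ys
    ts1 = diff & (((xs == 0) & (ys == 2)) | ((xs == 2) & (ys == 0)))
    ts2 = diff & (((xs == 1) & (ys == 3)) | ((xs == 3) & (ys == 1)))
    p1 = ts1.sum() / n
    p2 = ts2.sum() / n
    q = (diff.sum() - ts1.sum() - ts2.sum()) / n
    return n, float(p1), float(p2), float(q)


def _jc69(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


def _tn93(p1: float, p2: float, q: float, freqs: np.ndarray) -> float:
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    if pr <= 0 or py <= 0 or pa * pg == 0 or pc * pt == 0:
        raise ValueError(
            "degenerate base composition: TN93 requires all four nucleotides"
        )
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pc * pt / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
    w1 = 1.0 - p1 / k1 - q / (2.0 * pr)
    w2 = 1.0 - p2 / k2 - q / (2.0 * py)
    w3 = 1.0 - q / (2.0 * pr * py)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def pairwise_distance(
    a: str,
    b: str,
    model: str = "tn93",
    freqs: np.ndarray | None = None,
) -> float:
    """Evolutionary distance between two aligned sequences.

    Gap/ambiguity sites are excluded pairwise.  Returns ``nan`` for
    saturated pairs (logarithm argument <= 0); the caller decides how to
    treat them (see :func:`distance_matrix`).  For ``tn93``, *freqs* are
    the pooled base frequencies; when omitted they are estimated from
    the two sequences themselves.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
    sa = normalize(a, allow_gaps=True)
    sb = normalize(b, allow_gaps=True)
    if len(sa) != len(sb):
        raise ValueError("sequences must be aligned to equal length")
    codes = _encode_codes([sa, sb])
    n, p1, p2, q = _pair_proportions(codes[0], codes[1])
    p = p1 + p2 + q
    if model == "p":
        return p
    if model == "jc69":
        return _jc69(p)
    if freqs is None:
        freqs = _pooled_freqs(codes)
    return _tn93(p1, p2, q, np.asarray(freqs, dtype=float))


def distance_matrix(
    aln: Alignment,
    model: str = "tn93",
    saturation_ceiling: float | None = DEFAULT_SATURATION_CEILING,
) -> DistanceMatrix:
    """All pairwise distances for an alignment.

    Saturated (undefined) pairs are set to *saturation_ceiling* with a
    warning and listed in ``undefined_pairs``; pass ``None`` to keep the
    ``nan`` instead.
    """
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    codes = _encode_codes([r.seq for r in aln.records])
    freqs = _pooled_freqs(codes) if model == "tn93" else None
    n = len(aln)
    d = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            _, p1, p2, q = _pair_proportions(codes[i], codes[j])
            if model == "p":
                dist = p1 + p2 + q
            elif model == "jc69":
                dist = _jc69(p1 + p2 + q)
            else:
                dist = _tn93(p1, p2, q, freqs)
            if math.isnan(dist):
                undefined.append((aln.records[i].id, aln.records[j].id))
                if saturation_ceiling is not None:
                    dist = saturation_ceiling
            d[i, j] = d[j, i] = dist
    if undefined and saturation_ceiling is not None:
        warnings.warn(
            f"{len(undefined)} saturated pair(s) set to ceiling {saturation_ceiling}",
            SaturationWarning,
            stacklevel=2,
        )
    return DistanceMatrix(labels=aln.ids, d=d, undefined_pairs=undefined)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


@dataclass
class Tree:
    """Unrooted tree stored rooted at a (usually trifurcating) node."""

    root: TreeNode
    meta: dict = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def edge_map(self) -> dict:
        """Map every edge to its branch length (and support).

        Leaf edges are keyed by the leaf name; internal edges by the
        canonical bipartition ``frozenset({side, complement})`` of leaf
        names.  This representation is invariant to the rooting choice,
        so two representations of the same unrooted tree compare equal.
        """
        all_leaves = frozenset(self.leaf_names())
        edges: dict = {}

        def visit(node: TreeNode) -> frozenset:
            if node.is_leaf:
                side = frozenset([node.name])
                edges[node.name] = (node.length, node.support)
                return side
            side = frozenset().union(*(visit(ch) for ch in node.children))
            if node is not self.root:
                key = frozenset({side, all_leaves - side})
                edges[key] = (node.length, node.support)
            return side

        visit(self.root)
        return edges

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions (internal edges) of the unrooted tree."""
        return {k for k in self.edge_map() if isinstance(k, frozenset)}

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(ch) for ch in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                label = f"({inner}){sup}"
            if node.length is not None:
                label += f":{node.length:.10g}"
            return label

        return fmt(self.root) + ";"


def write_newick(tree: Tree, path: str | Path) -> None:
    """Write Newick with branch lengths and bootstrap supports as
    internal-node labels; :func:`read_newick` reproduces the tree."""
    Path(path).write_text(tree.to_newick() + "\n")


def _from_dendropy(node: "dendropy.Node") -> TreeNode:
    if node.is_leaf():
        name = node.taxon.label if node.taxon else node.label
        return TreeNode(name=name, length=node.edge.length)
    support = None
    if node.label is not None:
        try:
            support = float(node.label)
        except ValueError:
            support = None
    return TreeNode(
        name=None,
        length=node.edge.length,
        support=support,
        children=[_from_dendropy(ch) for ch in node.child_nodes()],
    )


def read_newick(source: str | Path) -> Tree:
    """Read a Newick tree (file path or literal string)."""
    text = str(source)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    dt = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root = _from_dendropy(dt.seed_node)
    root.length = None
    return Tree(root=root)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining.

    For an additive (tree-metric) input the output reproduces the
    generating tree's topology and branch lengths exactly.  Negative
    branch-length estimates are clamped to zero; the total clamped
    deficit is recorded in ``tree.meta["clamped_deficit"]``.  Ties in
    the Q criterion are broken lexicographically by index, so the
    output is deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.d
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0.0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)  # row-major argmin -> lexicographic ties
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        nodes[ai].length = clamp(li)
        nodes[aj].length = clamp(lj)
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        new = len(nodes)
        nodes.append(parent)
        rest = [k for k in active if k not in (ai, aj)]
        for k in rest:
            duk = 0.5 * (D[ai, k] + D[aj, k] - dij)
            D[new, k] = D[k, new] = duk
        active = rest + [new]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nodes[a].length = clamp(la)
    nodes[b].length = clamp(lb)
    nodes[c].length = clamp(lc)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, meta={"clamped_deficit": deficit})


def tree_to_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""

    def collect(node: TreeNode, acc: dict) -> dict:
        # returns {leaf_name: distance to `node`}, filling `acc` with
        # cross-pair distances on the way up
        if node.is_leaf:
            return {node.name: 0.0}
        per_child = []
        for ch in node.children:
            dists = collect(ch, acc)
            blen = ch.length or 0.0
            per_child.append({k: v + blen for k, v in dists.items()})
        for d1, d2 in itertools.combinations(per_child, 2):
            for n1, v1 in d1.items():
                for n2, v2 in d2.items():
                    acc[frozenset((n1, n2))] = v1 + v2
        merged: dict = {}
        for d in per_child:
            merged.update(d)
        return merged

    acc: dict = {}
    collect(tree.root, acc)
    labels = sorted(tree.leaf_names())
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = acc[frozenset((labels[i], labels[j]))]
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_supports(
    aln: Alignment,
    model: str = "tn93",
    n_replicates: int = 2000,
    seed: int = 0,
    saturation_ceiling: float | None = DEFAULT_SATURATION_CEILING,
) -> Tree:
    """Bootstrap supports for the NJ tree of an alignment.

    Alignment columns are resampled with replacement per replicate,
    distances and NJ recomputed, and the support of each internal edge
    of the reference tree is the percentage of replicates containing
    the same bipartition.  Replicates in which any pairwise distance is
    undefined (saturated) are dropped; the effective replicate count is
    recorded in ``tree.meta["n_effective_replicates"]``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ref_dm = distance_matrix(aln, model=model, saturation_ceiling=saturation_ceiling)
    ref_tree = neighbor_joining(ref_dm)
    ref_biparts = ref_tree.bipartitions()
    counts = {bp: 0 for bp in ref_biparts}

    rng = np.random.default_rng(seed)
    chars = aln.char_matrix()
    ncol = aln.ncol
    n_eff = 0
    n_dropped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SaturationWarning)
        for _ in range(n_replicates):
            cols = rng.integers(0, ncol, size=ncol)
            res = chars[:, cols]
            rep_aln = Alignment(
                [
                    type(rec)(id=rec.id, seq="".join(row), clade=rec.clade)
                    for rec, row in zip(aln.records, res)
                ]
            )
            rep_dm = distance_matrix(
                rep_aln, model=model, saturation_ceiling=saturation_ceiling
            )
            if rep_dm.undefined_pairs:
                n_dropped += 1
                continue
            n_eff += 1
            rep_biparts = neighbor_joining(rep_dm).bipartitions()
            for bp in ref_biparts & rep_biparts:
                counts[bp] += 1

    supports = {
        bp: (100.0 * c / n_eff if n_eff else 0.0) for bp, c in counts.items()
    }

    all_leaves = frozenset(ref_tree.leaf_names())

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        side = frozenset().union(*(annotate(ch) for ch in node.children))
        if node is not ref_tree.root:
            node.support = supports.get(frozenset({side, all_leaves - side}))
        return side

    annotate(ref_tree.root)
    ref_tree.meta["n_effective_replicates"] = n_eff
    ref_tree.meta["n_dropped_replicates"] = n_dropped
    return ref_tree


# ---------------------------------------------------------------------------
# Clade PD
# ---------------------------------------------------------------------------


@dataclass
class CladeReport:
    clade: str
    members: list[str]
    pd_mean: float
    pd_max: float
    eligible: bool
    threshold: float = DEFAULT_PD_THRESHOLD


def clade_pd(
    dm: DistanceMatrix,
    members: Iterable[str],
    clade: str = "",
    threshold: float = DEFAULT_PD_THRESHOLD,
) -> CladeReport:
    """Phylogenetic diversity of a clade: mean and max pairwise distance.

    Eligibility for primer design uses the mean (``pd_mean < threshold``);
    a singleton clade has PD 0 and is trivially eligible.
    """
    members = list(members)
    unknown = sorted(set(members) - set(dm.labels))
    if unknown:
        raise KeyError(f"unknown member id(s): {unknown}")
    if not members:
        raise ValueError("clade must have at least one member")
    idx = [dm.labels.index(m) for m in members]
    if len(idx) == 1:
        mean = mx = 0.0
    else:
        pairs = [dm.d[i, j] for i, j in itertools.combinations(idx, 2)]
        mean = float(np.mean(pairs))
        mx = float(np.max(pairs))
    return CladeReport(
        clade=clade,
        members=members,
        pd_mean=mean,
        pd_max=mx,
        eligible=mean < threshold,
        threshold=threshold,
    )


def read_clade_table(path: str | Path) -> dict[str, list[str]]:
    """Read a clade table TSV (columns ``clade, member_id``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"clade", "member_id"} <= set(df.columns):
        raise ValueError(f"clade table {path}: need columns clade, member_id")
    out: dict[str, list[str]] = {}
    for clade, grp in df.groupby("clade", sort=True):
        out[str(clade)] = list(grp["member_id"])
    return out


def write_clade_table(clades: dict[str, list[str]], path: str | Path) -> None:
    rows = [
        {"clade": clade, "member_id": member}
        for clade in sorted(clades)
        for member in clades[clade]
    ]
    pd.DataFrame(rows, columns=["clade", "member_id"]).to_csv(
        path, sep="\t", index=False
    )
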