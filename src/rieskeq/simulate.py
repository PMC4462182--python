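"""Seed-deterministic synthetic data for every pipeline stage.

``simulate_clades`` emulates the statistical structure of a curated
gene-family library: tight clades (low within-clade divergence) that are
mutually distant, the regime in which clade-specific primer design is
feasible.  Sequences evolve under a uniform (Jukes-Cantor-like)
substitution process from a common root, through clade ancestors, to
clade members.  Short "pinned" blocks are exempt from within-clade
mutation, emulating the functionally constrained motifs (such as the
Rieske-centre coding region) that real primer design exploits; the
blocks still diverge *between* clades, so they carry clade identity.

The qPCR generators draw Ct values and spike measurements directly from
the linear models the analysis modules fit, plus Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import Tree, TreeNode, write_newick
from .seqcore import Alignment, SequenceRecord, write_fasta
from .phylo import write_clade_table

_NTS = np.array(list("ACGT"))


def _jc_p_different(t: float) -> float:
    """Expected proportion of differing sites after branch length *t*
    substitutions/site under a uniform substitution process."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _evolve(
    seq: np.ndarray, t: float, rng: np.random.Generator, mask: np.ndarray | None = None
) -> np.ndarray:
    """Mutate a sequence along a branch of length *t*; sites where *mask*
    is True are frozen."""
    p = _jc_p_different(t)
    hit = rng.random(len(seq)) < p
    if mask is not None:
        hit &= ~mask
    out = seq.copy()
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


@dataclass(frozen=True)
class CladeSimSpec:
    """Design of a synthetic clade-structured library.

    Divergence targets are expected substitutions/site between two
    members of the same clade (*within*) and between members of
    different clades (*between*).  ``pin_blocks`` are (1-based start,
    length) windows frozen during within-clade evolution; their root
    composition is drawn at ``pin_gc`` GC content so that designable
    windows have primer-like melting temperatures.
    """

    n_clades: int = 10
    members_per_clade: int = 5
    length: int = 1400
    within: float = 0.10
    between: float = 0.90
    seed: int = 0
    pin_blocks: tuple[tuple[int, int], ...] = ((200, 24), (400, 24))
    pin_gc: float = 0.60

    def __post_init__(self) -> None:
        if self.n_clades < 1 or self.members_per_clade < 1:
            raise ValueError("need at least one clade and one member")
        if not 0 <= self.within < self.between:
            raise ValueError("require 0 <= within < between divergence")
        if self.between > 3.0:
            raise ValueError(
                "infeasible divergence: pairwise differences would be saturated"
            )
        if self.pin_blocks and self.length < 200:
            raise ValueError("primer-design fixtures need length >= 200")
        for start, blen in self.pin_blocks:
            if start < 1 or start + blen - 1 > self.length:
                raise ValueError(f"pin block ({start}, {blen}) outside sequence")


@dataclass
class SimulatedLibrary:
    records: list[SequenceRecord]
    clades: dict[str, list[str]]
    tree: Tree
    spec: CladeSimSpec

    def alignment(self, clade: str | None = None) -> Alignment:
        if clade is None:
            return Alignment(self.records)
        members = set(self.clades[clade])
        return Alignment([r for r in self.records if r.id in members])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "library.fasta",
            "clades": outdir / "clades.tsv",
            "tree": outdir / "truth.nwk",
        }
        write_fasta(self.records, paths["fasta"])
        write_clade_table(self.clades, paths["clades"])
        write_newick(self.tree, paths["tree"])
        return paths


def simulate_clades(spec: CladeSimSpec) -> SimulatedLibrary:
    """Generate a clade-labelled library plus its generating tree.

    Clade ancestors sit at ``between/2`` substitutions/site from a
    common root, members at ``within/2`` from their ancestor, so the
    expected pairwise divergences hit the spec targets.  Deterministic
    in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    root = _NTS[rng.integers(0, 4, size=spec.length)]
    pin_mask = np.zeros(spec.length, dtype=bool)
    for start, blen in spec.pin_blocks:
        pin_mask[start - 1 : start - 1 + blen] = True
    # primer-like composition inside the pinned blocks
    n_pin = int(pin_mask.sum())
    if n_pin:
        gc = rng.random(n_pin) < spec.pin_gc
        half = rng.random(n_pin) < 0.5
        block = np.where(gc, np.where(half, "G", "C"), np.where(half, "A", "T"))
        root[pin_mask] = block

    records: list[SequenceRecord] = []
    clades: dict[str, list[str]] = {}
    clade_nodes: list[TreeNode] = []
    for ci in range(spec.n_clades):
        clade = f"clade{ci + 1:02d}"
        ancestor = _evolve(root, spec.between / 2.0, rng)
        member_nodes: list[TreeNode] = []
        clades[clade] = []
        for mi in range(spec.members_per_clade):
            sid = f"{clade}_seq{mi + 1}"
            member = _evolve(ancestor, spec.within / 2.0, rng, mask=pin_mask)
            records.append(
                SequenceRecord(id=sid, seq="".join(member), clade=clade)
            )
            clades[clade].append(sid)
            member_nodes.append(TreeNode(name=sid, length=spec.within / 2.0))
        clade_nodes.append(
            TreeNode(length=spec.between / 2.0, children=member_nodes)
        )
    tree = Tree(root=TreeNode(children=clade_nodes))
    return SimulatedLibrary(records=records, clades=clades, tree=tree, spec=spec)


# ---------------------------------------------------------------------------
# Random trees (oracle surface for neighbour joining)
# ---------------------------------------------------------------------------


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    blen_range: tuple[float, float] = (0.05, 0.5),
) -> Tree:
    """Random unrooted binary tree with positive branch lengths.

    Built by repeatedly subdividing a random edge and attaching a new
    leaf; the root keeps degree 3, so the representation matches NJ
    output.  Edge subdivision keeps both parts at >= 30% of the original
    length, bounding internal branches away from zero.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    lo, hi = blen_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    leaves = [TreeNode(name=f"t{i + 1}", length=blen()) for i in range(3)]
    root = TreeNode(children=list(leaves))
    parent = {id(lf): root for lf in leaves}
    edges = list(leaves)  # nodes whose edge to their parent can be split
    for i in range(3, n_leaves):
        node = edges[rng.integers(0, len(edges))]
        par = parent[id(node)]
        frac = float(rng.uniform(0.3, 0.7))
        upper = node.length * frac
        lower = node.length - upper
        newleaf = TreeNode(name=f"t{i + 1}", length=blen())
        mid = TreeNode(length=upper, children=[node, newleaf])
        node.length = lower
        par.children[par.children.index(node)] = mid
        parent[id(mid)] = par
        parent[id(node)] = mid
        parent[id(newleaf)] = mid
        edges.extend([newleaf, mid])
    return Tree(root=root)


# ---------------------------------------------------------------------------
# qPCR generators
# ---------------------------------------------------------------------------


def simulate_standard_series(
    slope: float,
    intercept: float,
    levels: Sequence[float],
    reps: int = 3,
    sigma_ct: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic dilution-series table (``copies_per_ul, ct, replicate``).

    ``Ct = intercept + slope * log10(copies) + N(0, sigma_ct)`` per
    replicate; *levels* are log10 copy numbers (e.g. ``range(1, 10)``
    for a nine-order-of-magnitude series).
    """
    if sigma_ct < 0:
        raise ValueError("sigma_ct must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        for rep in range(1, reps + 1):
            ct = intercept + slope * level + (rng.normal(0, sigma_ct) if sigma_ct else 0.0)
            rows.append(
                {"copies_per_ul": 10.0**level, "ct": ct, "replicate": rep}
            )
    return pd.DataFrame(rows, columns=["copies_per_ul", "ct", "replicate"])


def simulate_spike_experiment(
    a: float,
    b: float,
    levels: Sequence[float] = (7.0, 8.0, 9.0),
    reps: int = 12,
    sigma: float = 0.05,
    seed: int = 0,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Synthetic spike-recovery table (``log10_true, log10_measured, sd``).

    Per replicate, ``log10_measured = a * log10_true - b + N(0, sigma)``.
    With ``aggregate=True`` (default) one row per level is returned with
    the replicate mean and SD — the form a weighted calibration fit
    consumes; otherwise raw replicate rows are returned.
    """
    if a <= 0:
        raise ValueError("forward-model slope a must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        meas = a * level - b + (
            rng.normal(0, sigma, size=reps) if sigma else np.zeros(reps)
        )
        if aggregate:
            rows.append(
                {
                    "log10_true": level,
                    "log10_measured": float(meas.mean()),
                    "sd": float(meas.std(ddof=1)) if reps > 1 else 0.0,
                }
            )
        else:
            rows.extend(
                {"log10_true": level, "log10_measured": float(m), "sd": float("nan")}
                for m in meas
            )
    return pd.DataFrame(rows, columns=["log10_true", "log10_measured", "sd"])
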