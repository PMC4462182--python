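"""IUPAC-aware in-silico PCR: binding-site search, amplicon prediction
and clade coverage / cross-clade specificity reporting.

Matching semantics: a primer code matches a target base iff their IUPAC
nucleotide sets intersect (so ``N`` in the target matches everything and
an ambiguous target base that cannot pair with the primer code counts as
a mismatch).  A binding site must additionally match exactly over the
3'-terminal bases of the primer (default 2 nt), mirroring the polymerase
extension requirement.  The matcher is vectorized over target positions
with 4-bit nucleotide masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .primerdesign import PrimerPair
from .seqcore import SequenceRecord, encode_mask, reverse_complement

DEFAULT_3PRIME_EXACT = 2
DEFAULT_MAX_AMPLICON_SCAN = 3000


@dataclass(frozen=True)
class BindingSite:
    target_id: str
    strand: str          # "forward": primer footprint reads 5'->3' with the
                         # sense strand; "reverse": primer anneals to it
    start: int           # 1-based leftmost sense-strand position of footprint
    length: int
    mismatches: int
    three_prime_exact: bool = True

    @property
    def end(self) -> int:
        """1-based rightmost sense-strand position of the footprint."""
        return self.start + self.length - 1


@dataclass(frozen=True)
class AmpliconPrediction:
    target_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    length: int


@dataclass(frozen=True)
class PrimerSet:
    """A named forward/reverse oligo pair aimed at one or more clades."""

    set_id: str
    forward: str
    reverse: str
    target_clades: tuple[str, ...]

    @classmethod
    def from_pair(cls, set_id: str, pair: PrimerPair) -> "PrimerSet":
        return cls(
            set_id=set_id,
            forward=pair.forward.sequence,
            reverse=pair.reverse.sequence,
            target_clades=tuple(pair.target_clades),
        )


@dataclass
class SpecificityReport:
    coverage: pd.DataFrame       # % amplifiable, primer sets x clades
    counts: pd.DataFrame         # amplifiable sequence counts, same shape
    off_targets: list[tuple[str, str, str]]  # (set_id, target_id, clade)
    specific: dict[str, bool]
    max_mismatch: int
    coverage_required: float

    def to_tsv(self, path: str | Path) -> None:
        self.coverage.to_csv(path, sep="\t", index_label="set_id")


def _target_seq(target: SequenceRecord | str) -> tuple[str, str]:
    if isinstance(target, SequenceRecord):
        return target.id, target.ungapped
    return "", str(target).upper().replace("-", "")


def find_binding_sites(
    primer: str,
    target: SequenceRecord | str,
    max_mismatch: int = 0,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
) -> list[BindingSite]:
    """All primer binding sites on both strands of a target.

    A site is reported where the IUPAC-intersection mismatch count is at
    most *max_mismatch* and the 3'-terminal *require_3prime_exact* bases
    of the primer match exactly.  ``start`` is the 1-based leftmost
    sense-strand position of the primer footprint; on the reverse strand
    the primer's 3' end faces the footprint's left edge.
    """
    tid, tseq = _target_seq(target)
    L = len(primer)
    if L == 0 or L > len(tseq):
        return []
    tmask = encode_mask(tseq)
    windows = np.lib.stride_tricks.sliding_window_view(tmask, L)
    k = min(require_3prime_exact, L)
    sites: list[BindingSite] = []
    for strand, footprint_mask, three_prime_slice in (
        ("forward", encode_mask(primer), np.s_[L - k : L] if k else np.s_[0:0]),
        ("reverse", encode_mask(reverse_complement(primer)), np.s_[0:k]),
    ):
        match = (windows & footprint_mask) != 0
        mism = L - match.sum(axis=1)
        ok = mism <= max_mismatch
        if k:
            ok &= match[:, three_prime_slice].all(axis=1)
        for pos in np.nonzero(ok)[0]:
            sites.append(
                BindingSite(
                    target_id=tid,
                    strand=strand,
                    start=int(pos) + 1,
                    length=L,
                    mismatches=int(mism[pos]),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _pair_oligos(pair: PrimerPair | PrimerSet) -> tuple[str, str]:
    if isinstance(pair, PrimerSet):
        return pair.forward, pair.reverse
    return pair.forward.sequence, pair.reverse.sequence


def predict_amplicons(
    pair: PrimerPair | PrimerSet,
    targets: Iterable[SequenceRecord] | SequenceRecord,
    max_mismatch: int = 0,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
    max_amplicon_scan: int = DEFAULT_MAX_AMPLICON_SCAN,
    min_amplicon: int = 60,
) -> list[AmpliconPrediction]:
    """Predicted amplicons of a primer pair across a target library.

    Considers every combination of a forward-primer site and a
    reverse-primer site in opposite orientations (both gene senses), and
    keeps products with ``min_amplicon <= length <= max_amplicon_scan``.
    The length is the inclusive sense-strand span from the leftmost
    footprint start to the rightmost footprint end.
    """
    if isinstance(targets, SequenceRecord):
        targets = [targets]
    fwd, rev = _pair_oligos(pair)
    out: list[AmpliconPrediction] = []
    for target in targets:
        f_sites = find_binding_sites(fwd, target, max_mismatch, require_3prime_exact)
        r_sites = find_binding_sites(rev, target, max_mismatch, require_3prime_exact)
        for fs, rs in [
            (f, r)
            for f in f_sites
            for r in r_sites
            if f.strand == "forward" and r.strand == "reverse"
        ] + [
            (f, r)
            for f in f_sites
            for r in r_sites
            if f.strand == "reverse" and r.strand == "forward"
        ]:
            left, right = (fs, rs) if fs.start <= rs.start else (rs, fs)
            # extension must run inward: the plus-strand primer sits left
            if left.strand != "forward":
                continue
            length = right.end - left.start + 1
            if min_amplicon <= length <= max_amplicon_scan:
                out.append(
                    AmpliconPrediction(
                        target_id=fs.target_id,
                        forward_site=fs,
                        reverse_site=rs,
                        length=length,
                    )
                )
    out.sort(key=lambda a: (a.target_id, a.length, a.forward_site.start))
    return out


def specificity_matrix(
    panel: Sequence[PrimerSet],
    library: Sequence[SequenceRecord],
    max_mismatch: int = 0,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
    coverage_required: float = 100.0,
    max_amplicon_scan: int = DEFAULT_MAX_AMPLICON_SCAN,
) -> SpecificityReport:
    """Clade x primer-set coverage matrix and off-target list.

    A set is *specific* iff its target-clade coverage reaches
    *coverage_required* while every non-target clade shows zero
    amplifiable sequences at the stated mismatch budget.
    """
    unlabeled = [r.id for r in library if not r.clade]
    if unlabeled:
        raise ValueError(f"unlabelled sequence(s): {unlabeled}")
    clades = sorted({r.clade for r in library})
    set_ids = [s.set_id for s in panel]
    counts = pd.DataFrame(0, index=set_ids, columns=clades, dtype=int)
    clade_sizes = pd.Series(
        {c: sum(1 for r in library if r.clade == c) for c in clades}
    )
    off_targets: list[tuple[str, str, str]] = []
    for pset in panel:
        for rec in library:
            hits = predict_amplicons(
                pset,
                rec,
                max_mismatch=max_mismatch,
                require_3prime_exact=require_3prime_exact,
                max_amplicon_scan=max_amplicon_scan,
            )
            if hits:
                counts.loc[pset.set_id, rec.clade] += 1
                if rec.clade not in pset.target_clades:
                    off_targets.append((pset.set_id, rec.id, rec.clade))
    coverage = 100.0 * counts / clade_sizes
    specific = {}
    for pset in panel:
        tgt = [c for c in pset.target_clades if c in clades]
        non_tgt = [c for c in clades if c not in pset.target_clades]
        specific[pset.set_id] = bool(tgt) and all(
            coverage.loc[pset.set_id, c] >= coverage_required for c in tgt
        ) and all(counts.loc[pset.set_id, c] == 0 for c in non_tgt)
    return SpecificityReport(
        coverage=coverage,
        counts=counts,
        off_targets=off_targets,
        specific=specific,
        max_mismatch=max_mismatch,
        coverage_required=coverage_required,
    )


def hits_table(
    panel: Sequence[PrimerSet],
    library: Sequence[SequenceRecord],
    max_mismatch: int = 0,
    require_3prime_exact: int = DEFAULT_3PRIME_EXACT,
) -> pd.DataFrame:
    """Flat TSV-ready table of predicted amplicons across a library."""
    rows = []
    for pset in panel:
        for rec in library:
            for amp in predict_amplicons(
                pset, rec, max_mismatch=max_mismatch,
                require_3prime_exact=require_3prime_exact,
            ):
                rows.append(
                    {
                        "set": pset.set_id,
                        "target": rec.id,
                        "clade": rec.clade or "",
                        "strand": amp.forward_site.strand,
                        "start": amp.forward_site.start,
                        "mismatches": amp.forward_site.mismatches
                        + amp.reverse_site.mismatches,
                        "amplicon_len": amp.length,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["set", "target", "clade", "strand", "start", "mismatches", "amplicon_len"],
    )
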