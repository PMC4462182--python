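"""Minimally-degenerate clade-specific primer design.

Candidates are generated by sliding windows over a clade alignment and
taking, per column, the minimal IUPAC code covering every residue
observed in the clade — so every emitted candidate matches 100% of the
clade members with zero mismatches by construction.  Candidates are
filtered against explicit design constraints:

* length 16-20 nt,
* melting-temperature estimate within 55-70 degC,
* GC content <= 60% (soft: violators are kept but penalized),
* at most 3 degenerate bases per primer,
* no self-complementary run of 4+ nt (3'-anchored runs are held to an
  even stricter limit, since primer-dimer extension starts there),
* paired amplicons of 60-299 bp.

Positions are 1-based and refer to the ungapped model reference
sequence of the clade (the first alignment record by default).  A
reverse candidate is stored as the oligo actually synthesized — the
reverse complement of its sense-strand window — and its ``start`` is
the sense-strand coordinate of the primer's 5' base, i.e. the 3'-most
template position it covers.  The expected amplicon of a pair is then
simply ``reverse.start - forward.start + 1``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from . import seqcore
from .seqcore import (
    GAP,
    IUPAC_SETS,
    SET_TO_CODE,
    Alignment,
    OligoMetrics,
    SequenceError,
    degeneracy,
    gc_content,
    reverse_complement,
)

#: nearest-neighbour Tm conditions: monovalent salt (mM) and primer
#: concentration (nM); declared once so reports can state them.
NN_SALT_MM = 50.0
NN_OLIGO_NM = 250.0
TM_EXPANSION_CAP = 64


class WindowInvalidError(ValueError):
    """A consensus window touches a gapped column."""


@dataclass(frozen=True)
class DesignConstraints:
    """Envelope a candidate primer (and pair) must satisfy."""

    length_min: int = 16
    length_max: int = 20
    tm_min: float = 55.0
    tm_max: float = 70.0
    gc_max: float = 60.0
    max_degenerate_bases: int = 3
    amplicon_min: int = 60
    amplicon_max: int = 300  # exclusive
    self_complement_max_run: int = 4
    coverage_required: float = 100.0
    tm_method: str = "nn"
    allow_soft_gc: bool = True
    min_base_freq: float | None = None

    def __post_init__(self) -> None:
        if self.length_min > self.length_max or self.length_min < 1:
            raise ValueError("empty primer length range")
        if self.tm_min > self.tm_max:
            raise ValueError("empty Tm window")
        if self.amplicon_min >= self.amplicon_max:
            raise ValueError("empty amplicon range")
        if not 0 < self.coverage_required <= 100:
            raise ValueError("coverage_required must be in (0, 100]")


@dataclass(frozen=True)
class TmEstimate:
    """Melting-temperature summary over the expansions of a degenerate oligo."""

    tm_min: float
    tm_mean: float
    tm_max: float
    method: str


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str            # oligo as synthesized (5'->3')
    start: int               # 1-based sense-strand coordinate of the 5' base
    strand: str              # "forward" | "reverse"
    metrics: OligoMetrics
    tm: TmEstimate
    coverage: float          # % of clade members matched with 0 mismatches
    gc_soft_violation: bool = False
    window: tuple[int, int] = (0, 0)  # 1-based inclusive alignment columns

    @property
    def length(self) -> int:
        return self.metrics.length


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    expected_amplicon: int
    target_clades: tuple[str, ...] = ()
    score: tuple = ()


class CandidateList(list):
    """List of candidates carrying a histogram of filter failures."""

    def __init__(self, items=(), failures: Counter | None = None):
        super().__init__(items)
        self.failures: Counter = failures if failures is not None else Counter()


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _column_set(residues: Iterable[str], min_freq: float | None = None) -> frozenset[str]:
    """Union of nucleotide sets in a column, optionally dropping rare residues.

    With *min_freq*, residues observed at frequency below it are ignored
    (noise tolerance for large clades) unless that would empty the
    column.
    """
    residues = list(residues)
    if GAP in residues:
        raise WindowInvalidError("column contains a gap")
    if min_freq:
        counts = Counter(residues)
        total = len(residues)
        kept = [r for r, c in counts.items() if c / total >= min_freq]
        if kept:
            residues = kept
    out: frozenset[str] = frozenset()
    for r in residues:
        out |= IUPAC_SETS[r]
    return out


def column_consensus(
    aln: Alignment,
    start: int,
    end: int,
    min_freq: float | None = None,
) -> str:
    """Minimal IUPAC consensus of alignment columns [start, end] (1-based).

    Every clade member matches the consensus with zero mismatches under
    IUPAC semantics.  A window containing a gap in any member is invalid.
    """
    if not 1 <= start <= end <= aln.ncol:
        raise ValueError(f"window [{start}, {end}] outside alignment (ncol={aln.ncol})")
    codes = []
    for col in range(start - 1, end):
        colset = _column_set(aln.column(col), min_freq=min_freq)
        codes.append(SET_TO_CODE[colset])
    return "".join(codes)


# ---------------------------------------------------------------------------
# Tm
# ---------------------------------------------------------------------------


def _tm_concrete(seq: str, method: str) -> float:
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq))
    if method == "nn":
        return float(_mt.Tm_NN(seq, Na=NN_SALT_MM, dnac1=NN_OLIGO_NM, dnac2=0))
    raise ValueError(f"unknown Tm method {method!r}")


def tm_estimate(
    seq: str,
    method: str = "nn",
    expansion_cap: int = TM_EXPANSION_CAP,
    sample: int | None = None,
    seed: int = 0,
) -> TmEstimate:
    """Melting-temperature estimate of a (possibly degenerate) oligo.

    ``wallace``: 2(A+T) + 4(G+C).  ``nn``: nearest-neighbour
    thermodynamics at 50 mM monovalent salt and 250 nM oligo.  For a
    degenerate oligo the min/mean/max over its concrete expansions are
    reported; expansions beyond *expansion_cap* require *sample* (the
    number of expansions to draw, seeded).
    """
    s = seqcore.normalize(seq)
    if len(s) < 8:
        raise SequenceError("Tm estimation requires length >= 8")
    n_exp = math.prod(len(IUPAC_SETS[ch]) for ch in s)
    if n_exp > expansion_cap:
        if sample is None:
            raise SequenceError(
                f"expansion {n_exp} exceeds cap {expansion_cap}; pass sample= to subsample"
            )
        rng = np.random.default_rng(seed)
        variants = [
            "".join(rng.choice(sorted(IUPAC_SETS[ch])) for ch in s)
            for _ in range(sample)
        ]
    else:
        variants = seqcore.expand(s)
    tms = [_tm_concrete(v, method) for v in variants]
    return TmEstimate(
        tm_min=min(tms), tm_mean=float(np.mean(tms)), tm_max=max(tms), method=method
    )


# ---------------------------------------------------------------------------
# Self-complementarity
# ---------------------------------------------------------------------------


def complementarity_run(a: str, b: str) -> tuple[int, int]:
    """Longest complementary run when *a* anneals antiparallel to *b*.

    Slides *a* against the reverse complement of *b* over every offset;
    IUPAC set intersection counts as a match.  Returns ``(longest_run,
    longest_run_touching_a_3prime)``.
    """
    sa = seqcore.normalize(a)
    sb_rc = reverse_complement(b)
    na, nb = len(sa), len(sb_rc)
    best = best3 = 0
    for offset in range(-(nb - 1), na):
        run = 0
        for i in range(max(0, offset), min(na, offset + nb)):
            j = i - offset
            if IUPAC_SETS[sa[i]] & IUPAC_SETS[sb_rc[j]]:
                run += 1
                best = max(best, run)
                if i == na - 1:
                    best3 = max(best3, run)
            else:
                run = 0
    return best, best3


@dataclass(frozen=True)
class SelfComplementarityResult:
    longest_run: int
    three_prime_run: int
    passed: bool


def self_complementarity(seq: str, max_run: int = 4) -> SelfComplementarityResult:
    """Self-dimer check: fail on a complementary run >= *max_run* nt, or a
    3'-anchored run >= *max_run* - 1 nt."""
    longest, three_prime = complementarity_run(seq, seq)
    passed = longest < max_run and three_prime < max_run - 1
    return SelfComplementarityResult(longest, three_prime, passed)


# ---------------------------------------------------------------------------
# Candidate scan
# ---------------------------------------------------------------------------


def _reference_positions(ref_seq: str) -> np.ndarray:
    """1-based ungapped reference coordinate of each alignment column
    (columns where the reference is gapped get the previous coordinate)."""
    pos = np.zeros(len(ref_seq), dtype=int)
    p = 0
    for i, ch in enumerate(ref_seq):
        if ch != GAP:
            p += 1
        pos[i] = p
    return pos


def _verify_coverage(aln: Alignment, consensus: str, col0: int) -> float:
    """Percent of members whose window residues fall inside the consensus
    codes (always 100 for a minimal covering consensus; asserted)."""
    hit = 0
    for rec in aln.records:
        window = rec.seq[col0 : col0 + len(consensus)]
        if all(
            IUPAC_SETS[r] <= IUPAC_SETS[c] for r, c in zip(window, consensus)
        ):
            hit += 1
    return 100.0 * hit / len(aln)


def scan_candidates(
    aln: Alignment,
    constraints: DesignConstraints | None = None,
    reference_index: int = 0,
) -> CandidateList:
    """Enumerate all primer candidates of a clade alignment.

    Every window of each allowed length is scored on both strands;
    candidates passing the degeneracy, GC (soft), self-complementarity
    and Tm constraints are returned sorted by (expansion ascending,
    length descending, strand, position).  When the list is empty, the
    ``failures`` attribute holds a histogram of rejection reasons.
    """
    c = constraints or DesignConstraints()
    if len(aln) == 0:
        raise ValueError("alignment is empty")
    ncol = aln.ncol
    failures: Counter = Counter()

    # per-column covering sets; None marks a gapped (unusable) column
    col_sets: list[frozenset[str] | None] = []
    for i in range(ncol):
        try:
            col_sets.append(_column_set(aln.column(i), min_freq=c.min_base_freq))
        except WindowInvalidError:
            col_sets.append(None)
    card = np.array([0 if s is None else len(s) for s in col_sets])
    gapped = np.array([s is None for s in col_sets])
    degen = (card > 1) & ~gapped
    gap_cum = np.concatenate([[0], np.cumsum(gapped)])
    deg_cum = np.concatenate([[0], np.cumsum(degen)])
    ref_pos = _reference_positions(aln.records[reference_index].seq)

    out: list[PrimerCandidate] = []
    for L in range(c.length_min, c.length_max + 1):
        for s0 in range(0, ncol - L + 1):
            if gap_cum[s0 + L] - gap_cum[s0] > 0:
                failures["gap_in_window"] += 1
                continue
            ndeg = int(deg_cum[s0 + L] - deg_cum[s0])
            if ndeg > c.max_degenerate_bases:
                failures["degeneracy"] += 1
                continue
            consensus = "".join(SET_TO_CODE[col_sets[i]] for i in range(s0, s0 + L))
            metrics = degeneracy(consensus)
            gc_violation = metrics.gc_percent > c.gc_max
            if gc_violation and not c.allow_soft_gc:
                failures["gc"] += 1
                continue
            coverage = _verify_coverage(aln, consensus, s0)
            if c.min_base_freq is None:
                assert coverage == 100.0, "minimal covering consensus must cover the clade"
            elif coverage < c.coverage_required:
                failures["coverage"] += 1
                continue
            for strand, oligo, start in (
                ("forward", consensus, int(ref_pos[s0])),
                ("reverse", reverse_complement(consensus), int(ref_pos[s0 + L - 1])),
            ):
                sc = self_complementarity(oligo, c.self_complement_max_run)
                if not sc.passed:
                    failures["self_complementarity"] += 1
                    continue
                tm = tm_estimate(oligo, method=c.tm_method)
                if not c.tm_min <= tm.tm_mean <= c.tm_max:
                    failures["tm"] += 1
                    continue
                out.append(
                    PrimerCandidate(
                        sequence=oligo,
                        start=start,
                        strand=strand,
                        metrics=metrics,
                        tm=tm,
                        coverage=coverage,
                        gc_soft_violation=gc_violation,
                        window=(s0 + 1, s0 + L),
                    )
                )
    out.sort(key=lambda p: (p.metrics.expansion, -p.length, p.strand, p.start))
    return CandidateList(out, failures)


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


def pair_primers(
    cands: Sequence[PrimerCandidate],
    constraints: DesignConstraints | None = None,
    target_clades: tuple[str, ...] = (),
) -> list[PrimerPair]:
    """All forward x reverse combinations with an in-range amplicon.

    The expected amplicon is ``reverse.start - forward.start + 1`` on
    the ungapped reference (inclusive span), accepted when
    ``amplicon_min <= amplicon < amplicon_max``.  Pairs are ranked by
    (total expansion, amplicon length, |Tm_F - Tm_R|, GC-soft
    violations) ascending and deduplicated by (forward.start,
    reverse.start).
    """
    c = constraints or DesignConstraints()
    forwards = [p for p in cands if p.strand == "forward"]
    reverses = [p for p in cands if p.strand == "reverse"]
    best: dict[tuple[int, int], PrimerPair] = {}
    for f in forwards:
        for r in reverses:
            amplicon = r.start - f.start + 1
            if not c.amplicon_min <= amplicon < c.amplicon_max:
                continue
            score = (
                f.metrics.expansion + r.metrics.expansion,
                amplicon,
                abs(f.tm.tm_mean - r.tm.tm_mean),
                int(f.gc_soft_violation) + int(r.gc_soft_violation),
            )
            key = (f.start, r.start)
            pair = PrimerPair(
                forward=f,
                reverse=r,
                expected_amplicon=amplicon,
                target_clades=target_clades,
                score=score,
            )
            if key not in best or score < best[key].score:
                best[key] = pair
    pairs = sorted(best.values(), key=lambda p: p.score)
    return pairs


def design_primer_set(
    aln: Alignment,
    clade: str = "",
    constraints: DesignConstraints | None = None,
    reference_index: int = 0,
) -> tuple[PrimerPair | None, CandidateList]:
    """Convenience: scan a clade alignment and return the top-ranked pair
    (or None) plus the full candidate list."""
    cands = scan_candidates(aln, constraints, reference_index=reference_index)
    pairs = pair_primers(cands, constraints, target_clades=(clade,) if clade else ())
    return (pairs[0] if pairs else None), cands
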