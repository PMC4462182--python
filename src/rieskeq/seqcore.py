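"""Core IUPAC nucleotide machinery shared by every other module.

Sequences are modelled as plain upper-case strings over the IUPAC
nucleotide alphabet (``A C G T`` plus the ambiguity codes
``R Y S W K M B D H V N``).  Gaps (``-``) are legal only inside
alignments; oligonucleotides (primers) never carry them.  ``U`` is
accepted on ingest and mapped to ``T``.

The module provides

* :class:`SequenceRecord` / :class:`Alignment` containers,
* FASTA reading/writing (via Biopython, 60-column wrapped output),
* per-oligo metrics: GC content, degeneracy, expansion count,
* IUPAC-aware reverse complement and bitmask encoding used by the
  in-silico PCR matcher,
* the tab-separated primer-panel dialect
  (``set_id, role, sequence, clade, note``) and the packaged reference
  panel of clade-specific dioxygenase primers.

GC convention
-------------
``gc_content`` counts only literal ``G``/``C`` characters by default:
ambiguity codes are excluded from the count even when every expansion is
G/C (code ``S``).  An alternate ``mode="expected"`` weighs each code by
the G/C fraction of the nucleotide set it denotes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"

#: IUPAC code -> set of concrete nucleotides it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: nucleotide set -> minimal IUPAC code covering it.
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
#: IUPAC code -> 4-bit mask (A=1, C=2, G=4, T=8); two codes are
#: compatible iff their masks intersect.
CODE_BITS: dict[str, int] = {
    code: sum(_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

ALPHABET = frozenset(IUPAC_SETS)


class SequenceError(ValueError):
    """Illegal character, empty input, or similar sequence-level problem."""


class FastaParseError(SequenceError):
    """Malformed FASTA input; the message names the offending line."""


def normalize(seq: str, allow_gaps: bool = False) -> str:
    """Upper-case *seq*, map U->T and validate against the IUPAC alphabet."""
    s = str(seq).upper().replace("U", "T")
    allowed = ALPHABET | {GAP} if allow_gaps else ALPHABET
    bad = sorted(set(s) - allowed)
    if bad:
        raise SequenceError(
            f"illegal character(s) {bad!r} (allowed: IUPAC nucleotide codes"
            + (" and gaps)" if allow_gaps else ", no gaps)")
        )
    return s


@dataclass
class SequenceRecord:
    """A named IUPAC nucleotide sequence, optionally clade-labelled."""

    id: str
    seq: str
    clade: str | None = None
    meta: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        self.seq = normalize(self.seq, allow_gaps=True)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


@dataclass
class Alignment:
    """Ordered collection of equal-length (gapped) sequence records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if self.records:
            ncol = len(self.records[0].seq)
            if ncol == 0:
                raise SequenceError("alignment columns must be non-empty")
            for rec in self.records:
                if len(rec.seq) != ncol:
                    raise SequenceError(
                        f"record {rec.id!r} has length {len(rec.seq)}, expected {ncol}"
                    )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate sequence ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def ncol(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def char_matrix(self) -> np.ndarray:
        """(n_records, ncol) array of single characters."""
        return np.array([list(r.seq) for r in self.records], dtype="U1")

    def column(self, i: int) -> list[str]:
        """Residues of 0-based column *i*."""
        return [r.seq[i] for r in self.records]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.id in wanted])

    @classmethod
    def from_fasta(cls, path: str | Path, clades: dict[str, str] | None = None) -> "Alignment":
        records = read_fasta(path)
        if clades:
            for rec in records:
                rec.clade = clades.get(rec.id, rec.clade)
        return cls(records)


def _check_fasta_shape(path: Path) -> None:
    """Reject text that is not FASTA-shaped, naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            return


def _locate_illegal_char(path: Path) -> tuple[int, str]:
    allowed = ALPHABET | {GAP}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") or not line.strip():
                continue
            for ch in line.strip().upper().replace("U", "T"):
                if ch not in allowed:
                    return lineno, ch
    return -1, "?"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased, ``U`` is mapped to ``T`` and record order
    is preserved.  Malformed headers or characters outside the IUPAC
    alphabet raise :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    _check_fasta_shape(path)
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        entries = list(SeqIO.parse(handle, "fasta"))
    for entry in entries:
        if not entry.id:
            raise FastaParseError(f"{path}: record with empty identifier")
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        try:
            seq = normalize(str(entry.seq), allow_gaps=True)
        except SequenceError as exc:
            lineno, ch = _locate_illegal_char(path)
            raise FastaParseError(
                f"{path}: line {lineno}: illegal character {ch!r} in record {entry.id!r}"
            ) from exc
        out.append(SequenceRecord(id=entry.id, seq=seq, meta=entry.description))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    """Reverse complement extended to ambiguity codes (R<->Y, B<->V, ...).

    Gaps are not permitted: oligos never carry them.
    """
    s = normalize(seq)  # rejects gaps and illegal characters
    return str(Seq(s).reverse_complement())


def gc_content(seq: str, mode: str = "unambiguous") -> float:
    """GC content of an oligo, as a percentage.

    ``mode="unambiguous"`` (default) counts only literal G/C characters;
    ambiguity codes contribute nothing, even the always-G/C code ``S``.
    ``mode="expected"`` adds the fractional G/C content of each
    ambiguity code (e.g. ``S`` -> 1, ``Y`` -> 0.5).
    """
    s = normalize(seq)
    if not s:
        raise SequenceError("gc_content of empty sequence is undefined")
    if mode == "unambiguous":
        gc = sum(1 for ch in s if ch in "GC")
    elif mode == "expected":
        gc = sum(
            len(IUPAC_SETS[ch] & {"G", "C"}) / len(IUPAC_SETS[ch]) for ch in s
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * gc / len(s)


@dataclass(frozen=True)
class OligoMetrics:
    """Length, GC%, degenerate-base count and expansion of one oligo."""

    length: int
    gc_percent: float
    n_degenerate: int
    expansion: int

    @property
    def gc_rounded(self) -> int:
        return round(self.gc_percent)


def degeneracy(seq: str) -> OligoMetrics:
    """Per-oligo metrics: degenerate-base count and expansion.

    ``n_degenerate`` counts characters outside ``ACGT``; ``expansion``
    is the number of concrete sequences the degenerate oligo denotes
    (product of per-position code cardinalities).
    """
    s = normalize(seq)
    if not s:
        raise SequenceError("degeneracy of empty sequence is undefined")
    n_deg = sum(1 for ch in s if ch not in "ACGT")
    expansion = math.prod(len(IUPAC_SETS[ch]) for ch in s)
    return OligoMetrics(
        length=len(s),
        gc_percent=gc_content(s),
        n_degenerate=n_deg,
        expansion=expansion,
    )


def expand(seq: str, cap: int | None = None) -> list[str]:
    """Enumerate the concrete ACGT sequences a degenerate oligo denotes.

    With *cap*, raise if the expansion exceeds it (guards combinatorial
    blow-up; callers that sample should enumerate themselves).
    """
    s = normalize(seq)
    n = math.prod(len(IUPAC_SETS[ch]) for ch in s)
    if cap is not None and n > cap:
        raise SequenceError(f"expansion {n} exceeds cap {cap}")
    return [
        "".join(p)
        for p in itertools.product(*(sorted(IUPAC_SETS[ch]) for ch in s))
    ]


def encode_mask(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 bitmask array (A=1 C=2 G=4 T=8).

    Two positions are compatible iff the bitwise AND of their masks is
    non-zero; this is the matching primitive of the in-silico PCR scan.
    """
    s = normalize(seq)
    return np.array([CODE_BITS[ch] for ch in s], dtype=np.uint8)


# ---------------------------------------------------------------------------
# Primer-panel TSV dialect
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["set_id", "role", "sequence", "clade", "note"]


def read_primer_panel(path: str | Path) -> pd.DataFrame:
    """Read a primer panel TSV (columns ``set_id role sequence clade note``).

    Extra columns (positions, printed metrics, annealing temperatures)
    are preserved.  Sequences are validated as gap-free IUPAC oligos.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in PANEL_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"primer panel {path}: missing columns {missing}")
    if "note" not in df.columns:
        df["note"] = ""
    bad_roles = sorted(set(df["role"]) - {"F", "R"})
    if bad_roles:
        raise ValueError(f"primer panel {path}: roles must be F or R, got {bad_roles}")
    df["sequence"] = [normalize(s) for s in df["sequence"]]
    return df


def write_primer_panel(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _data_path(name: str):
    return resources.files("rieskeq.data").joinpath(name)


def load_reference_panel() -> pd.DataFrame:
    """The packaged clade-specific dioxygenase primer panel.

    Nine primer sets (18 oligos) targeting the conserved Rieske-centre
    region of aromatic dioxygenase alpha-subunit genes, with their
    published positions, amplicon sizes, GC percentages and optimized
    annealing temperatures.
    """
    with resources.as_file(_data_path("dioxygenase_primer_panel.tsv")) as p:
        df = read_primer_panel(p)
    for col in ("position", "amplicon_bp", "gc_printed", "anneal_c"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_reference_standard_curves() -> pd.DataFrame:
    """Published qPCR standard-curve coefficients for the reference panel."""
    with resources.as_file(_data_path("dioxygenase_standard_curves.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
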