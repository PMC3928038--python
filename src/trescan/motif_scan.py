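"""IUPAC half-site and dyad (half-site / spacer / half-site) scanning.

Nuclear-receptor response elements are built from AGGTCA-like hexamer
half-sites arranged as direct, everted or inverted repeats with a
characteristic spacer (DR-n / ER-n / IP-n).  This module compiles the text
grammar for such elements (``AGGnCA-4-AGGnCA`` means two half-sites spaced
by 4 unconstrained bases) and reports every occurrence on both strands.

Matching rules:

* ``N``/``n`` in a pattern matches any genome base including ``N``; every
  other IUPAC code matches only its defined base set, never ``N`` (an
  unknown base should not satisfy a specific-base requirement).
* Spacer bases are unconstrained (the grammar defines the spacer only by
  its length).
* All overlapping matches are reported; no masking.
* A pattern whose IUPAC string equals its own reverse complement describes
  one biological site per footprint, so bidirectional scans report such
  footprints once (as strand ``+``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Union

from .io_formats import GenomicInterval

__all__ = [
    "IUPAC_SETS",
    "IUPACPattern",
    "DyadSpec",
    "MotifMatch",
    "Motif",
    "reverse_complement",
    "parse_motif_notation",
    "read_motif_grammar",
    "scan_pattern",
    "scan_dyad",
    "scan_motif",
]

# Base sets over the genome alphabet {A,C,G,T,N}.  N in a pattern is the
# only code that matches genomic N.
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
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class AlphabetError(ValueError):
    """A sequence or pattern contains a character outside its alphabet."""


class MotifParseError(ValueError):
    """Motif grammar text does not parse."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA or IUPAC string (involution)."""
    s = seq.upper()
    for ch in s:
        if ch not in IUPAC_SETS:
            raise AlphabetError(f"invalid character {ch!r} in {seq!r}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACPattern:
    """A fixed-length degenerate pattern over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise MotifParseError("empty pattern")
        for i, ch in enumerate(pat):
            if ch not in IUPAC_SETS:
                raise MotifParseError(
                    f"invalid IUPAC code {ch!r} at position {i} in {self.pattern!r}"
                )
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    def reverse_complement(self) -> "IUPACPattern":
        return IUPACPattern(reverse_complement(self.pattern))

    @property
    def is_palindromic(self) -> bool:
        """Self-reverse-complementary as an IUPAC string."""
        return reverse_complement(self.pattern) == self.pattern


@dataclass(frozen=True)
class DyadSpec:
    """Two half-site patterns separated by a fixed spacer or a spacer range.

    ``spacer`` is either a single non-negative int or an inclusive
    ``(lo, hi)`` range; the total footprint for spacer s is
    ``len(left) + s + len(right)``.
    """

    label: str
    left: IUPACPattern
    spacer: Union[int, tuple[int, int]]
    right: IUPACPattern

    def __post_init__(self) -> None:
        lo, hi = self.spacer_range
        if lo < 0 or hi < lo:
            raise MotifParseError(f"invalid spacer {self.spacer!r}")

    @property
    def spacer_range(self) -> tuple[int, int]:
        if isinstance(self.spacer, int):
            return (self.spacer, self.spacer)
        return self.spacer

    def footprint(self, spacer: int) -> int:
        return len(self.left) + spacer + len(self.right)

    def composite(self, spacer: int) -> IUPACPattern:
        """The dyad at a fixed spacer as one flat IUPAC pattern."""
        return IUPACPattern(str(self.left) + "N" * spacer + str(self.right))

    def __str__(self) -> str:
        lo, hi = self.spacer_range
        sp = str(lo) if lo == hi else f"{lo}..{hi}"
        return f"{self.left}-{sp}-{self.right}"


Motif = Union[IUPACPattern, DyadSpec]


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; the interval is the footprint in plus-strand
    coordinates and ``matched`` the plus-strand sequence under it."""

    interval: GenomicInterval
    strand: str
    matched: str
    spacer_used: int | None = None


# ---------------------------------------------------------------------------
# Grammar parsing

_DYAD_RE = re.compile(
    r"^(?P<left>[A-Za-z]+)-(?P<lo>\d+)(?:\.\.(?P<hi>\d+))?-(?P<right>[A-Za-z]+)$"
)


def parse_motif_notation(text: str, label: str = "") -> Motif:
    """Parse ``HALF``, ``HALF-k-HALF`` or ``HALF-k..j-HALF`` notation.

    >>> parse_motif_notation("AGGnCA-4-AGGnCA")
    DyadSpec(label='', left=IUPACPattern(pattern='AGGNCA'), spacer=4, ...)
    """
    text = text.strip()
    if not text:
        raise MotifParseError("empty motif notation")
    if "-" in text:
        m = _DYAD_RE.match(text)
        if m is None:
            raise MotifParseError(
                f"malformed dyad notation {text!r} (expected HALF-k-HALF "
                f"or HALF-k..j-HALF)"
            )
        lo = int(m.group("lo"))
        hi = int(m.group("hi")) if m.group("hi") is not None else lo
        if hi < lo:
            raise MotifParseError(f"spacer range {lo}..{hi} is inverted in {text!r}")
        spacer: Union[int, tuple[int, int]] = lo if lo == hi else (lo, hi)
        return DyadSpec(
            label=label,
            left=IUPACPattern(m.group("left")),
            spacer=spacer,
            right=IUPACPattern(m.group("right")),
        )
    return IUPACPattern(text)


def read_motif_grammar(path: str | Path) -> list[tuple[str, Motif]]:
    """Read a grammar file: one ``LABEL<TAB>NOTATION`` per line, ``#``
    comments allowed.  Returns (label, motif) pairs in file order."""
    out: list[tuple[str, Motif]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MotifParseError(
                    f"{path}:{lineno}: expected LABEL<TAB>NOTATION"
                )
            label, notation = parts[0].strip(), parts[1].strip()
            try:
                out.append((label, parse_motif_notation(notation, label=label)))
            except MotifParseError as exc:
                raise MotifParseError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Scanning

@lru_cache(maxsize=512)
def _compile_str(pattern: str) -> re.Pattern[str]:
    # Overlapping matches via a capturing lookahead.
    body = "".join("[" + "".join(sorted(IUPAC_SETS[ch])) + "]" for ch in pattern)
    return re.compile(f"(?=({body}))")


def _compile(pattern: IUPACPattern) -> re.Pattern[str]:
    return _compile_str(pattern.pattern)


def _find(seq: str, pattern: IUPACPattern) -> list[int]:
    return [m.start() for m in _compile(pattern).finditer(seq)]


def _validate_seq(seq: str) -> str:
    s = seq.upper()
    if s.strip("ACGTN"):
        bad = next(ch for ch in s if ch not in "ACGTN")
        raise AlphabetError(f"invalid sequence character {bad!r}")
    return s


def scan_pattern(
    seq: str,
    pattern: IUPACPattern,
    bidirectional: bool = True,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifMatch]:
    """All occurrences of ``pattern`` in ``seq``, optionally on both strands.

    Minus-strand occurrences are positions where the reverse complement of
    the pattern matches the given (plus-strand) sequence.  Palindromic
    patterns are reported once per footprint.  ``chrom``/``offset`` shift
    reported intervals into genome coordinates.
    """
    s = _validate_seq(seq)
    L = len(pattern)
    matches = [
        MotifMatch(
            GenomicInterval(chrom or ".", offset + i, offset + i + L, "+"),
            "+",
            s[i : i + L],
        )
        for i in _find(s, pattern)
    ]
    if bidirectional and not pattern.is_palindromic:
        rc = pattern.reverse_complement()
        matches += [
            MotifMatch(
                GenomicInterval(chrom or ".", offset + i, offset + i + L, "-"),
                "-",
                s[i : i + L],
            )
            for i in _find(s, rc)
        ]
    matches.sort(key=lambda m: (m.interval.start, m.strand))
    return matches


def scan_dyad(
    seq: str,
    dyad: DyadSpec,
    bidirectional: bool = True,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifMatch]:
    """All dyad occurrences: left half at i, right half at i+|left|+s for
    every spacer s in the dyad's range, both strands.  Each match records
    the spacer it used."""
    s = _validate_seq(seq)
    lo, hi = dyad.spacer_range
    matches: list[MotifMatch] = []
    for sp in range(lo, hi + 1):
        comp = dyad.composite(sp)
        L = len(comp)
        hits = [(i, "+") for i in _find(s, comp)]
        if bidirectional and not comp.is_palindromic:
            hits += [(i, "-") for i in _find(s, comp.reverse_complement())]
        for i, strand in hits:
            matches.append(
                MotifMatch(
                    GenomicInterval(chrom or ".", offset + i, offset + i + L, strand),
                    strand,
                    s[i : i + L],
                    spacer_used=sp,
                )
            )
    matches.sort(key=lambda m: (m.interval.start, m.spacer_used or 0, m.strand))
    return matches


def scan_motif(
    seq: str,
    motif: Motif,
    bidirectional: bool = True,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifMatch]:
    """Dispatch to :func:`scan_pattern` or :func:`scan_dyad`."""
    if isinstance(motif, DyadSpec):
        return scan_dyad(seq, motif, bidirectional, chrom=chrom, offset=offset)
    return scan_pattern(seq, motif, bidirectional, chrom=chrom, offset=offset)


def write_matches_bed(
    matches: Iterable[MotifMatch], label: str, path: str | Path
) -> None:
    """Match output as BED6 with name=label and score=1."""
    with open(path, "w") as fh:
        for m in matches:
            iv = m.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t1\t{m.strand}\n"
            )
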