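"""Consensus derivation from top-ranked peaks and PWM scoring.

A position frequency matrix (PFM) is built by anchoring each top peak
sequence on its best half-site seed match (e.g. AGGnCA), taking a fixed
window of flanks around the re-oriented match, and stacking the windows.
The PFM reduces to an IUPAC consensus by a majority / cumulative-coverage
rule, and converts to a log-odds position weight matrix (PWM) for scoring
candidate response elements.

This seeded-alignment procedure is deterministic (unlike EM-style de-novo
discovery) and recovers a planted consensus exactly in simulation; de-novo
discovery without a seed is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomicInterval, Peak
from .motif_scan import IUPACPattern, IUPAC_SETS, MotifMatch, reverse_complement, scan_pattern

__all__ = [
    "PFM",
    "PWM",
    "rank_peaks",
    "build_pfm_from_seed",
    "pfm_to_iupac",
    "pwm_scan",
    "read_jaspar",
    "write_jaspar",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC codes ordered by base-set size then alphabetically, for consensus
# reduction (prefer the least degenerate code that covers enough mass).
_CODES_BY_SIZE = sorted(
    (c for c in IUPAC_SETS if c != "N"),
    key=lambda c: (len(IUPAC_SETS[c]), c),
) + ["N"]


class EmptyPFMError(ValueError):
    """No sequence contributed a seed-aligned window."""


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: per-column base counts of aligned sites.

    ``counts`` is a 4 x L integer array with rows in A, C, G, T order;
    every column sums to ``n_sequences``.
    """

    counts: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("PFM counts must be a 4 x L array")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        sums = counts.sum(axis=0)
        if not (sums == self.n_sequences).all():
            raise ValueError(
                f"PFM column sums {sums.tolist()} != n_sequences {self.n_sequences}"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def consensus(self) -> str:
        """Plurality base per column (ties broken in A<C<G<T order)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PWM:
    """Log2-odds matrix against a background base composition."""

    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @classmethod
    def from_pfm(
        cls,
        pfm: PFM,
        background: Sequence[float] | None = None,
        pseudocount: float = 1.0,
    ) -> "PWM":
        """log2((count_b + pseudocount*bg_b) / (n + pseudocount) / bg_b).

        The scalar pseudocount is split across bases by the background, so
        the default of 1.0 gives 0.25 per base under a uniform background.
        """
        bg = np.asarray(
            background if background is not None else [0.25] * 4, dtype=float
        )
        if bg.shape != (4,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 frequencies summing to 1")
        if (bg <= 0).any():
            raise ValueError("background frequencies must be positive")
        probs = (pfm.counts + pseudocount * bg[:, None]) / (
            pfm.n_sequences + pseudocount
        )
        return cls(np.log2(probs / bg[:, None]), bg, pseudocount)


def genome_base_composition(genome: Mapping[str, str]) -> np.ndarray:
    """Observed A/C/G/T frequencies of a genome (N excluded)."""
    counts = np.zeros(4, dtype=float)
    for seq in genome.values():
        for i, b in enumerate(BASES):
            counts[i] += seq.count(b)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def rank_peaks(peaks: Sequence[Peak], n: int) -> list[Peak]:
    """Top-n peaks by descending score; ties broken by (chrom, start) so
    the ranking is stable across runs.  Returns all peaks when n exceeds
    the available count."""
    ordered = sorted(
        peaks,
        key=lambda p: (-p.score, p.interval.chrom, p.interval.start, p.interval.end),
    )
    return ordered[: min(n, len(ordered))]


def _best_seed_window(
    seq: str, seed: IUPACPattern, flank5: int, flank3: int
) -> str | None:
    """Seed-oriented window around the seed match closest to the sequence
    midpoint (ChIP signal is midpoint-centred); ties prefer the plus
    strand, then the leftmost match.  None if no usable match."""
    matches = scan_pattern(seq, seed, bidirectional=True)
    if not matches:
        return None
    mid = len(seq) / 2

    def key(m: MotifMatch) -> tuple:
        centre = (m.interval.start + m.interval.end) / 2
        return (abs(centre - mid), 0 if m.strand == "+" else 1, m.interval.start)

    for m in sorted(matches, key=key):
        if m.strand == "+":
            lo = m.interval.start - flank5
            hi = m.interval.end + flank3
            if lo < 0 or hi > len(seq):
                continue
            window = seq[lo:hi]
        else:
            lo = m.interval.start - flank3
            hi = m.interval.end + flank5
            if lo < 0 or hi > len(seq):
                continue
            window = reverse_complement(seq[lo:hi])
        if set(window) <= set(BASES):  # windows containing N cannot be counted
            return window
    return None


def build_pfm_from_seed(
    peak_seqs: Sequence[str],
    seed: IUPACPattern | str,
    flank5: int = 0,
    flank3: int = 0,
) -> PFM:
    """Stack seed-anchored windows of width ``flank5 + len(seed) + flank3``
    from each peak sequence into a PFM.

    Minus-strand seed matches are reverse-complemented into seed
    orientation, so the result is invariant to flipping input sequences.
    Sequences without an in-bounds match are skipped; all-skipped raises
    :class:`EmptyPFMError`.
    """
    if flank5 < 0 or flank3 < 0:
        raise ValueError("flanks must be >= 0")
    if isinstance(seed, str):
        seed = IUPACPattern(seed)
    width = flank5 + len(seed) + flank3
    counts = np.zeros((4, width), dtype=int)
    n = 0
    for seq in peak_seqs:
        window = _best_seed_window(seq.upper(), seed, flank5, flank3)
        if window is None:
            continue
        for j, base in enumerate(window):
            counts[_BASE_INDEX[base], j] += 1
        n += 1
    if n == 0:
        raise EmptyPFMError(
            f"no sequence produced a seed-aligned window for seed {seed}"
        )
    return PFM(counts, n)


def pfm_to_iupac(
    pfm: PFM, major_threshold: float = 0.6, coverage_threshold: float = 0.8
) -> IUPACPattern:
    """Reduce a PFM to an IUPAC consensus.

    Per column: the plurality base if its frequency >= ``major_threshold``;
    otherwise the smallest IUPAC base set whose cumulative frequency
    reaches ``coverage_threshold`` (falling back to N).
    """
    if not (0 < major_threshold <= 1 and 0 < coverage_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    freqs = pfm.frequencies()
    out = []
    for col in freqs.T:
        top = int(col.argmax())
        if col[top] >= major_threshold:
            out.append(BASES[top])
            continue
        for code in _CODES_BY_SIZE:
            mass = sum(col[_BASE_INDEX[b]] for b in IUPAC_SETS[code] if b in _BASE_INDEX)
            if mass >= coverage_threshold - 1e-12:
                out.append(code)
                break
    return IUPACPattern("".join(out))


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> -1."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def pwm_scan(
    seq: str,
    pwm: PWM,
    score_fraction: float = 0.8,
    bidirectional: bool = True,
    chrom: str = ".",
    offset: int = 0,
) -> list[tuple[MotifMatch, float]]:
    """Windows scoring >= score_fraction * max_score, on both strands.

    The score of a window is the sum of its per-column log2-odds; windows
    containing N are not scored.  Minus-strand windows are scored on the
    reverse complement and reported with strand '-' at their plus-strand
    footprint.
    """
    if not (0 < score_fraction <= 1):
        raise ValueError("score_fraction must lie in (0, 1]")
    seq = seq.upper()
    L = pwm.width
    if len(seq) < L:
        return []
    enc = _encode(seq)
    threshold = score_fraction * pwm.max_score
    n_windows = len(seq) - L + 1
    # sliding window of encoded bases
    idx = np.arange(n_windows)[:, None] + np.arange(L)[None, :]
    windows = enc[idx]  # n_windows x L
    valid = (windows >= 0).all(axis=1)
    results: list[tuple[MotifMatch, float]] = []

    def collect(mat: np.ndarray, strand: str) -> None:
        # mat is 4 x L, indexed [base, column]
        cols = np.arange(L)
        safe = np.where(windows >= 0, windows, 0)
        scores = mat[safe, cols].sum(axis=1)
        hits = np.flatnonzero(valid & (scores >= threshold - 1e-9))
        for i in hits:
            iv = GenomicInterval(chrom or ".", offset + int(i), offset + int(i) + L, strand)
            results.append(
                (MotifMatch(iv, strand, seq[i : i + L]), float(scores[i]))
            )

    collect(pwm.log_odds, "+")
    if bidirectional:
        # scoring the reverse complement of a window == scoring the window
        # itself with base rows complemented (A<->T, C<->G, i.e. reversed
        # row order) and columns reversed
        collect(pwm.log_odds[::-1, ::-1], "-")
    results.sort(key=lambda r: (r[0].interval.start, r[0].strand))
    return results


# ---------------------------------------------------------------------------
# JASPAR-style matrix I/O (4 labelled rows of integer counts)

def write_jaspar(pfm: PFM, name: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, b in enumerate(BASES):
            vals = " ".join(str(int(v)) for v in pfm.counts[i])
            fh.write(f"{b} [ {vals} ]\n")


def read_jaspar(path: str | Path) -> tuple[str, PFM]:
    name = ""
    rows: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base = line[0].upper()
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [int(float(x)) for x in body.split()]
    if set(rows) != set(BASES):
        raise ValueError(f"{path}: expected rows A, C, G, T; got {sorted(rows)}")
    counts = np.array([rows[b] for b in BASES], dtype=int)
    return name, PFM(counts, int(counts.sum(axis=0)[0]))
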