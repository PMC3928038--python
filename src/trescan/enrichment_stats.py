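"""Length-normalized motif occurrence rates and fold enrichment of peak
sets over a genomic background.

The central quantities are, per motif and region set:

* ``rate_per_bp`` — total bidirectional occurrences / total bp scanned,
* ``fraction_with_hit`` — share of regions containing >= 1 occurrence,
* ``fold_enrichment`` — foreground rate / background rate.

The default background for report-style folds is the whole genome
*including* peak regions (peaks are a negligible genome fraction at
mammalian scale); ``exclude_foreground`` switches to a genome-minus-peaks
denominator, which is the right contrast when the foreground occupies a
non-trivial share of the sequence scanned.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, Peak, extract_sequences
from .motif_scan import Motif, scan_motif

_N_RUN = re.compile("N+")

__all__ = [
    "OccurrenceStats",
    "EnrichmentResult",
    "count_motif_hits",
    "region_occurrences",
    "genome_occurrences",
    "fold_enrichment",
    "table1_report",
    "colocalization_z",
]


@dataclass(frozen=True)
class OccurrenceStats:
    """Occurrence summary for one motif over one region set."""

    n_regions: int
    n_regions_with_hit: int
    total_hits: int
    total_bp: int
    rate_per_bp: float
    fraction_with_hit: float  # NaN when n_regions == 0

    @classmethod
    def from_counts(
        cls, n_regions: int, n_with_hit: int, total_hits: int, total_bp: int
    ) -> "OccurrenceStats":
        rate = total_hits / total_bp if total_bp > 0 else 0.0
        frac = n_with_hit / n_regions if n_regions > 0 else math.nan
        return cls(n_regions, n_with_hit, total_hits, total_bp, rate, frac)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold enrichment of a motif in a foreground vs a background.

    ``fold_enrichment`` is NaN (flagged, not raised) when the background
    rate is zero.
    """

    motif_label: str
    foreground: OccurrenceStats
    background: OccurrenceStats
    fold_enrichment: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.fold_enrichment)


def count_motif_hits(seq: str, motif: Motif, bidirectional: bool = True) -> int:
    return len(scan_motif(seq, motif, bidirectional=bidirectional))


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals (overlaps merged), sorted by (chrom, start)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def region_occurrences(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    motif: Motif,
) -> OccurrenceStats:
    """Bidirectional occurrence stats over a region set.

    Hits are attributed to the region whose extracted sequence they start
    in; region bp is counted as-is (no merging), matching per-condition
    peak lists which are non-overlapping by peak-caller construction.
    """
    seqs = extract_sequences(regions, genome)
    n_with = 0
    total = 0
    bp = 0
    for seq in seqs:
        n = count_motif_hits(seq, motif)
        total += n
        n_with += 1 if n > 0 else 0
        bp += len(seq)
    return OccurrenceStats.from_counts(len(regions), n_with, total, bp)


def genome_occurrences(
    genome: Mapping[str, str],
    motif: Motif,
    exclude: Sequence[GenomicInterval] | None = None,
) -> OccurrenceStats:
    """Whole-genome occurrence stats, one region per contig.

    With ``exclude``, hits starting inside an excluded interval are
    dropped and the excluded bp removed from the denominator (the motif is
    still scanned in genomic context, so occurrences straddling an
    exclusion edge count if they start outside it).
    """
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    excl_bp = 0
    if exclude:
        for iv in merge_intervals(exclude):
            excl_by_chrom.setdefault(iv.chrom, []).append(iv)
            excl_bp += len(iv)
    n_regions = 0
    n_with = 0
    total = 0
    bp = 0
    for chrom, seq in genome.items():
        hits = scan_motif(seq, motif, chrom=chrom)
        if chrom in excl_by_chrom:
            spans = excl_by_chrom[chrom]
            starts = np.array([iv.start for iv in spans])
            ends = np.array([iv.end for iv in spans])
            kept = [
                h
                for h in hits
                if not np.any(
                    (starts <= h.interval.start) & (h.interval.start < ends)
                )
            ]
            hits = kept
        n_regions += 1
        n_with += 1 if hits else 0
        total += len(hits)
        bp += len(seq)
    return OccurrenceStats.from_counts(n_regions, n_with, total, bp - excl_bp)


def fold_enrichment(
    foreground_regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    motif: Motif,
    motif_label: str = "",
    background_regions: Sequence[GenomicInterval] | None = None,
    exclude_foreground: bool = False,
) -> EnrichmentResult:
    """Per-bp rate ratio of a motif in foreground regions vs a background.

    The background is either explicit regions, the whole genome (default),
    or the genome minus the foreground (``exclude_foreground=True``).
    """
    fg = region_occurrences(foreground_regions, genome, motif)
    if background_regions is not None:
        bg = region_occurrences(merge_intervals(background_regions), genome, motif)
    else:
        bg = genome_occurrences(
            genome,
            motif,
            exclude=foreground_regions if exclude_foreground else None,
        )
    fold = fg.rate_per_bp / bg.rate_per_bp if bg.rate_per_bp > 0 else math.nan
    return EnrichmentResult(motif_label, fg, bg, fold)


def table1_report(
    peak_sets_by_condition: Mapping[str, Sequence[Peak]],
    genome: Mapping[str, str],
    motif_list: Sequence[tuple[str, Motif]],
    exclude_foreground: bool = False,
) -> pd.DataFrame:
    """Occurrence / enrichment report: one row per (motif, condition).

    Columns: motif_label, notation, condition, pct_regions_with_hit,
    rate_per_bp, background_rate_per_bp, fold_enrichment, plus
    fraction_ratio (the region-fraction reading of enrichment) so either
    interpretation of a fold column can be checked.  Row order follows the
    motif list then the condition mapping.
    """
    rows = []
    for label, motif in motif_list:
        for condition, peaks in peak_sets_by_condition.items():
            regions = [p.interval for p in peaks]
            res = fold_enrichment(
                regions,
                genome,
                motif,
                motif_label=label,
                exclude_foreground=exclude_foreground,
            )
            bg = res.background
            # region-fraction reading: fraction of length-matched windows is
            # not observable genome-wide, so use per-contig fraction only for
            # the rate; emit the per-bp ratio and the raw pieces.
            rows.append(
                {
                    "motif_label": label,
                    "notation": str(motif),
                    "condition": condition,
                    "pct_regions_with_hit": 100.0 * res.foreground.fraction_with_hit,
                    "n_regions": res.foreground.n_regions,
                    "total_hits": res.foreground.total_hits,
                    "rate_per_bp": res.foreground.rate_per_bp,
                    "background_rate_per_bp": bg.rate_per_bp,
                    "fold_enrichment": res.fold_enrichment,
                }
            )
    return pd.DataFrame(rows)


def colocalization_z(
    peak_regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    motif: Motif,
    n_permutations: int = 1000,
    seed: int = 0,
    max_n_run_fraction: float = 0.5,
) -> float:
    """Permutation z-score for motif/peak co-localization.

    The observed bidirectional hit count inside the peaks is compared with
    a null built by dropping equally many length-matched intervals
    uniformly on the genome ``n_permutations`` times.  Placements whose
    longest N-run exceeds ``max_n_run_fraction`` of the placed length are
    resampled (assembly-gap-like N runs would deflate the null).  Returns
    NaN when the null is degenerate (sd 0).
    """
    if not peak_regions:
        raise ValueError("colocalization_z requires at least one peak region")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    obs = sum(
        count_motif_hits(s, motif) for s in extract_sequences(peak_regions, genome)
    )
    contigs = list(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    region_lens = [len(iv) for iv in peak_regions]
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        count = 0
        for rl in region_lens:
            for _ in range(100):  # resample budget per placement
                ci = rng.choice(len(contigs), p=probs)
                seq = genome[contigs[ci]]
                if len(seq) < rl:
                    continue
                start = int(rng.integers(0, len(seq) - rl + 1))
                sub = seq[start : start + rl]
                longest_n = max((len(r) for r in _N_RUN.findall(sub)), default=0)
                if longest_n <= max_n_run_fraction * rl:
                    count += count_motif_hits(sub, motif)
                    break
        null[p] = count
    sd = float(null.std(ddof=1))
    if sd == 0:
        return math.nan
    return (obs - float(null.mean())) / sd
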