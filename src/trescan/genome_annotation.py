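"""Peak-to-feature classification, genome composition, TSS profiles and
condition overlap.

Each genomic base (and each peak, via its midpoint) receives exactly one
feature class under the precedence

    promoter > 5'UTR > 3'UTR > exon > intron > downstream > intergenic

with promoter = the ``promoter_bp`` window upstream of a TSS and
downstream = the ``downstream_bp`` window past the transcript end, both
strand-aware.  Per-base genome labelling and per-peak classification share
one code path (a painted per-contig label array), which makes peak-class
fractions directly comparable to genome bp fractions — the ratio of the
two is the feature fold enrichment.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoordinateError, GeneModel, GenomicInterval, Peak

# overlap search window: intervals starting more than this many bp before a
# query cannot overlap it (generous bound on peak length)
_MAX_PEAK_SPAN = 1_000_000

__all__ = [
    "FeatureClass",
    "FeatureDistribution",
    "TssProfile",
    "GenomeLabeler",
    "classify_peak",
    "genome_feature_fractions",
    "feature_enrichment",
    "tss_profile",
    "condition_overlap",
]


class FeatureClass(IntEnum):
    """Feature classes in increasing precedence order (painting order)."""

    intergenic = 0
    downstream = 1
    intron = 2
    exon = 3
    three_utr = 4
    five_utr = 5
    promoter = 6

    def __str__(self) -> str:
        return self.name


CLASS_ORDER = [
    FeatureClass.promoter,
    FeatureClass.five_utr,
    FeatureClass.three_utr,
    FeatureClass.exon,
    FeatureClass.intron,
    FeatureClass.downstream,
    FeatureClass.intergenic,
]


def _gene_feature_spans(
    gene: GeneModel, promoter_bp: int, downstream_bp: int, contig_len: int
) -> dict[FeatureClass, list[tuple[int, int]]]:
    """Half-open spans per class contributed by one gene, clipped to the
    contig."""
    iv = gene.interval
    plus = iv.strand == "+"
    spans: dict[FeatureClass, list[tuple[int, int]]] = {c: [] for c in FeatureClass}

    def clip(a: int, b: int) -> tuple[int, int] | None:
        a, b = max(0, a), min(contig_len, b)
        return (a, b) if a < b else None

    prom = clip(iv.start - promoter_bp, iv.start) if plus else clip(iv.end, iv.end + promoter_bp)
    if prom:
        spans[FeatureClass.promoter].append(prom)
    down = clip(iv.end, iv.end + downstream_bp) if plus else clip(iv.start - downstream_bp, iv.start)
    if down:
        spans[FeatureClass.downstream].append(down)
    spans[FeatureClass.intron].append((iv.start, iv.end))
    cds_s, cds_e = gene.cds_start, gene.cds_end
    for ex in gene.exons:
        # split each exon into 5'UTR / CDS(exon) / 3'UTR parts
        left_utr = (ex.start, min(ex.end, cds_s))
        right_utr = (max(ex.start, cds_e), ex.end)
        coding = (max(ex.start, cds_s), min(ex.end, cds_e))
        five, three = (left_utr, right_utr) if plus else (right_utr, left_utr)
        if five[0] < five[1]:
            spans[FeatureClass.five_utr].append(five)
        if three[0] < three[1]:
            spans[FeatureClass.three_utr].append(three)
        if coding[0] < coding[1]:
            spans[FeatureClass.exon].append(coding)
    return spans


class GenomeLabeler:
    """Per-base feature labels for every contig.

    Classes are painted in increasing precedence, so the highest-precedence
    claim wins at every base — the single source of truth for both peak
    classification and genome composition.
    """

    def __init__(
        self,
        gene_models: Sequence[GeneModel],
        contig_lengths: Mapping[str, int],
        promoter_bp: int = 5000,
        downstream_bp: int = 5000,
    ) -> None:
        self.promoter_bp = promoter_bp
        self.downstream_bp = downstream_bp
        self.contig_lengths = dict(contig_lengths)
        self.labels: dict[str, np.ndarray] = {
            c: np.zeros(L, dtype=np.int8) for c, L in contig_lengths.items()
        }
        for gene in gene_models:
            iv = gene.interval
            if iv.chrom not in contig_lengths:
                raise CoordinateError(f"gene {gene.gene_id}: unknown contig {iv.chrom}")
            if iv.end > contig_lengths[iv.chrom]:
                raise CoordinateError(
                    f"gene {gene.gene_id} extends past contig "
                    f"{iv.chrom} ({iv.end} > {contig_lengths[iv.chrom]})"
                )
        by_chrom: dict[str, list[GeneModel]] = {}
        for gene in gene_models:
            by_chrom.setdefault(gene.interval.chrom, []).append(gene)
        for chrom, genes in by_chrom.items():
            arr = self.labels[chrom]
            L = len(arr)
            for cls in [
                FeatureClass.downstream,
                FeatureClass.intron,
                FeatureClass.exon,
                FeatureClass.three_utr,
                FeatureClass.five_utr,
                FeatureClass.promoter,
            ]:
                for gene in genes:
                    for a, b in _gene_feature_spans(
                        gene, promoter_bp, downstream_bp, L
                    )[cls]:
                        arr[a:b] = int(cls)

    def class_at(self, chrom: str, pos: int) -> FeatureClass:
        arr = self.labels.get(chrom)
        if arr is None or not (0 <= pos < len(arr)):
            return FeatureClass.intergenic
        return FeatureClass(int(arr[pos]))

    def genome_fractions(self) -> dict[FeatureClass, float]:
        total = sum(self.contig_lengths.values())
        counts = np.zeros(len(FeatureClass))
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(FeatureClass))
        return {c: counts[int(c)] / total for c in FeatureClass}


def classify_peak(
    peak: Peak | GenomicInterval,
    labeler: GenomeLabeler,
) -> FeatureClass:
    """Feature class of a peak's midpoint (single-class partition, so
    class fractions over a peak set sum to 1)."""
    iv = peak.interval if isinstance(peak, Peak) else peak
    return labeler.class_at(iv.chrom, iv.midpoint)


def genome_feature_fractions(
    gene_models: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    promoter_bp: int = 5000,
    downstream_bp: int = 5000,
) -> dict[FeatureClass, float]:
    """Per-class genome bp fractions under the shared precedence rule."""
    return GenomeLabeler(
        gene_models, contig_lengths, promoter_bp, downstream_bp
    ).genome_fractions()


@dataclass(frozen=True)
class FeatureDistribution:
    """Peak-class shares vs genome-class shares and their ratio."""

    peak_fraction: dict[FeatureClass, float]
    genome_fraction: dict[FeatureClass, float]
    fold: dict[FeatureClass, float]  # NaN where genome share is 0 with peaks
    n_peaks: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_class": str(c),
                "n_peaks": round(self.peak_fraction[c] * self.n_peaks),
                "pct_peaks": 100 * self.peak_fraction[c],
                "pct_genome": 100 * self.genome_fraction[c],
                "fold": self.fold[c],
            }
            for c in CLASS_ORDER
        ]
        return pd.DataFrame(rows)


def feature_enrichment(
    peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    promoter_bp: int = 5000,
    downstream_bp: int = 5000,
    labeler: GenomeLabeler | None = None,
) -> FeatureDistribution:
    """Fold enrichment of peak midpoints per feature class relative to the
    class's genome bp share."""
    if not peaks:
        raise ValueError("feature_enrichment requires at least one peak")
    if labeler is None:
        labeler = GenomeLabeler(gene_models, contig_lengths, promoter_bp, downstream_bp)
    counts = {c: 0 for c in FeatureClass}
    for p in peaks:
        counts[classify_peak(p, labeler)] += 1
    n = len(peaks)
    peak_frac = {c: counts[c] / n for c in FeatureClass}
    genome_frac = labeler.genome_fractions()
    fold = {}
    for c in FeatureClass:
        if genome_frac[c] > 0:
            fold[c] = peak_frac[c] / genome_frac[c]
        else:
            fold[c] = math.nan if peak_frac[c] > 0 else 0.0
    return FeatureDistribution(peak_frac, genome_frac, fold, n)


@dataclass(frozen=True)
class TssProfile:
    """Binned counts of peak midpoints by signed distance to the nearest
    TSS (upstream negative, orientation-corrected by gene strand)."""

    half_width: int
    bin_size: int
    bin_edges: np.ndarray  # len n_bins + 1, covers [-W, +W)
    counts: np.ndarray
    n_assigned: int

    def to_frame(self) -> pd.DataFrame:
        centers = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        return pd.DataFrame({"bin_center": centers.astype(int), "count": self.counts})


def tss_profile(
    peaks: Sequence[Peak],
    gene_models: Sequence[GeneModel],
    W: int = 10000,
    bin_size: int = 200,
) -> TssProfile:
    """Frequency profile of peak midpoints around the nearest TSS.

    Distance is ``midpoint - TSS`` for + strand genes and ``TSS - midpoint``
    for - strand genes, so negative is always upstream of the gene.  Peaks
    whose nearest-TSS distance falls outside [-W, +W) are excluded.
    """
    if W % bin_size != 0:
        raise ValueError("W must be a multiple of bin_size")
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.interval.chrom for g in gene_models}:
        genes = [g for g in gene_models if g.interval.chrom == chrom]
        pos = np.array([g.tss for g in genes])
        sign = np.array([1 if g.strand == "+" else -1 for g in genes])
        order = np.argsort(pos, kind="stable")
        tss_by_chrom[chrom] = (pos[order], sign[order])
    edges = np.arange(-W, W + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=int)
    assigned = 0
    for p in peaks:
        iv = p.interval
        entry = tss_by_chrom.get(iv.chrom)
        if entry is None:
            continue
        pos, sign = entry
        mid = iv.midpoint
        j = int(np.searchsorted(pos, mid))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(pos):
                d = abs(mid - pos[k])
                if best is None or d < best[0]:
                    best = (d, k)
        if best is None:
            continue
        k = best[1]
        signed = (mid - pos[k]) * sign[k]
        if -W <= signed < W:
            counts[int((signed + W) // bin_size)] += 1
            assigned += 1
    return TssProfile(W, bin_size, edges, counts, assigned)


def condition_overlap(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap_frac: float = 0.0,
) -> dict[str, float]:
    """Shared / condition-specific peak counts between two conditions.

    A peak is shared iff it reciprocally overlaps some peak of the other
    set by >= ``min_overlap_frac`` of each peak's length (default: any
    >= 1 bp overlap).  The unchanged fraction is (shared_a + shared_b) /
    (|A| + |B|) — shared peaks over all peaks of the union of the sets.
    """

    def shared_count(xs: Sequence[Peak], ys: Sequence[Peak]) -> int:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for p in ys:
            by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
        starts_by_chrom = {c: [iv.start for iv in ivs] for c, ivs in by_chrom.items()}
        n = 0
        for p in xs:
            iv = p.interval
            candidates = by_chrom.get(iv.chrom, [])
            j = bisect.bisect_left(starts_by_chrom.get(iv.chrom, []), iv.end)
            hit = False
            for c in reversed(candidates[:j]):
                if c.end <= iv.start:
                    # candidates are sorted by start; once one ends before
                    # this peak starts, only long earlier intervals could
                    # still overlap — keep scanning a bounded window
                    if iv.start - c.start > _MAX_PEAK_SPAN:
                        break
                    continue
                ov = iv.overlap_bp(c)
                if ov > 0 and (
                    min_overlap_frac <= 0
                    or (ov >= min_overlap_frac * len(iv) and ov >= min_overlap_frac * len(c))
                ):
                    hit = True
                    break
            if hit:
                n += 1
        return n

    shared_a = shared_count(peaks_a, peaks_b)
    shared_b = shared_count(peaks_b, peaks_a)
    total = len(peaks_a) + len(peaks_b)
    return {
        "a_only": len(peaks_a) - shared_a,
        "shared_a": shared_a,
        "shared_b": shared_b,
        "b_only": len(peaks_b) - shared_b,
        "fraction_shared": (shared_a + shared_b) / total if total else math.nan,
    }
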