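"""Synthetic study generator: genome, gene models, planted response
elements, condition-labelled peak sets and a two-group expression matrix.

The generator emulates the statistical structure of a nuclear-receptor
ChIP study in a hepatic cell background so that every analysis stage has a
planted ground truth at desk scale:

* an i.i.d. background genome at mammalian-like base composition,
* non-overlapping gene models with exon/UTR anatomy,
* response-element motifs planted at a low rate outside peaks and a
  higher rate inside them (the enrichment truth),
* two condition peak sets with a controlled shared fraction (the
  hormone-dependency truth),
* induced/repressed/null gene classes with log2 effect sizes and Gaussian
  noise, a stated fraction of induced genes receiving a motif-bearing
  peak near their TSS (the binding-association truth).

One global seed feeds a named sub-stream per stage, so stages can be
regenerated independently and the full bundle is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneModel,
    GenomicInterval,
    Peak,
    SequenceSet,
    write_bed,
    write_fasta,
    write_refflat,
)
from .motif_scan import DyadSpec, IUPACPattern, IUPAC_SETS, Motif, parse_motif_notation, reverse_complement

__all__ = [
    "MotifPlant",
    "SimulationConfig",
    "PlantRecord",
    "StudyBundle",
    "simulate_genome",
    "plant_motifs",
    "simulate_genes",
    "simulate_peaks",
    "simulate_expression",
    "simulate_study",
]

_STAGES = {"genome": 0, "plants": 1, "genes": 2, "peaks": 3, "expression": 4}
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class MotifPlant:
    """A motif to plant: rate per bp outside peaks and inside peaks."""

    notation: str
    background_rate: float
    in_peak_rate: float

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.in_peak_rate < 0:
            raise ConfigError("plant rates must be >= 0")
        parse_motif_notation(self.notation)  # validate eagerly


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults are desk-scale: a 2 x 1 Mb genome, 300 genes, 400 peaks per
    condition of which 30% are shared between conditions, a DR-4 element
    planted 10x denser inside peaks than outside, three replicates per
    expression group, and half of the induced genes given a motif-bearing
    peak within 25 kb of the TSS.
    """

    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    # A, C, G, T; ~41% GC, mammalian-like
    base_composition: tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (1_000, 4_000)
    exons_per_gene_range: tuple[int, int] = (1, 4)
    min_gene_gap: int = 1_000
    motif_plants: tuple[MotifPlant, ...] = (
        MotifPlant("AGGTCA-4-AGGTCA", 1e-4, 1e-3),
    )
    conditions: tuple[str, str] = ("untreated", "T3")
    n_peaks: int = 400
    peak_length_range: tuple[int, int] = (200, 500)
    shared_peak_fraction: float = 0.3
    n_induced: int = 40
    n_repressed: int = 20
    n_null: int = 240
    effect_log2: float = 1.5
    noise_sd: float = 0.25
    replicates: int = 3
    expr_base_mean: float = 8.0
    expr_base_sd: float = 1.0
    expr_offset: float = 50.0
    proximal_tre_fraction: float = 0.5
    proximal_distance: int = 25_000

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or not math.isclose(
            float(comp.sum()), 1.0, abs_tol=1e-9
        ):
            raise ConfigError("base_composition must be 4 probabilities summing to 1")
        if self.n_induced + self.n_repressed + self.n_null != self.n_genes:
            raise ConfigError(
                "n_induced + n_repressed + n_null must equal n_genes"
            )
        if not 0 <= self.shared_peak_fraction <= 1:
            raise ConfigError("shared_peak_fraction must lie in [0, 1]")
        if not 0 <= self.proximal_tre_fraction <= 1:
            raise ConfigError("proximal_tre_fraction must lie in [0, 1]")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        n_prox = round(self.proximal_tre_fraction * self.n_induced)
        if n_prox > round(self.shared_peak_fraction * self.n_peaks):
            raise ConfigError(
                "proximal peaks exceed the shared-peak quota; raise n_peaks "
                "or shared_peak_fraction"
            )

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGES[stage]])

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class PlantRecord:
    """One planted motif instance."""

    chrom: str
    start: int
    end: int
    strand: str
    notation: str
    context: str  # "background" | "peak" | "proximal"


# ---------------------------------------------------------------------------
# Genome

def simulate_genome(config: SimulationConfig) -> SequenceSet:
    """i.i.d. genome at the configured base composition (seed-reproducible)."""
    rng = config.rng("genome")
    comp = np.asarray(config.base_composition, dtype=float)
    out = SequenceSet()
    for name, length in config.contigs:
        idx = rng.choice(4, size=length, p=comp)
        out[name] = _BASE_BYTES[idx].tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# Genes and regulation truth

def _partition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Random non-negative integer composition of ``total`` into ``parts``."""
    if parts <= 0:
        return np.zeros(0, dtype=int)
    return rng.multinomial(total, np.full(parts, 1.0 / parts))


def simulate_genes(config: SimulationConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Non-overlapping gene models plus the regulation truth table.

    Genes are laid out left to right with random inter-gene gaps (at least
    ``min_gene_gap``), so placement never fails when the genome has room.
    Regulation classes are assigned uniformly at random over genes.
    """
    rng = config.rng("genes")
    lo, hi = config.gene_length_range
    ex_lo, ex_hi = config.exons_per_gene_range
    contig_lens = np.array([L for _, L in config.contigs], dtype=float)
    # genes per contig, proportional to length
    n_per = rng.multinomial(config.n_genes, contig_lens / contig_lens.sum())
    genes: list[GeneModel] = []
    gid = 0
    for (chrom, L), n in zip(config.contigs, n_per):
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        need = int(lengths.sum()) + config.min_gene_gap * (n + 1)
        if need > L:
            raise ConfigError(
                f"cannot place {n} genes totalling {int(lengths.sum())} bp on "
                f"{chrom} ({L} bp) with min gap {config.min_gene_gap}"
            )
        extra = _partition(L - need, n + 1, rng)
        pos = config.min_gene_gap + int(extra[0])
        for i in range(n):
            glen = int(lengths[i])
            start, end = pos, pos + glen
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(ex_lo, ex_hi + 1))
            genes.append(
                _make_gene(f"gene{gid:04d}", chrom, start, end, strand, n_exons, rng)
            )
            gid += 1
            pos = end + config.min_gene_gap + int(extra[i + 1])
    classes = (
        ["induced"] * config.n_induced
        + ["repressed"] * config.n_repressed
        + ["unchanged"] * config.n_null
    )
    perm = rng.permutation(len(genes))
    truth = pd.DataFrame(
        {
            "gene_id": [genes[i].gene_id for i in perm],
            "class": classes[: len(genes)],
        }
    ).sort_values("gene_id", ignore_index=True)
    effect = np.where(
        truth["class"] == "induced",
        config.effect_log2,
        np.where(truth["class"] == "repressed", -config.effect_log2, 0.0),
    )
    truth["effect_log2"] = effect
    return genes, truth


_MIN_SEGMENT = 50  # bp floor for exon/intron segments


def _make_gene(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    n_exons: int,
    rng: np.random.Generator,
) -> GeneModel:
    glen = end - start
    n_seg = 2 * n_exons - 1  # exon, intron, exon, ...
    while n_seg * _MIN_SEGMENT > glen and n_exons > 1:
        n_exons -= 1
        n_seg = 2 * n_exons - 1
    seg = _partition(glen - n_seg * _MIN_SEGMENT, n_seg, rng) + _MIN_SEGMENT
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    exons = tuple(
        GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]), strand)
        for i in range(0, n_seg, 2)
    )
    # CDS interior to the first/last exon, leaving UTR stubs on both ends
    utr5 = min(_MIN_SEGMENT // 2, (len(exons[0]) - 2) // 2)
    utr3 = min(_MIN_SEGMENT // 2, (len(exons[-1]) - 2) // 2)
    cds_start = exons[0].start + max(1, utr5)
    cds_end = exons[-1].end - max(1, utr3)
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        cds_start=cds_start,
        cds_end=cds_end,
        exons=exons,
    )


# ---------------------------------------------------------------------------
# Peaks

class _Pool:
    """Mutually non-overlapping interval pool with rejection insertion."""

    def __init__(self) -> None:
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.by_chrom.get(chrom, []))

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))


def simulate_peaks(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
) -> tuple[dict[str, list[Peak]], pd.DataFrame]:
    """Condition peak sets with a planted shared fraction, plus the
    proximal-binding truth table.

    All peaks (shared and condition-unique) are drawn into one mutually
    non-overlapping pool, so the planted shared fraction is recovered
    exactly: a peak is shared iff it was planted shared.  A configured
    fraction of induced genes receives a shared peak whose TSS gap is
    drawn uniformly within the proximal distance.
    """
    rng = config.rng("peaks")
    pool = _Pool()
    contig_len = dict(config.contigs)
    contig_names = [c for c, _ in config.contigs]
    weights = np.array([contig_len[c] for c in contig_names], dtype=float)
    weights /= weights.sum()
    plo, phi = config.peak_length_range

    def sample_len() -> int:
        return int(rng.integers(plo, phi + 1))

    def place_random() -> GenomicInterval:
        for _ in range(10_000):
            chrom = contig_names[int(rng.choice(len(contig_names), p=weights))]
            plen = sample_len()
            L = contig_len[chrom]
            if L < plen:
                continue
            start = int(rng.integers(0, L - plen + 1))
            if not pool.conflicts(chrom, start, start + plen):
                pool.add(chrom, start, start + plen)
                return GenomicInterval(chrom, start, start + plen)
        raise ConfigError("peak placement retry budget exceeded")

    n_shared = round(config.shared_peak_fraction * config.n_peaks)
    induced = truth.loc[truth["class"] == "induced", "gene_id"].tolist()
    n_prox = round(config.proximal_tre_fraction * len(induced))
    prox_genes = [induced[i] for i in rng.choice(len(induced), n_prox, replace=False)] if n_prox else []
    models = {g.gene_id: g for g in genes}

    prox_rows = []
    shared: list[GenomicInterval] = []
    for gid in prox_genes:
        g = models[gid]
        L = contig_len[g.interval.chrom]
        placed = None
        for _ in range(10_000):
            plen = sample_len()
            gap = int(rng.integers(0, config.proximal_distance + 1))
            upstream = rng.random() < 0.5
            if upstream:
                end = g.tss - gap
                start = end - plen
            else:
                start = g.tss + gap
                end = start + plen
            if start < 0 or end > L:
                continue
            if pool.conflicts(g.interval.chrom, start, end):
                continue
            pool.add(g.interval.chrom, start, end)
            placed = GenomicInterval(g.interval.chrom, start, end)
            break
        if placed is None:
            raise ConfigError(f"could not place proximal peak for {gid}")
        shared.append(placed)
        prox_rows.append(
            {
                "gene_id": gid,
                "chrom": placed.chrom,
                "start": placed.start,
                "end": placed.end,
                "tss_gap": max(0, placed.start - g.tss, g.tss - placed.end),
            }
        )
    while len(shared) < n_shared:
        shared.append(place_random())
    unique: dict[str, list[GenomicInterval]] = {
        cond: [place_random() for _ in range(config.n_peaks - n_shared)]
        for cond in config.conditions
    }
    peak_sets: dict[str, list[Peak]] = {}
    for cond in config.conditions:
        ivs = shared + unique[cond]
        scores = rng.gamma(shape=2.0, scale=3.0, size=len(ivs))
        peaks = [
            Peak(iv, score=float(s), condition=cond, name=f"{cond}_peak{i:04d}")
            for i, (iv, s) in enumerate(zip(ivs, scores))
        ]
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        peak_sets[cond] = peaks
    prox_truth = pd.DataFrame(
        prox_rows, columns=["gene_id", "chrom", "start", "end", "tss_gap"]
    )
    return peak_sets, prox_truth


# ---------------------------------------------------------------------------
# Motif planting

def _concretize(motif: Motif, rng: np.random.Generator) -> tuple[str, int | None]:
    """A concrete A/C/G/T instance of a motif; degenerate positions drawn
    uniformly over the code's base set (N over A/C/G/T)."""

    def draw(pattern: str) -> str:
        out = []
        for ch in pattern:
            choices = sorted(IUPAC_SETS[ch] - {"N"})
            out.append(choices[int(rng.integers(0, len(choices)))])
        return "".join(out)

    if isinstance(motif, DyadSpec):
        lo, hi = motif.spacer_range
        sp = int(rng.integers(lo, hi + 1))
        return draw(str(motif.left) + "N" * sp + str(motif.right)), sp
    return draw(str(motif)), None


def plant_motifs(
    genome: Mapping[str, str],
    config: SimulationConfig,
    peak_regions: Sequence[GenomicInterval] = (),
    guaranteed: Sequence[GenomicInterval] = (),
) -> tuple[SequenceSet, list[PlantRecord]]:
    """Write motif instances into the genome at Poisson-distributed,
    non-overlapping positions.

    Background plants fall outside ``peak_regions`` at each motif's
    background rate; in-peak plants fall inside them at the in-peak rate.
    Every interval in ``guaranteed`` additionally receives one centred
    instance of the first configured motif (used for TSS-proximal peaks).
    Instances never straddle a contig boundary; a strand is drawn for each
    and minus-strand instances are written as the reverse complement.
    """
    rng = config.rng("plants")
    arrs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    occupied = _Pool()
    peaks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    total_peak_bp = 0
    for iv in peak_regions:
        peaks_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        total_peak_bp += len(iv)
    ledger: list[PlantRecord] = []

    def in_peak(chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in peaks_by_chrom.get(chrom, []))

    def write(chrom: str, start: int, inst: str, notation: str, context: str) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        written = inst if strand == "+" else reverse_complement(inst)
        arrs[chrom][start : start + len(inst)] = written.encode()
        occupied.add(chrom, start, start + len(inst))
        ledger.append(
            PlantRecord(chrom, start, start + len(inst), strand, notation, context)
        )

    first_motif = (
        parse_motif_notation(config.motif_plants[0].notation)
        if config.motif_plants
        else None
    )
    for iv in guaranteed:
        if first_motif is None:
            break
        inst, _ = _concretize(first_motif, rng)
        start = iv.start + (len(iv) - len(inst)) // 2
        write(iv.chrom, start, inst, config.motif_plants[0].notation, "proximal")

    genome_bp = sum(len(s) for s in genome.values())
    bg_bp = genome_bp - total_peak_bp
    for plant_idx, plant in enumerate(config.motif_plants):
        motif = parse_motif_notation(plant.notation)
        for context, rate, target_bp in (
            ("background", plant.background_rate, bg_bp),
            ("peak", plant.in_peak_rate, total_peak_bp),
        ):
            if rate == 0 or target_bp == 0:
                continue
            n_plants = int(rng.poisson(rate * target_bp))
            if plant_idx == 0 and context == "peak":
                # the guaranteed TSS-proximal instances are in-peak
                # instances of this motif, not extras on top of the rate
                n_plants = max(0, n_plants - len(guaranteed))
            placed = 0
            budget = 200 * n_plants + 1000
            while placed < n_plants and budget > 0:
                budget -= 1
                inst, _ = _concretize(motif, rng)
                if context == "peak":
                    # pick a peak weighted by length, then a start within it
                    idx = int(rng.integers(0, len(peak_regions)))
                    piv = peak_regions[idx]
                    if len(piv) < len(inst):
                        continue
                    start = int(rng.integers(piv.start, piv.end - len(inst) + 1))
                    chrom = piv.chrom
                else:
                    chrom = list(genome)[int(rng.integers(0, len(genome)))]
                    L = len(genome[chrom])
                    if L < len(inst):
                        continue
                    start = int(rng.integers(0, L - len(inst) + 1))
                    if in_peak(chrom, start, start + len(inst)):
                        continue
                if occupied.conflicts(chrom, start, start + len(inst)):
                    continue
                write(chrom, start, inst, plant.notation, context)
                placed += 1
            if placed < n_plants:
                raise ConfigError(
                    f"could not place {n_plants} instances of {plant.notation} "
                    f"in {context} space; lower the rate"
                )
    out = SequenceSet({c: bytes(a).decode("ascii") for c, a in arrs.items()})
    return out, ledger


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Raw intensity matrix with planted group effects.

    Per gene: log2 level = baseline (+ effect in the treated group) +
    Gaussian noise; intensities are 2^level - offset (clipped at 0) so the
    downstream log2(x + offset) transform recovers the level exactly.
    """
    rng = config.rng("expression")
    group_a, group_b = "control", "treated"
    samples = [f"{group_a}_{i + 1}" for i in range(config.replicates)] + [
        f"{group_b}_{i + 1}" for i in range(config.replicates)
    ]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    n = len(truth)
    baseline = rng.normal(config.expr_base_mean, config.expr_base_sd, size=n)
    effect = truth["effect_log2"].to_numpy(dtype=float)
    levels = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        shift = effect if groups[s] == group_b else 0.0
        levels[:, j] = baseline + shift + rng.normal(0, config.noise_sd, size=n)
    raw = np.maximum(np.exp2(levels) - config.expr_offset, 0.0)
    df = pd.DataFrame(raw, index=truth["gene_id"], columns=samples)
    df.index.name = "gene_id"
    return df, groups


# ---------------------------------------------------------------------------
# Bundle

@dataclass
class StudyBundle:
    """A complete in-memory synthetic study plus its file layout."""

    config: SimulationConfig
    genome: SequenceSet
    genes: list[GeneModel]
    gene_truth: pd.DataFrame
    peak_sets: dict[str, list[Peak]]
    proximal_truth: pd.DataFrame
    plant_ledger: list[PlantRecord]
    expression: pd.DataFrame
    groups: dict[str, str]

    def peak_regions(self) -> list[GenomicInterval]:
        """Union pool of peak intervals across conditions (shared peaks
        listed once)."""
        seen = set()
        out = []
        for peaks in self.peak_sets.values():
            for p in peaks:
                key = (p.interval.chrom, p.interval.start, p.interval.end)
                if key not in seen:
                    seen.add(key)
                    out.append(p.interval)
        out.sort(key=lambda iv: (iv.chrom, iv.start))
        return out


def simulate_study(
    config: SimulationConfig, outdir: str | Path | None = None
) -> StudyBundle:
    """Generate the full study; optionally write the bundle to ``outdir``.

    Files written: genome.fa, genes.refflat, peaks_<condition>.bed,
    expression.tsv, groups.tsv, truth_genes.tsv, truth_proximal.tsv,
    truth_plants.tsv and manifest.json.  Re-running with the same config
    reproduces the files byte-identically.
    """
    genome = simulate_genome(config)
    genes, gene_truth = simulate_genes(config)
    peak_sets, proximal_truth = simulate_peaks(config, genes, gene_truth)
    all_regions: list[GenomicInterval] = []
    seen: set[tuple] = set()
    for peaks in peak_sets.values():
        for p in peaks:
            key = (p.interval.chrom, p.interval.start, p.interval.end)
            if key not in seen:
                seen.add(key)
                all_regions.append(p.interval)
    guaranteed = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in proximal_truth.itertuples(index=False)
    ]
    genome, ledger = plant_motifs(genome, config, all_regions, guaranteed)
    expression, groups = simulate_expression(config, gene_truth)
    bundle = StudyBundle(
        config=config,
        genome=genome,
        genes=genes,
        gene_truth=gene_truth,
        peak_sets=peak_sets,
        proximal_truth=proximal_truth,
        plant_ledger=ledger,
        expression=expression,
        groups=groups,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: StudyBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    write_fasta(bundle.genome, outdir / "genome.fa")
    files["genome"] = "genome.fa"
    write_refflat(bundle.genes, outdir / "genes.refflat")
    files["genes"] = "genes.refflat"
    for cond, peaks in bundle.peak_sets.items():
        name = f"peaks_{cond}.bed"
        write_bed(peaks, outdir / name)
        files[f"peaks_{cond}"] = name
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")
    files["expression"] = "expression.tsv"
    with open(outdir / "groups.tsv", "w") as fh:
        for sample, group in bundle.groups.items():
            fh.write(f"{sample}\t{group}\n")
    files["groups"] = "groups.tsv"
    bundle.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    bundle.proximal_truth.to_csv(outdir / "truth_proximal.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(r) for r in bundle.plant_ledger]).to_csv(
        outdir / "truth_plants.tsv", sep="\t", index=False
    )
    files["truth_genes"] = "truth_genes.tsv"
    files["truth_proximal"] = "truth_proximal.tsv"
    files["truth_plants"] = "truth_plants.tsv"
    manifest = {
        "seed": bundle.config.seed,
        "config_hash": bundle.config.config_hash(),
        "config": asdict(bundle.config),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
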