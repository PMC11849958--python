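"""Synthetic data generator with serialized ground truth.

Generates every input the pipeline consumes — genome, gene models, planted
NAD intervals, paired nucleolar/whole-cell bin counts, promoter peak sets
for three assays, and compartmentalized expression — from a single seeded
configuration, so each stage can be validated against a known truth.

The noise model: whole-cell counts are negative-binomial around a uniform
depth; nucleolar counts are negative-binomial around depth x enrichment
factor inside planted NADs (background factor elsewhere). Active genes
receive promoter-window peaks per assay subject to false-negative /
false-positive rates; expression is log-normal with a per-replicate noise
term, and nucleolar abundance is scaled by a retention or export
multiplier. Chromosome bias weights let NADs concentrate on chosen
chromosomes, emulating the strongly uneven chromosomal NAD distributions
seen in real nucleolar libraries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from bisect import bisect_left, insort
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomeAssembly,
    Interval,
    make_bins,
    merge_intervals,
    overlap,
    write_bed,
    write_chrom_sizes,
    write_gtf_genes,
)
from .nad_calling import BinCountTable
from .activity import PeakSet, promoter_interval
from .rna import ExpressionTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genome",
    "plant_nads",
    "simulate_truth",
    "simulate_bin_counts",
    "simulate_peaks",
    "simulate_expression",
    "simulate_dataset",
]

NON_CODING_BIOTYPES = ("lincRNA", "snoRNA", "miRNA", "antisense", "rRNA")
NON_CODING_WEIGHTS = (0.40, 0.25, 0.15, 0.15, 0.05)

# per-stage stream keys so each operation draws from an independent,
# call-order-insensitive substream of the configured seed
_STAGE = {"genome": 1, "nads": 2, "labels": 3, "counts": 4, "peaks": 5, "expr": 6}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed makes every output reproducible."""

    seed: int = 42
    n_chromosomes: int = 3
    chromosome_length: int = 20_000_000
    bin_size: int = 100_000
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    min_gene_gap: int = 6_000  # keeps promoter windows unambiguous
    protein_coding_fraction: float = 0.87
    nad_fraction: float = 0.25
    nad_enrichment_factor: float = 4.0
    background_factor: float = 1.0
    depth: float = 100.0
    dispersion: float = 10.0  # negative-binomial size; larger -> Poisson-like
    chrom_bias: tuple[float, ...] | None = None
    mean_segment_bins: float = 3.0
    active_fraction: float = 0.13  # of NAGs carrying all three marks
    peak_fnr: float = 0.05
    peak_fpr: float = 0.01
    peak_width_range: tuple[int, int] = (150, 400)
    promoter_window: tuple[int, int] = (-2000, 500)
    retained_fraction: float = 0.10  # of active genes with nucleolar-retained RNA
    retention_multiplier: float = 4.0
    export_multiplier: float = 0.25
    background_expressed_fraction: float = 0.5  # of non-NAG genes
    expr_log_mean: float = 3.0
    expr_log_sd: float = 1.0
    expr_noise_sd: float = 0.25
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < self.bin_size:
            raise ValueError("invalid genome geometry")
        if not 0 < self.nad_fraction < 1:
            raise ValueError("nad_fraction must lie in (0, 1)")
        for name in ("nad_enrichment_factor", "background_factor", "depth",
                     "dispersion", "retention_multiplier", "export_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("active_fraction", "peak_fnr", "peak_fpr",
                     "retained_fraction", "background_expressed_fraction",
                     "protein_coding_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.chrom_bias is not None and len(self.chrom_bias) != self.n_chromosomes:
            raise ValueError("chrom_bias must list one weight per chromosome")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Planted ground truth plus the configuration that produced it."""

    config: SimulationConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    nads: list[Interval]
    nag_ids: set[str]
    active_ids: set[str]
    retained_ids: set[str]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "chromosomes": self.assembly.sizes,
            "n_genes": len(self.genes),
            "nads": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                for iv in self.nads
            ],
            "nag_ids": sorted(self.nag_ids),
            "active_ids": sorted(self.active_ids),
            "retained_ids": sorted(self.retained_ids),
        }


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAssembly, list[GeneModel]]:
    """Uniform gene placement without overlap (rejection sampling).

    Genes keep a ``min_gene_gap`` buffer from each other so that promoter
    windows never span a neighboring gene. Biotypes are protein_coding
    with the configured probability, otherwise a weighted non-coding
    subclass.
    """
    rng = _rng(config, "genome")
    assembly = GenomeAssembly(
        {
            f"chr{i + 1}": config.chromosome_length
            for i in range(config.n_chromosomes)
        }
    )
    chroms = assembly.chroms
    lengths = np.array([assembly.length(c) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    spans: list[tuple[str, int, int]] = []
    lo, hi = config.gene_length_range
    gap = config.min_gene_gap
    tries = 0
    max_tries = 200 * config.n_genes
    while len(spans) < config.n_genes:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_genes} non-overlapping genes "
                f"after {max_tries} attempts; genome too crowded"
            )
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        glen = int(rng.integers(lo, hi + 1))
        if glen >= assembly.length(chrom):
            continue
        start = int(rng.integers(0, assembly.length(chrom) - glen))
        end = start + glen
        occ = placed[chrom]
        i = bisect_left(occ, (start, end))
        if i > 0 and occ[i - 1][1] + gap > start:
            continue
        if i < len(occ) and end + gap > occ[i][0]:
            continue
        insort(occ, (start, end))
        spans.append((chrom, start, end))
    spans.sort(key=lambda s: (chroms.index(s[0]), s[1]))
    n_coding = rng.random(len(spans)) < config.protein_coding_fraction
    subclasses = rng.choice(
        len(NON_CODING_BIOTYPES), size=len(spans), p=NON_CODING_WEIGHTS
    )
    strands = rng.choice(["+", "-"], size=len(spans))
    genes = [
        GeneModel(
            gene_id=f"G{i + 1:05d}",
            gene_name=f"GENE{i + 1}",
            chrom=chrom,
            start=start,
            end=end,
            strand=str(strands[i]),
            biotype="protein_coding"
            if n_coding[i]
            else NON_CODING_BIOTYPES[subclasses[i]],
        )
        for i, (chrom, start, end) in enumerate(spans)
    ]
    return assembly, genes


def plant_nads(config: SimulationConfig, assembly: GenomeAssembly) -> list[Interval]:
    """Plant NAD intervals as unions of whole bins.

    The number of NAD bins is the target fraction of all bins, allocated
    across chromosomes proportionally to ``chrom_bias`` weights (uniform
    by default); segments are seeded at random bins with geometric lengths
    until each chromosome's quota is met exactly.
    """
    rng = _rng(config, "nads")
    grid = make_bins(assembly, config.bin_size)
    chroms = assembly.chroms
    n_bins_per_chrom = np.array(
        [grid.chrom_slice(c).stop - grid.chrom_slice(c).start for c in chroms]
    )
    bias = (
        np.asarray(config.chrom_bias, dtype=float)
        if config.chrom_bias is not None
        else np.ones(len(chroms))
    )
    if (bias <= 0).any():
        raise ValueError("chromosome bias weights must be positive")
    target_total = int(round(config.nad_fraction * grid.n_bins))
    if target_total < 1:
        raise ValueError("target NAD fraction yields zero bins")
    weights = bias * n_bins_per_chrom
    quota = np.floor(target_total * weights / weights.sum()).astype(int)
    # largest-remainder rounding, then clamp to chromosome capacity
    remainder = target_total * weights / weights.sum() - quota
    for i in np.argsort(-remainder):
        if quota.sum() >= target_total:
            break
        quota[i] += 1
    for _ in range(len(chroms)):
        excess = quota - n_bins_per_chrom
        if (excess <= 0).all():
            break
        for i in np.flatnonzero(excess > 0):
            spill = quota[i] - n_bins_per_chrom[i]
            quota[i] = n_bins_per_chrom[i]
            room = np.flatnonzero(quota < n_bins_per_chrom)
            for j in room:
                take = min(spill, n_bins_per_chrom[j] - quota[j])
                quota[j] += take
                spill -= take
                if spill == 0:
                    break
    if quota.sum() != target_total:
        raise ValueError(
            "target NAD fraction unreachable with the given geometry"
        )
    intervals: list[Interval] = []
    p_geom = min(1.0, 1.0 / config.mean_segment_bins)
    for ci, chrom in enumerate(chroms):
        k = int(quota[ci])
        n = int(n_bins_per_chrom[ci])
        marked = np.zeros(n, dtype=bool)
        while marked.sum() < k:
            start = int(rng.integers(0, n))
            length = int(rng.geometric(p_geom))
            marked[start : start + length] = True
        # trim overshoot from the right so the quota is met exactly
        excess = int(marked.sum()) - k
        if excess:
            marked_idx = np.flatnonzero(marked)
            marked[marked_idx[-excess:]] = False
        sl = grid.chrom_slice(chrom)
        idx = np.flatnonzero(marked) + sl.start
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        for a, b in zip(run_starts, run_ends):
            intervals.append(
                Interval(chrom, int(grid.start[idx[a]]), int(grid.end[idx[b]]))
            )
    return intervals


def simulate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Genome, genes, planted NADs, and the derived gene-label truth.

    Planted NAGs are exactly the genes overlapping planted NADs; active
    genes are a random subset of NAGs; nucleolar-retained genes a random
    subset of the active set.
    """
    assembly, genes = simulate_genome(config)
    nads = plant_nads(config, assembly)
    nad_union = merge_intervals(nads)
    gene_ivs = [g.interval() for g in genes]
    nag_ids = {genes[gi].gene_id for gi, _, _ in overlap(gene_ivs, nad_union)}
    rng = _rng(config, "labels")
    nag_sorted = sorted(nag_ids)
    n_active = int(round(config.active_fraction * len(nag_sorted)))
    active_ids = set(
        rng.choice(nag_sorted, size=n_active, replace=False)
    ) if n_active else set()
    active_sorted = sorted(active_ids)
    n_retained = int(round(config.retained_fraction * len(active_sorted)))
    retained_ids = set(
        rng.choice(active_sorted, size=n_retained, replace=False)
    ) if n_retained else set()
    return SyntheticTruth(
        config=config,
        assembly=assembly,
        genes=genes,
        nads=nads,
        nag_ids=nag_ids,
        active_ids=active_ids,
        retained_ids=retained_ids,
    )


def _nb(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_bin_counts(truth: SyntheticTruth, config: SimulationConfig) -> BinCountTable:
    """Negative-binomial paired counts with planted enrichment.

    Whole-cell counts have mean ``depth`` everywhere; nucleolar counts
    have mean ``depth x nad_enrichment_factor`` in planted NAD bins and
    ``depth x background_factor`` elsewhere.
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(config, "counts")
    grid = make_bins(truth.assembly, config.bin_size)
    nad_mask = np.zeros(grid.n_bins, dtype=bool)
    for iv in truth.nads:
        first = grid.bin_index(iv.chrom, iv.start)
        last = grid.bin_index(iv.chrom, iv.end - 1)
        nad_mask[first : last + 1] = True
    factor = np.where(
        nad_mask, config.nad_enrichment_factor, config.background_factor
    )
    n_count = _nb(rng, np.full(grid.n_bins, config.depth), config.dispersion)
    no_count = _nb(rng, config.depth * factor, config.dispersion)
    return BinCountTable(grid, no_count, n_count)


def simulate_peaks(
    truth: SyntheticTruth, config: SimulationConfig
) -> dict[str, PeakSet]:
    """Promoter peak sets for ATAC, H3K4me3, and RNA Pol II.

    Each active gene receives a peak inside its promoter window per assay
    with probability 1 - fnr; each inactive gene with probability fpr.
    Peak positions and widths are jittered within the window.
    """
    rng = _rng(config, "peaks")
    wlo, whi = config.peak_width_range
    out: dict[str, PeakSet] = {}
    for assay in ("ATAC", "H3K4me3", "POL2"):
        intervals: list[Interval] = []
        for g in truth.genes:
            p = (
                1.0 - config.peak_fnr
                if g.gene_id in truth.active_ids
                else config.peak_fpr
            )
            if rng.random() >= p:
                continue
            prom = promoter_interval(g, config.promoter_window)
            width = int(rng.integers(wlo, whi + 1))
            width = min(width, prom.length)
            start = int(rng.integers(prom.start, prom.end - width + 1))
            intervals.append(
                Interval(
                    g.chrom,
                    start,
                    start + width,
                    name=f"{assay}_{g.gene_id}",
                    score=float(np.round(rng.uniform(10, 1000), 3)),
                )
            )
        out[assay] = PeakSet(assay=assay, sample="sim", intervals=intervals)
    return out


def simulate_expression(
    truth: SyntheticTruth, config: SimulationConfig
) -> ExpressionTable:
    """Raw abundances for nucleolar / total / nuclear compartments.

    Expressed genes (active NAGs plus a background fraction of non-NAG
    genes) draw a log-normal base level; nucleolar abundance is the base
    scaled by the retention multiplier for nucleolar-retained genes and
    the export multiplier otherwise. Silent genes are zero. Each
    replicate applies an independent log-normal noise term.
    """
    rng = _rng(config, "expr")
    gene_ids = [g.gene_id for g in truth.genes]
    expressed = set(truth.active_ids)
    for g in truth.genes:
        if g.gene_id not in truth.nag_ids:
            if rng.random() < config.background_expressed_fraction:
                expressed.add(g.gene_id)
    base = np.where(
        [gid in expressed for gid in gene_ids],
        rng.lognormal(config.expr_log_mean, config.expr_log_sd, len(gene_ids)),
        0.0,
    )
    mult_nucleolar = np.array(
        [
            config.retention_multiplier
            if gid in truth.retained_ids
            else config.export_multiplier
            for gid in gene_ids
        ]
    )
    columns: dict[str, np.ndarray] = {}
    compartments: dict[str, str] = {}
    for comp, mult in (
        ("nucleolar", mult_nucleolar),
        ("total", np.ones(len(gene_ids))),
        ("nuclear", np.ones(len(gene_ids))),
    ):
        for rep in range(1, config.n_replicates + 1):
            noise = (
                np.exp(rng.normal(0.0, config.expr_noise_sd, len(gene_ids)))
                if config.expr_noise_sd > 0
                else 1.0
            )
            sample = f"{comp}_{rep}"
            columns[sample] = np.round(base * mult * noise, 4)
            compartments[sample] = comp
    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionTable(values, compartments, normalized=False)


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> SyntheticTruth:
    """Generate the full dataset and write every file plus a manifest.

    Outputs under ``outdir``: chrom.sizes, genes.gtf, truth_nads.bed,
    bin_counts.tsv, peaks_<assay>.bed, expression.tsv, samples.tsv,
    truth.json, and manifest.json listing them all with the config digest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    counts = simulate_bin_counts(truth, config)
    peaks = simulate_peaks(truth, config)
    expression = simulate_expression(truth, config)

    files: dict[str, str] = {}

    def emit(key: str, filename: str, writer) -> None:
        path = outdir / filename
        writer(path)
        files[key] = filename

    emit("chrom_sizes", "chrom.sizes", lambda p: write_chrom_sizes(truth.assembly, p))
    emit("genes", "genes.gtf", lambda p: write_gtf_genes(truth.genes, p))
    emit("truth_nads", "truth_nads.bed", lambda p: write_bed(truth.nads, p))
    emit("bin_counts", "bin_counts.tsv", counts.to_tsv)
    for assay, ps in peaks.items():
        emit(
            f"peaks_{assay.lower()}",
            f"peaks_{assay.lower()}.bed",
            lambda p, ps=ps: write_bed(ps.intervals, p),
        )
    emit("expression", "expression.tsv", expression.to_tsv)

    def write_samples(path: Path) -> None:
        pd.DataFrame(
            {
                "sample": list(expression.compartments),
                "compartment": list(expression.compartments.values()),
                "replicate": [
                    int(s.rsplit("_", 1)[1]) for s in expression.compartments
                ],
            }
        ).to_csv(path, sep="\t", index=False)

    emit("samples", "samples.tsv", write_samples)
    emit(
        "truth",
        "truth.json",
        lambda p: Path(p).write_text(json.dumps(truth.to_dict(), indent=1)),
    )
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return truth
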