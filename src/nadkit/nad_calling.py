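"""NAD calling from paired nucleolar / whole-cell binned read counts.

A nucleolus-associated domain (NAD) is a genomic region whose purified
nucleolar DNA library (No) is enriched at least two-fold over the matched
whole-cell genomic library (N) in fixed-width bins (100 kb by default).
This module computes the library-size-normalized No/N ratio per bin, calls
NAD segments at an inclusive threshold, and derives genome-fraction,
per-chromosome and cross-sample sharing statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import BinGrid, GenomeAssembly, Interval, merge_intervals

__all__ = [
    "BinCountTable",
    "EnrichmentTrack",
    "NadSegment",
    "NadCallResult",
    "count_reads_in_bins",
    "compute_enrichment",
    "call_nads",
    "nad_genome_fraction",
    "chromosome_contribution",
    "shared_nad_fraction",
]


@dataclass
class BinCountTable:
    """Paired nucleolar (No) and whole-cell (N) read counts per grid bin."""

    grid: BinGrid
    no_count: np.ndarray
    n_count: np.ndarray

    def __post_init__(self) -> None:
        self.no_count = np.asarray(self.no_count, dtype=np.int64)
        self.n_count = np.asarray(self.n_count, dtype=np.int64)
        if len(self.no_count) != self.grid.n_bins:
            raise ValueError("no_count length does not match grid")
        if len(self.n_count) != self.grid.n_bins:
            raise ValueError("n_count length does not match grid")
        if (self.no_count < 0).any() or (self.n_count < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def no_total(self) -> int:
        return int(self.no_count.sum())

    @property
    def n_total(self) -> int:
        return int(self.n_count.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["no_count"] = self.no_count
        df["n_count"] = self.n_count
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, grid: BinGrid) -> "BinCountTable":
        df = pd.read_csv(path, sep="\t")
        required = {"bin_index", "no_count", "n_count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"count table lacks columns: {sorted(missing)}")
        df = df.sort_values("bin_index")
        if len(df) != grid.n_bins or not (
            df["bin_index"].to_numpy() == np.arange(grid.n_bins)
        ).all():
            raise ValueError("count table rows do not match grid bins")
        return cls(grid, df["no_count"].to_numpy(), df["n_count"].to_numpy())


@dataclass
class EnrichmentTrack:
    """Per-bin normalized No/N ratio and its log2, with the pseudocount used."""

    grid: BinGrid
    ratio: np.ndarray
    pseudocount: float
    background: str | None = "median"

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.ratio) != self.grid.n_bins:
            raise ValueError("ratio length does not match grid")
        if not np.all(np.isfinite(self.ratio)) or (self.ratio <= 0).any():
            raise ValueError("ratios must be finite and positive")

    @property
    def log2_ratio(self) -> np.ndarray:
        return np.log2(self.ratio)

    def to_bedgraph(self, path: str | Path, log2: bool = True) -> None:
        values = self.log2_ratio if log2 else self.ratio
        with open(path, "w") as fh:
            for c, s, e, v in zip(
                self.grid.chrom, self.grid.start, self.grid.end, values
            ):
                fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


@dataclass(frozen=True)
class NadSegment:
    """A maximal run of NAD-positive bins, merged into one interval."""

    interval: Interval
    n_bins: int
    mean_ratio: float
    max_ratio: float

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class NadCallResult:
    """NAD segments on an assembly plus the threshold and per-bin calls."""

    assembly: GenomeAssembly
    grid: BinGrid
    threshold: float
    segments: list[NadSegment]
    positive_bins: np.ndarray  # boolean mask over grid bins

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def nad_bp(self) -> int:
        return sum(seg.length for seg in self.segments)

    @property
    def nad_genome_fraction(self) -> float:
        """Percent of the assembly covered by NAD segments."""
        return 100.0 * self.nad_bp / self.assembly.total_length

    def chromosome_table(self) -> pd.DataFrame:
        """Per-chromosome NAD statistics.

        ``contribution`` is each chromosome's share of the total number of
        segments; ``bp_share`` its share of NAD-covered bp. Both sum to 1
        over chromosomes when any segment exists.
        """
        rows = []
        total_segments = self.n_segments
        total_bp = self.nad_bp
        for chrom in self.assembly:
            segs = [s for s in self.segments if s.interval.chrom == chrom]
            bp = sum(s.length for s in segs)
            rows.append(
                {
                    "chrom": chrom,
                    "n_segments": len(segs),
                    "nad_bp": bp,
                    "contribution": len(segs) / total_segments
                    if total_segments
                    else 0.0,
                    "bp_share": bp / total_bp if total_bp else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def intervals(self) -> list[Interval]:
        return [
            Interval(
                s.interval.chrom,
                s.interval.start,
                s.interval.end,
                name=f"NAD_{i + 1}",
                score=float(np.log2(s.mean_ratio)),
            )
            for i, s in enumerate(self.segments)
        ]

    def to_bed(self, path: str | Path) -> None:
        from .genome_io import write_bed

        write_bed(self.intervals(), path)


def count_reads_in_bins(
    reads: Sequence[Interval],
    grid: BinGrid,
    *,
    skip_unknown: bool = False,
) -> np.ndarray:
    """Assign each read placement to exactly one bin by its midpoint.

    Returns a per-bin count vector; the total equals the number of placed
    reads (conservation). Placements on chromosomes absent from the grid
    raise unless ``skip_unknown`` is set, in which case they are dropped
    with a warning.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    skipped = 0
    for read in reads:
        if read.chrom not in grid.assembly:
            if skip_unknown:
                skipped += 1
                continue
            raise ValueError(
                f"read on unknown chromosome {read.chrom!r}; "
                "pass skip_unknown=True to drop such reads"
            )
        counts[grid.bin_index(read.chrom, read.midpoint)] += 1
    if skipped:
        warnings.warn(
            f"skipped {skipped} reads on chromosomes absent from the grid",
            stacklevel=2,
        )
    return counts


def compute_enrichment(
    counts: BinCountTable,
    pseudocount: float = 0.5,
    background: str | None = "median",
) -> EnrichmentTrack:
    """Normalized nucleolar-to-genomic ratio per bin.

    The library-size ratio is
    r_i = ((no_i + a) / No_total) / ((n_i + a) / N_total), with pseudocount
    a > 0 keeping every ratio finite and positive; it is invariant under
    uniform rescaling of either library. With ``background="median"`` (the
    default) the ratios are additionally divided by their genome-wide
    median, correcting for the background shift that library-size scaling
    introduces when a sizeable genome fraction is enriched: a typical
    non-enriched bin then sits at r = 1, so a k-fold-enriched bin sits
    near r = k. The correction assumes enriched bins are a minority
    (< 50% of bins); ``background=None`` returns the plain library-size
    ratio.
    """
    if counts.no_total == 0:
        raise ValueError("empty nucleolar library (No_total == 0)")
    if counts.n_total == 0:
        raise ValueError("empty genomic library (N_total == 0)")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (
        (counts.no_count == 0).any() or (counts.n_count == 0).any()
    ):
        raise ValueError(
            "pseudocount 0 with zero-count bins would yield 0 or infinite "
            "ratios; use a positive pseudocount"
        )
    if background not in (None, "median"):
        raise ValueError(f"unknown background mode {background!r}")
    no = (counts.no_count + pseudocount) / counts.no_total
    n = (counts.n_count + pseudocount) / counts.n_total
    ratio = no / n
    if background == "median":
        ratio = ratio / np.median(ratio)
    return EnrichmentTrack(counts.grid, ratio, pseudocount, background)


def compute_enrichment_replicates(
    counts: Sequence[BinCountTable],
    pseudocount: float = 0.5,
    background: str | None = "median",
) -> EnrichmentTrack:
    """Combine replicate count tables into one track (geometric mean ratio)."""
    if not counts:
        raise ValueError("no replicate tables supplied")
    grid = counts[0].grid
    if any(c.grid.n_bins != grid.n_bins for c in counts):
        raise ValueError("replicate tables are on different grids")
    tracks = [compute_enrichment(c, pseudocount, background) for c in counts]
    ratio = np.exp(np.mean([np.log(t.ratio) for t in tracks], axis=0))
    return EnrichmentTrack(grid, ratio, pseudocount, background)


def call_nads(
    track: EnrichmentTrack,
    threshold: float = 2.0,
    max_gap_bins: int = 0,
) -> NadCallResult:
    """Call NAD segments from the enrichment track.

    A bin is NAD-positive iff its ratio is >= ``threshold`` (inclusive).
    Runs of positive bins on a chromosome separated by at most
    ``max_gap_bins`` negative bins are merged into one segment. With
    ``max_gap_bins=0`` the union of segments equals the union of positive
    bins exactly.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if max_gap_bins < 0:
        raise ValueError("max_gap_bins must be >= 0")
    grid = track.grid
    positive = track.ratio >= threshold
    segments: list[NadSegment] = []
    for chrom in grid.assembly:
        sl = grid.chrom_slice(chrom)
        pos_idx = np.flatnonzero(positive[sl]) + sl.start
        if len(pos_idx) == 0:
            continue
        run_start = pos_idx[0]
        prev = pos_idx[0]
        runs: list[tuple[int, int]] = []
        for idx in pos_idx[1:]:
            if idx - prev - 1 > max_gap_bins:
                runs.append((run_start, prev))
                run_start = idx
            prev = idx
        runs.append((run_start, prev))
        for first, last in runs:
            member = track.ratio[first : last + 1]
            member = member[member >= threshold]
            segments.append(
                NadSegment(
                    interval=Interval(
                        chrom, int(grid.start[first]), int(grid.end[last])
                    ),
                    n_bins=last - first + 1,
                    mean_ratio=float(member.mean()),
                    max_ratio=float(member.max()),
                )
            )
    return NadCallResult(
        assembly=grid.assembly,
        grid=grid,
        threshold=threshold,
        segments=segments,
        positive_bins=positive,
    )


def nad_genome_fraction(result: NadCallResult) -> float:
    """Percent of the assembly covered by NAD segments."""
    return result.nad_genome_fraction


def chromosome_contribution(result: NadCallResult) -> pd.DataFrame:
    """Per-chromosome share of NAD segments and NAD bp (each sums to 1)."""
    if result.n_segments == 0:
        raise ValueError("no NAD segments called")
    return result.chromosome_table()


def shared_nad_fraction(a: NadCallResult, b: NadCallResult) -> float:
    """Fraction of a's NAD bp that lies inside b's NADs.

    Directional: shared_nad_fraction(a, b) is the share of *a*'s NAD
    territory also called in *b*; it is 1 when a == b and generally not
    symmetric.
    """
    if a.assembly != b.assembly:
        raise ValueError("NAD calls are on different assemblies")
    a_bp = a.nad_bp
    if a_bp == 0:
        raise ValueError("first NAD call has no segments")
    b_merged = merge_intervals([s.interval for s in b.segments]) if b.segments else []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    shared = 0
    for seg in a.segments:
        for iv in by_chrom.get(seg.interval.chrom, []):
            shared += max(
                0,
                min(seg.interval.end, iv.end)
                - max(seg.interval.start, iv.start),
            )
    return shared / a_bp
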