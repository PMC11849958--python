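"""Multi-omic activity integration for nucleolus-associated genes.

Combines ATAC accessibility, H3K4me3, and RNA Pol II peak sets with a NAG
set to classify transcriptionally active NAGs: a NAG is "active" when its
promoter carries an ATAC peak, an H3K4me3 peak, and a Pol II peak (the
triple mark). Also provides cross-sample Merged Regions — connected
components of the peak-overlap graph, spanned from the most upstream start
to the most downstream end — peak-to-gene annotation, and strand-aware TSS
metaprofiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneModel, Interval
from .nag_annotation import NagSet

__all__ = [
    "ASSAYS",
    "PeakSet",
    "MergedRegion",
    "PeakAnnotation",
    "GeneActivityProfile",
    "SummaryRow",
    "promoter_interval",
    "build_merged_regions",
    "peak_overlap_fraction",
    "annotate_peaks",
    "tss_profile",
    "classify_active_nags",
]

ASSAYS = ("ATAC", "H3K4me3", "H3K9me3", "H3K27me3", "POL2")

#: promoter window around the TSS in transcription orientation:
#: 2 kb upstream to 500 bp downstream.
DEFAULT_PROMOTER_WINDOW = (-2000, 500)


@dataclass
class PeakSet:
    """Peaks from one assay in one sample."""

    assay: str
    sample: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        if not self.assay:
            raise ValueError("assay label is mandatory")
        if self.assay not in ASSAYS:
            warnings.warn(f"unrecognized assay label {self.assay!r}", stacklevel=2)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class MergedRegion:
    """A connected component of overlapping peaks across samples.

    The interval spans from the minimum start to the maximum end of the
    member peaks; ``presence`` flags which samples contribute a peak.
    """

    interval: Interval
    presence: dict[str, bool]
    members: list[tuple[str, int]]  # (sample, peak index within its set)


@dataclass
class PeakAnnotation:
    """Per-peak genomic category and target gene."""

    peaks: PeakSet
    table: pd.DataFrame  # peak_index, chrom, start, end, category, gene_id, tss_distance

    def category_counts(self) -> dict[str, int]:
        return self.table["category"].value_counts().to_dict()

    def promoter_gene_ids(self) -> set[str]:
        mask = self.table["category"] == "promoter"
        return set(self.table.loc[mask, "gene_id"].dropna())

    def gene_ids(self) -> set[str]:
        mask = self.table["category"].isin(["promoter", "gene_body"])
        return set(self.table.loc[mask, "gene_id"].dropna())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class GeneActivityProfile:
    """Per-gene activity flags for a NAG set, with the triple-mark call."""

    table: pd.DataFrame  # gene_id, atac_gene, atac_promoter, h3k4me3, pol2, double, active
    assays_used: list[str]

    @property
    def active_gene_ids(self) -> set[str]:
        return set(self.table.loc[self.table["active"], "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SummaryRow:
    """One cell line's NAG activity summary (Table-2-style layout)."""

    cell_line: str
    n_nad: int | None = None
    n_nag: int = 0
    n_nag_accessible: int = 0
    n_nag_promoter_accessible: int = 0
    n_nag_h3k4me3: int = 0
    n_nag_pol2: int = 0
    n_double: int = 0
    n_triple: int = 0
    n_nuclear_transcript: int | None = None
    n_nuclear_transcript_coding: int | None = None
    n_nuclear_transcript_non_coding: int | None = None
    n_nucleolar_transcript: int | None = None
    n_nucleolar_transcript_coding: int | None = None
    n_nucleolar_transcript_non_coding: int | None = None

    def validate(self) -> None:
        if self.n_triple > min(
            self.n_nag_promoter_accessible, self.n_nag_h3k4me3, self.n_nag_pol2
        ):
            raise ValueError("triple-marked count exceeds a constituent count")
        for name in (
            "n_nag_accessible",
            "n_nag_promoter_accessible",
            "n_nag_h3k4me3",
            "n_nag_pol2",
            "n_triple",
        ):
            if getattr(self, name) > self.n_nag:
                raise ValueError(f"{name} exceeds NAG count")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def promoter_interval(
    gene: GeneModel,
    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> Interval:
    """Promoter window around the TSS, oriented by strand and clipped at 0.

    ``window = (w0, w1)`` selects positions whose signed offset o from the
    TSS (positive downstream in transcription direction) satisfies
    w0 <= o < w1.
    """
    w0, w1 = window
    if w0 >= w1:
        raise ValueError("promoter window must satisfy w0 < w1")
    t = gene.tss
    if gene.strand == "+":
        start, end = t + w0, t + w1
    else:
        start, end = t - w1 + 1, t - w0 + 1
    return Interval(gene.chrom, max(0, start), max(1, end), name=gene.gene_id)


def build_merged_regions(peaksets: Sequence[PeakSet]) -> list[MergedRegion]:
    """Group overlapping peaks across samples into Merged Regions.

    Regions are the connected components of the overlap graph over the
    union of all peaks; each region spans from the start of its most
    upstream member to the end of its most downstream member. A sorted
    sweep suffices because interval-overlap components are contiguous in
    (chrom, start) order.
    """
    if len(peaksets) < 1:
        raise ValueError("need at least one peak set")
    samples = [ps.sample for ps in peaksets]
    if len(set(samples)) != len(samples):
        raise ValueError("peak sets must carry distinct sample labels")
    if len({ps.assay for ps in peaksets}) > 1:
        warnings.warn(
            "merging peak sets from different assays: "
            + ", ".join(sorted({ps.assay for ps in peaksets})),
            stacklevel=2,
        )
    records = [
        (iv.chrom, iv.start, iv.end, ps.sample, i)
        for ps in peaksets
        for i, iv in enumerate(ps.intervals)
    ]
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    regions: list[MergedRegion] = []

    def flush(chrom: str, start: int, end: int, members: list[tuple[str, int]]):
        presence = {s: False for s in samples}
        for sample, _ in members:
            presence[sample] = True
        regions.append(
            MergedRegion(Interval(chrom, start, end), presence, list(members))
        )

    cur: tuple[str, int, int] | None = None
    members: list[tuple[str, int]] = []
    for chrom, start, end, sample, idx in records:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur = (chrom, cur[1], max(cur[2], end))
            members.append((sample, idx))
        else:
            if cur is not None:
                flush(*cur, members)
            cur = (chrom, start, end)
            members = [(sample, idx)]
    if cur is not None:
        flush(*cur, members)
    return regions


def peak_overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of a's peaks lying in Merged Regions that also contain b.

    Reproduces cross-sample peak sharing statements such as "x% of
    sample A's peaks overlap those of sample B"; directional in general.
    """
    if len(a) == 0:
        raise ValueError("first peak set is empty")
    a_label, b_label = "__a__", "__b__"
    regions = build_merged_regions(
        [
            PeakSet(a.assay, a_label, a.intervals),
            PeakSet(b.assay, b_label, b.intervals),
        ]
    )
    shared = sum(
        sum(1 for s, _ in reg.members if s == a_label)
        for reg in regions
        if reg.presence[b_label]
    )
    return shared / len(a)


def _tree(intervals: Sequence[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> PeakAnnotation:
    """Assign each peak a category (promoter > gene_body > intergenic).

    A peak overlapping any promoter window is a promoter peak; otherwise a
    peak overlapping a gene body is a gene_body peak; otherwise intergenic.
    When several genes compete, the target is the gene with the nearest TSS
    to the peak midpoint, ties broken by lexicographically smallest
    gene_id. ``tss_distance`` is the unsigned midpoint-to-nearest-TSS
    distance over all genes on the chromosome.
    """
    promoter_trees = _tree([promoter_interval(g, promoter_window) for g in genes])
    body_trees = _tree([g.interval() for g in genes])
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))

    def pick(gene_indices: set[int], mid: int) -> str:
        return min(
            gene_indices,
            key=lambda gi: (abs(mid - genes[gi].tss), genes[gi].gene_id),
        )

    rows = []
    for pi, iv in enumerate(peaks.intervals):
        mid = iv.midpoint
        tss_list = tss_by_chrom.get(iv.chrom, [])
        tss_distance = (
            min(abs(mid - t) for t, _ in tss_list) if tss_list else np.nan
        )
        prom_hits = {
            h.data
            for h in promoter_trees.get(iv.chrom, IntervalTree()).overlap(
                iv.start, iv.end
            )
        }
        if prom_hits:
            gi = pick(prom_hits, mid)
            category, gene_id = "promoter", genes[gi].gene_id
        else:
            body_hits = {
                h.data
                for h in body_trees.get(iv.chrom, IntervalTree()).overlap(
                    iv.start, iv.end
                )
            }
            if body_hits:
                gi = pick(body_hits, mid)
                category, gene_id = "gene_body", genes[gi].gene_id
            else:
                category, gene_id = "intergenic", None
        rows.append(
            {
                "peak_index": pi,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "category": category,
                "gene_id": gene_id,
                "tss_distance": tss_distance,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "peak_index",
            "chrom",
            "start",
            "end",
            "category",
            "gene_id",
            "tss_distance",
        ],
    )
    return PeakAnnotation(peaks=peaks, table=table)


def tss_profile(
    signal: PeakSet | Sequence[Interval],
    genes: Sequence[GeneModel],
    window: int = 2000,
    n_bins: int = 40,
) -> np.ndarray:
    """Mean binary occupancy around TSSs, strand-aware.

    For each gene the +/-``window`` bp region around the TSS is scanned in
    transcription orientation (minus-strand genes are flipped), peak
    occupancy is marked per bp, and the per-bp average over genes is
    pooled into ``n_bins`` equal bins. Returns an array of length
    ``n_bins`` with values in [0, 1].
    """
    if len(genes) == 0:
        raise ValueError("need at least one gene")
    span = 2 * window
    if span % n_bins != 0:
        raise ValueError(f"window span {span} not divisible by n_bins {n_bins}")
    intervals = signal.intervals if isinstance(signal, PeakSet) else list(signal)
    trees = _tree(intervals)
    acc = np.zeros(span, dtype=float)
    for g in genes:
        occ = np.zeros(span, dtype=float)
        lo, hi = g.tss - window, g.tss + window
        tree = trees.get(g.chrom)
        if tree is not None:
            for hit in tree.overlap(max(0, lo), hi):
                s = max(hit.begin, lo) - lo
                e = min(hit.end, hi) - lo
                if e > s:
                    occ[s:e] = 1.0
        if g.strand == "-":
            occ = occ[::-1]
        acc += occ
    acc /= len(genes)
    return acc.reshape(n_bins, span // n_bins).mean(axis=1)


def _promoter_flag(
    peakset: PeakSet,
    genes_by_id: Mapping[str, GeneModel],
    promoter_window: tuple[int, int],
) -> dict[str, bool]:
    trees = _tree(peakset.intervals)
    flags = {}
    for gid, g in genes_by_id.items():
        prom = promoter_interval(g, promoter_window)
        tree = trees.get(g.chrom)
        flags[gid] = bool(tree is not None and tree.overlap(prom.start, prom.end))
    return flags


def classify_active_nags(
    nags: NagSet,
    genes: Sequence[GeneModel],
    atac: PeakAnnotation | None = None,
    h3k4me3: PeakSet | None = None,
    pol2: PeakSet | None = None,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    cell_line: str | None = None,
    n_nad: int | None = None,
) -> tuple[GeneActivityProfile, SummaryRow]:
    """Triple-mark activity classification of NAGs.

    Flags per NAG: ``atac_gene`` / ``atac_promoter`` from the ATAC peak
    annotation (peaks targeted to the gene, promoter category for the
    promoter flag); ``h3k4me3`` and ``pol2`` from any peak of that assay
    overlapping the gene's promoter window. ``active`` is the conjunction
    of atac_promoter, h3k4me3, and pol2; ``double`` the H3K4me3+Pol II
    conjunction. Missing assay inputs are excluded from the conjunction
    and reported via ``assays_used`` (with a warning).
    """
    if len(nags) == 0:
        raise ValueError("empty NAG set")
    nag_ids = nags.gene_ids
    genes_by_id = {g.gene_id: g for g in genes if g.gene_id in nag_ids}
    missing = nag_ids - set(genes_by_id)
    if missing:
        raise ValueError(
            f"{len(missing)} NAG ids missing from gene models, "
            f"e.g. {sorted(missing)[:3]}"
        )
    order = list(nags.table["gene_id"])
    flags: dict[str, dict[str, bool]] = {}
    assays_used: list[str] = []
    if atac is not None:
        atac_any = atac.gene_ids()
        atac_prom = atac.promoter_gene_ids()
        flags["atac_gene"] = {gid: gid in atac_any for gid in order}
        flags["atac_promoter"] = {gid: gid in atac_prom for gid in order}
        assays_used.append("ATAC")
    if h3k4me3 is not None:
        flags["h3k4me3"] = _promoter_flag(h3k4me3, genes_by_id, promoter_window)
        assays_used.append("H3K4me3")
    if pol2 is not None:
        flags["pol2"] = _promoter_flag(pol2, genes_by_id, promoter_window)
        assays_used.append("POL2")
    if len(assays_used) < 3:
        warnings.warn(
            "missing assay inputs; 'active' is the conjunction over "
            f"available assays only: {assays_used}",
            stacklevel=2,
        )
    table = pd.DataFrame({"gene_id": order})
    for col in ("atac_gene", "atac_promoter", "h3k4me3", "pol2"):
        table[col] = (
            [flags[col][gid] for gid in order] if col in flags else pd.NA
        )
    active_cols = [
        c for c in ("atac_promoter", "h3k4me3", "pol2") if c in flags
    ]
    conj = np.ones(len(order), dtype=bool)
    for c in active_cols:
        conj &= table[c].to_numpy(dtype=bool)
    table["double"] = (
        table["h3k4me3"].to_numpy(dtype=bool)
        & table["pol2"].to_numpy(dtype=bool)
        if {"h3k4me3", "pol2"} <= set(flags)
        else pd.NA
    )
    table["active"] = conj if active_cols else False
    profile = GeneActivityProfile(table=table, assays_used=assays_used)

    def count(col: str) -> int:
        return int(table[col].sum()) if col in flags else 0

    summary = SummaryRow(
        cell_line=cell_line if cell_line is not None else nags.cell_line,
        n_nad=n_nad,
        n_nag=len(nags),
        n_nag_accessible=count("atac_gene"),
        n_nag_promoter_accessible=count("atac_promoter"),
        n_nag_h3k4me3=count("h3k4me3"),
        n_nag_pol2=count("pol2"),
        n_double=int(table["double"].sum())
        if {"h3k4me3", "pol2"} <= set(flags)
        else 0,
        n_triple=int(table["active"].sum()) if len(assays_used) == 3 else 0,
    )
    summary.validate()
    return profile, summary
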