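"""Genome model, interval arithmetic, and readers/writers for standard formats.

All coordinates are 0-based half-open internally. BED is the native
convention; GTF (1-based closed) is converted on read. The genome assembly
is supplied as a ``chrom.sizes`` file and never hard-coded, so the same
pipeline runs on real assemblies and on synthetic desk-scale genomes alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeAssembly",
    "Interval",
    "BinGrid",
    "GeneModel",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "make_bins",
    "read_bed",
    "write_bed",
    "read_gtf_genes",
    "write_gtf_genes",
    "overlap",
    "overlap_length",
    "merge_intervals",
]


class GenomeAssembly:
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        seen: dict[str, int] = {}
        for name, length in items:
            if name in seen:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length < 1:
                raise ValueError(f"non-positive length for {name!r}: {length}")
            seen[name] = length
        if not seen:
            raise ValueError("assembly has no chromosomes")
        self._sizes = seen

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self._sizes)

    @property
    def chroms(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def length(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __len__(self) -> int:
        return len(self._sizes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAssembly):
            return NotImplemented
        return self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"GenomeAssembly({len(self)} chromosomes, {self.total_length:,} bp)"


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally named/scored/stranded."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=True)
    score: float | None = field(default=None, compare=True)
    strand: str | None = field(default=None, compare=True)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"unknown strand symbol: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and max(
            self.start, other.start
        ) < min(self.end, other.end)

    def validate(self, assembly: GenomeAssembly) -> None:
        if self.chrom not in assembly:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > assembly.length(self.chrom):
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {assembly.length(self.chrom)}"
            )


class BinGrid:
    """Fixed-width tiling of an assembly (default 100 kb bins).

    Bins within a chromosome are adjacent, non-overlapping, and tile it
    completely; only the terminal bin of a chromosome may be shorter than
    ``bin_size``. Each bin has a stable integer index over the whole grid.
    """

    def __init__(self, assembly: GenomeAssembly, bin_size: int = 100_000):
        if bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {bin_size}")
        self.assembly = assembly
        self.bin_size = int(bin_size)
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        self._offset: dict[str, int] = {}
        for chrom in assembly:
            length = assembly.length(chrom)
            self._offset[chrom] = len(starts)
            n = -(-length // bin_size)  # ceil division
            for i in range(n):
                chroms.append(chrom)
                starts.append(i * bin_size)
                ends.append(min((i + 1) * bin_size, length))
        self.chrom = np.array(chroms, dtype=object)
        self.start = np.array(starts, dtype=np.int64)
        self.end = np.array(ends, dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def bin_lengths(self) -> np.ndarray:
        return self.end - self.start

    def bin_index(self, chrom: str, pos: int) -> int:
        """Grid index of the bin containing position ``pos`` on ``chrom``."""
        if chrom not in self._offset:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if pos < 0 or pos >= self.assembly.length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offset[chrom] + pos // self.bin_size

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offset[chrom]
        n = -(-self.assembly.length(chrom) // self.bin_size)
        return slice(off, off + n)

    def intervals(self) -> list[Interval]:
        return [
            Interval(c, int(s), int(e))
            for c, s, e in zip(self.chrom, self.start, self.end)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
            }
        )

    def __repr__(self) -> str:
        return (
            f"BinGrid({len(self.assembly)} chromosomes, "
            f"{self.n_bins} bins of {self.bin_size:,} bp)"
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with coordinates, strand, and biotype.

    The TSS is the 5' end in transcription orientation: ``start`` on the
    plus strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid gene span for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"unknown strand symbol {self.strand!r} for {self.gene_id}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"

    def interval(self) -> Interval:
        return Interval(
            self.chrom, self.start, self.end, name=self.gene_id,
            strand=self.strand,
        )


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a two-column ``chrom.sizes`` file, preserving file order."""
    pairs: list[tuple[str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: malformed line: {line!r}")
        try:
            length = int(fields[1])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: non-integer length {fields[1]!r}"
            ) from exc
        pairs.append((fields[0], length))
    return GenomeAssembly(pairs)


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in assembly:
            fh.write(f"{chrom}\t{assembly.length(chrom)}\n")


def make_bins(assembly: GenomeAssembly, bin_size: int = 100_000) -> BinGrid:
    """Tile every chromosome into fixed-width bins (terminal bins truncated)."""
    return BinGrid(assembly, bin_size)


def read_bed(
    path: str | Path, assembly: GenomeAssembly | None = None
) -> list[Interval]:
    """Read BED3+ records; columns beyond the canonical six are ignored."""
    out: list[Interval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            f = line.split()
        if len(f) < 3:
            raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        if start >= end:
            raise ValueError(
                f"{path}:{lineno}: start >= end ({start} >= {end})"
            )
        name = f[3] if len(f) > 3 and f[3] != "." else None
        score = float(f[4]) if len(f) > 4 and f[4] != "." else None
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
        iv = Interval(chrom, start, end, name=name, score=score, strand=strand)
        if assembly is not None:
            iv.validate(assembly)
        out.append(iv)
    return out


def _bed_line(iv: Interval) -> str:
    fields = [iv.chrom, str(iv.start), str(iv.end)]
    if iv.name is not None or iv.score is not None or iv.strand is not None:
        fields.append(iv.name if iv.name is not None else ".")
    if iv.score is not None or iv.strand is not None:
        fields.append(format(iv.score, "g") if iv.score is not None else ".")
    if iv.strand is not None:
        fields.append(iv.strand)
    return "\t".join(fields)


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write intervals as BED3/BED6; round-trips through :func:`read_bed`."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(_bed_line(iv) + "\n")


def read_gtf_genes(
    path: str | Path,
    *,
    id_key: str = "gene_id",
    name_key: str = "gene_name",
    biotype_key: str = "gene_biotype",
) -> list[GeneModel]:
    """Read gene feature lines from a GTF (Ensembl attribute dialect).

    Coordinates are converted from GTF 1-based closed to 0-based half-open.
    Attribute keys are configurable to accommodate dialects that use e.g.
    ``gene_type`` instead of ``gene_biotype``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        attrs = feat.attributes
        if id_key not in attrs:
            raise ValueError(
                f"gene feature at {feat.seqid}:{feat.start} lacks {id_key!r}"
            )
        gene_id = attrs[id_key][0]
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"unknown strand symbol {feat.strand!r} for gene {gene_id}"
            )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=attrs[name_key][0] if name_key in attrs else gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                biotype=attrs[biotype_key][0]
                if biotype_key in attrs
                else "protein_coding",
            )
        )
    return genes


def write_gtf_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF gene feature lines (1-based closed coords)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tnadkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def overlap_length(a: Interval, b: Interval) -> int:
    """Overlap in bp between two intervals (0 if disjoint or trans)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _trees_by_chrom(intervals: Sequence[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees

def overlap(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[tuple[int, int, int]]:
    """All overlapping pairs between two interval lists.

    Returns ``(index_in_a, index_in_b, overlap_bp)`` for every pair on the
    same chromosome with ``max(starts) < min(ends)`` (half-open semantics:
    intervals that merely touch do not overlap).
    """
    trees = _trees_by_chrom(b)
    pairs: list[tuple[int, int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append(
                (i, hit.data, min(iv.end, hit.end) - max(iv.start, hit.begin))
            )
    pairs.sort()
    return pairs


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals: merge all overlapping or touching intervals."""
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    chrom_order: list[str] = []
    for iv in intervals:
        if iv.chrom not in by_chrom:
            chrom_order.append(iv.chrom)
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in chrom_order:
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out
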