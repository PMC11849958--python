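"""Nucleolus-associated gene (NAG) annotation and multi-set comparison.

A NAG is a gene whose body overlaps a called NAD segment by at least
``min_overlap`` bp (1 bp by default, half-open semantics: a gene merely
adjacent to a segment is not a NAG). Cross-cell-line sharing is expressed
as exact membership-pattern counts — the numbers behind a Venn diagram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import GeneModel, merge_intervals, overlap
from .nad_calling import NadCallResult

__all__ = [
    "NagSet",
    "SetComparison",
    "annotate_nags",
    "biotype_composition",
    "compare_sets",
]

def is_coding_biotype(biotype: str) -> bool:
    return biotype == "protein_coding"


@dataclass
class NagSet:
    """Genes overlapping NADs in one cell line, with overlap statistics."""

    cell_line: str
    table: pd.DataFrame  # gene_id, gene_name, biotype, overlap_bp, fraction_of_gene_in_nad

    @property
    def gene_ids(self) -> set[str]:
        return set(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.table["gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SetComparison:
    """Exact region counts for every non-empty membership pattern."""

    labels: list[str]
    region_counts: dict[frozenset[str], int]
    union_size: int

    def count(self, *labels: str) -> int:
        """Count of elements belonging to exactly the given label set."""
        return self.region_counts.get(frozenset(labels), 0)

    def in_all(self) -> int:
        return self.count(*self.labels)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "union_size": self.union_size,
            "regions": {
                "&".join(sorted(k)): v
                for k, v in sorted(
                    self.region_counts.items(),
                    key=lambda kv: (len(kv[0]), sorted(kv[0])),
                )
            },
        }


def annotate_nags(
    nads: NadCallResult,
    genes: Sequence[GeneModel],
    min_overlap: int = 1,
    cell_line: str = "",
) -> NagSet:
    """Identify genes overlapping NAD segments by at least ``min_overlap`` bp.

    Overlap is computed against the union of NAD segments, so a gene
    spanning two abutting segments is counted once with its total covered
    bp. Enlarging segments can only add genes, never remove them.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1 bp")
    nad_union = merge_intervals([s.interval for s in nads.segments])
    gene_ivs = [g.interval() for g in genes]
    per_gene_bp: dict[int, int] = {}
    for gi, _, bp in overlap(gene_ivs, nad_union):
        per_gene_bp[gi] = per_gene_bp.get(gi, 0) + bp
    rows = []
    for gi, bp in sorted(per_gene_bp.items()):
        if bp < min_overlap:
            continue
        g = genes[gi]
        rows.append(
            {
                "gene_id": g.gene_id,
                "gene_name": g.gene_name,
                "biotype": g.biotype,
                "overlap_bp": bp,
                "fraction_of_gene_in_nad": bp / g.length,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "gene_name",
            "biotype",
            "overlap_bp",
            "fraction_of_gene_in_nad",
        ],
    )
    return NagSet(cell_line=cell_line, table=table)


def biotype_composition(nags: NagSet) -> dict:
    """Biotype make-up of a NAG set.

    Returns per-biotype fractions (summing to 1) together with the
    protein-coding vs non-coding rollup.
    """
    if len(nags) == 0:
        raise ValueError("empty NAG set")
    counts = nags.table["biotype"].value_counts()
    total = int(counts.sum())
    fractions = {str(k): v / total for k, v in counts.items()}
    coding = sum(v for k, v in fractions.items() if is_coding_biotype(k))
    return {
        "n_genes": total,
        "fractions": fractions,
        "protein_coding": coding,
        "non_coding": 1.0 - coding,
    }


def compare_sets(sets: Mapping[str, Iterable[str]]) -> SetComparison:
    """Exact Venn-region counts for 2+ named gene-id sets.

    Every element of the union is assigned to exactly one membership
    pattern (the subset of labels containing it), so region counts sum to
    the union size. More than 6 sets is computed but flagged with a
    warning, since the 2^k - 1 patterns stop being interpretable.
    """
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("need at least 2 sets to compare")
    if len(labels) > 6:
        warnings.warn(
            f"comparing {len(labels)} sets yields "
            f"{2 ** len(labels) - 1} membership patterns",
            stacklevel=2,
        )
    materialized = {k: set(v) for k, v in sets.items()}
    union = set().union(*materialized.values())
    region_counts: dict[frozenset[str], int] = {}
    for element in union:
        pattern = frozenset(k for k, v in materialized.items() if element in v)
        region_counts[pattern] = region_counts.get(pattern, 0) + 1
    return SetComparison(
        labels=labels, region_counts=region_counts, union_size=len(union)
    )
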