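"""Nucleolar RNA compartment enrichment.

Compares gene-level abundance between nucleolar and total-cell RNA
libraries: a transcript is nucleolar-enriched when its mean nucleolar CPM
is at least ``fold`` times its mean total CPM (inclusive, 2-fold by
default). NAGs are then partitioned into nucleolar-retained, exported
(nuclear but not nucleolar), and silent classes, and gene sets are scored
for SINE/LINE repeat association.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import GeneModel, Interval, overlap
from .nag_annotation import NagSet, is_coding_biotype

__all__ = [
    "COMPARTMENTS",
    "ExpressionTable",
    "EnrichmentCall",
    "normalize_expression",
    "call_nucleolar_enriched",
    "nucleolar_transcriptome_composition",
    "nag_transcription_partition",
    "repeat_association",
]

COMPARTMENTS = ("nucleolar", "total", "nuclear")


@dataclass
class ExpressionTable:
    """Genes x samples abundance matrix with per-sample compartment labels."""

    values: pd.DataFrame  # index: gene_id; columns: sample names
    compartments: dict[str, str]  # sample -> compartment
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.values.columns) - set(self.compartments)
        if missing:
            raise ValueError(f"samples lacking compartment labels: {sorted(missing)}")
        bad = set(self.compartments.values()) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, compartment: str) -> list[str]:
        return [
            s for s in self.values.columns
            if self.compartments.get(s) == compartment
        ]

    def compartment_mean(self, compartment: str) -> pd.Series:
        samples = self.samples_of(compartment)
        if not samples:
            raise ValueError(f"no samples in compartment {compartment!r}")
        return self.values[samples].mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        manifest_path: str | Path,
        normalized: bool = False,
    ) -> "ExpressionTable":
        df = pd.read_csv(counts_path, sep="\t").set_index("gene_id")
        manifest = pd.read_csv(manifest_path, sep="\t")
        compartments = dict(zip(manifest["sample"], manifest["compartment"]))
        return cls(df, compartments, normalized=normalized)


@dataclass
class EnrichmentCall:
    """Per-gene nucleolar/total fold change and the enrichment decision."""

    table: pd.DataFrame  # gene_id, fold_change, enriched, biotype
    fold: float
    pseudocount: float

    @property
    def enriched_gene_ids(self) -> set[str]:
        return set(self.table.loc[self.table["enriched"], "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def normalize_expression(
    table: ExpressionTable, *, allow_normalized: bool = False
) -> ExpressionTable:
    """Counts-per-million per sample: every column sums to 1e6.

    Refuses already-normalized input unless ``allow_normalized`` is set,
    in which case the call is an idempotent no-op.
    """
    if table.normalized:
        if allow_normalized:
            return table
        raise ValueError("table is already normalized")
    totals = table.values.sum(axis=0)
    zero = [s for s, t in totals.items() if t == 0]
    if zero:
        raise ValueError(f"all-zero samples cannot be normalized: {zero}")
    cpm = table.values / totals * 1e6
    return ExpressionTable(cpm, dict(table.compartments), normalized=True)


def call_nucleolar_enriched(
    table: ExpressionTable,
    fold: float = 2.0,
    pseudocount: float = 0.5,
    biotypes: Mapping[str, str] | None = None,
) -> EnrichmentCall:
    """Call genes enriched in the nucleolar RNA pool.

    fold_change = (mean nucleolar CPM + a) / (mean total CPM + a); a gene
    is enriched iff fold_change >= ``fold`` (inclusive, matching a
    "two-fold or more" rule at the default).
    """
    if not table.normalized:
        raise ValueError("normalize the table first (CPM)")
    if fold <= 0 or pseudocount < 0:
        raise ValueError("fold must be > 0 and pseudocount >= 0")
    no = table.compartment_mean("nucleolar")
    tot = table.compartment_mean("total")
    fc = (no + pseudocount) / (tot + pseudocount)
    out = pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "fold_change": fc.to_numpy(),
            "enriched": (fc >= fold).to_numpy(),
        }
    )
    out["biotype"] = (
        out["gene_id"].map(dict(biotypes)) if biotypes is not None else pd.NA
    )
    return EnrichmentCall(table=out, fold=fold, pseudocount=pseudocount)


def nucleolar_transcriptome_composition(calls: EnrichmentCall) -> dict:
    """Biotype make-up of the nucleolar-enriched transcript set."""
    enriched = calls.table.loc[calls.table["enriched"]]
    if len(enriched) == 0:
        raise ValueError("no enriched genes to summarize")
    if enriched["biotype"].isna().any():
        raise ValueError("enriched genes lack biotype annotations")
    counts = enriched["biotype"].value_counts()
    total = int(counts.sum())
    fractions = {str(k): v / total for k, v in counts.items()}
    coding = sum(v for k, v in fractions.items() if is_coding_biotype(k))
    return {
        "n_enriched": total,
        "fractions": fractions,
        "protein_coding": coding,
        "non_coding": 1.0 - coding,
    }


def nag_transcription_partition(
    nags: NagSet,
    calls: EnrichmentCall,
    nuclear_expression: ExpressionTable,
    min_expr: float = 1.0,
    nuclear_compartment: str = "nuclear",
) -> tuple[dict[str, int], pd.DataFrame]:
    """Partition NAGs by where their transcripts are found.

    - ``nucleolar``: nucleolar-enriched per ``calls``;
    - ``nuclear_only``: not enriched, but nuclear CPM >= ``min_expr``;
    - ``silent``: neither.

    The partition is disjoint and exhaustive over the NAG set. Returns
    (counts, per-gene table with the assigned class).
    """
    nag_ids = list(nags.table["gene_id"])
    call_ids = set(calls.table["gene_id"])
    expr_ids = set(nuclear_expression.gene_ids)
    unmatched = [g for g in nag_ids if g not in call_ids or g not in expr_ids]
    if unmatched:
        raise ValueError(
            f"{len(unmatched)} NAG ids missing from expression inputs, "
            f"e.g. {unmatched[:3]}"
        )
    enriched = calls.enriched_gene_ids
    nuclear = nuclear_expression.compartment_mean(nuclear_compartment)
    classes = []
    for gid in nag_ids:
        if gid in enriched:
            classes.append("nucleolar")
        elif nuclear[gid] >= min_expr:
            classes.append("nuclear_only")
        else:
            classes.append("silent")
    table = pd.DataFrame({"gene_id": nag_ids, "transcript_class": classes})
    counts = {
        "nag_transcript_nucleolar": classes.count("nucleolar"),
        "nag_transcript_nuclear_only": classes.count("nuclear_only"),
        "nag_silent": classes.count("silent"),
    }
    return counts, table


def repeat_association(
    gene_ids: Iterable[str],
    gene_models: Sequence[GeneModel],
    repeats: Sequence[Interval],
    classes: tuple[str, ...] = ("SINE", "LINE"),
) -> dict[str, float]:
    """Fraction of the given genes overlapping each repeat class.

    Repeat class is taken from the BED name column; labels outside
    ``classes`` are pooled as "other". A gene counts once per class no
    matter how many elements it overlaps.
    """
    wanted = set(gene_ids)
    genes = [g for g in gene_models if g.gene_id in wanted]
    missing = wanted - {g.gene_id for g in genes}
    if missing:
        raise ValueError(
            f"{len(missing)} gene ids lack models, e.g. {sorted(missing)[:3]}"
        )
    if not genes:
        raise ValueError("empty gene set")

    def repeat_class(iv: Interval) -> str:
        return iv.name if iv.name in classes else "other"

    gene_ivs = [g.interval() for g in genes]
    hit: dict[str, set[str]] = {c: set() for c in (*classes, "other")}
    for gi, ri, _ in overlap(gene_ivs, repeats):
        hit[repeat_class(repeats[ri])].add(genes[gi].gene_id)
    return {c: len(members) / len(genes) for c, members in hit.items()}
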