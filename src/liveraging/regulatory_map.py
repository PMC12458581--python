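"""Promoter windows, enhancer anchors, peak-to-gene assignment, concordance.

Enhancer catalogs aggregated across tissues contain many overlapping or
book-ended intervals describing the same regulatory element; these are
consolidated into *anchors* (transitive merge, links unioned).  Differential
peaks are then assigned to genes through promoter windows (TSS +/- flank)
or through the anchors' link sets, and each (gene, mark) change is called
concordant or discordant with the gene's expression change given the mark's
polarity: an active mark is concordant when it moves with expression, a
repressive mark when it moves against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneAnnotation, GenomicInterval
from .laasp_core import OverlapFraction, overlap_fraction

logger = logging.getLogger(__name__)

#: Default histone-mark polarity.
DEFAULT_POLARITY: dict[str, str] = {
    "H3K27ac": "active",
    "H3K4me1": "active",
    "H3K4me3": "active",
    "H3K27me3": "repressive",
    "H3K9me3": "repressive",
}

#: H3K9me3 is flat across the age range modelled here, so it is excluded
#: from aging concordance unless explicitly included.
DEFAULT_EXCLUDED_MARKS: tuple[str, ...] = ("H3K9me3",)

CATEGORIES = ("promoter_only", "enhancer_only", "both", "neither")


@dataclass(frozen=True)
class EnhancerAnchor:
    interval: GenomicInterval
    linked_genes: frozenset[str]
    n_source_enhancers: int

    @property
    def anchor_id(self) -> str:
        return self.interval.interval_id


def promoter_windows(
    annotation: Iterable[GeneAnnotation], flank: int = 3000
) -> dict[str, GenomicInterval]:
    """Strand-aware promoter window [tss - flank, tss + flank), clipped at 0."""
    out: dict[str, GenomicInterval] = {}
    for gene in annotation:
        start = max(0, gene.tss - flank)
        out[gene.gene_id] = GenomicInterval(
            gene.chrom, start, gene.tss + flank, strand=gene.strand, name=gene.gene_id
        )
    return out


def build_anchors(
    enhancers: Iterable[tuple[GenomicInterval, Iterable[str]]],
    max_gap: int = 0,
) -> list[EnhancerAnchor]:
    """Merge overlapping or near-adjacent enhancers into anchors.

    A single sorted sweep per chromosome merges any intervals overlapping
    or separated by <= max_gap (0 merges book-ended intervals only); the
    anchor spans min(start)..max(end), its link set is the union of the
    constituents' links.  Output is sorted by (chrom, start) and is
    independent of input order.
    """
    by_chrom: dict[str, list[tuple[GenomicInterval, frozenset[str]]]] = {}
    for interval, genes in enhancers:
        by_chrom.setdefault(interval.chrom, []).append((interval, frozenset(genes)))

    anchors: list[EnhancerAnchor] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        cur_start, cur_end = items[0][0].start, items[0][0].end
        cur_genes: set[str] = set(items[0][1])
        cur_n = 1
        for interval, genes in items[1:]:
            if interval.start <= cur_end + max_gap:
                cur_end = max(cur_end, interval.end)
                cur_genes |= genes
                cur_n += 1
            else:
                anchors.append(
                    EnhancerAnchor(GenomicInterval(chrom, cur_start, cur_end),
                                   frozenset(cur_genes), cur_n)
                )
                cur_start, cur_end, cur_genes, cur_n = interval.start, interval.end, set(genes), 1
        anchors.append(
            EnhancerAnchor(GenomicInterval(chrom, cur_start, cur_end), frozenset(cur_genes), cur_n)
        )
    return anchors


def _tree_of(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def assign_peaks(
    deps: pd.DataFrame,
    promoters: Mapping[str, GenomicInterval],
    anchors: Sequence[EnhancerAnchor],
) -> pd.DataFrame:
    """Assign differential peaks to genes via promoters and enhancer anchors.

    ``deps`` needs columns chrom/start/end/direction/mark.  Any >= 1 bp
    overlap (half-open semantics) assigns; a peak hitting several promoters
    or a multi-gene anchor yields one row per (gene, region_class); peaks
    hitting nothing are dropped and counted in the log.
    """
    promoter_trees = _tree_of((iv, gene) for gene, iv in promoters.items())
    anchor_trees = _tree_of((a.interval, a) for a in anchors)

    rows = []
    n_orphans = 0
    for peak in deps.itertuples(index=False):
        peak_id = f"{peak.chrom}:{peak.start}-{peak.end}"
        hit = False
        tree = promoter_trees.get(peak.chrom)
        if tree is not None:
            for node in sorted(tree.overlap(peak.start, peak.end)):
                rows.append((node.data, peak.mark, "promoter", peak.direction, peak_id))
                hit = True
        tree = anchor_trees.get(peak.chrom)
        if tree is not None:
            for node in sorted(tree.overlap(peak.start, peak.end)):
                anchor: EnhancerAnchor = node.data
                for gene in sorted(anchor.linked_genes):
                    rows.append((gene, peak.mark, "enhancer", peak.direction, peak_id))
                    hit = True
        if not hit:
            n_orphans += 1
    if n_orphans:
        logger.info("assign_peaks: %d peaks overlapped no promoter or anchor", n_orphans)
    return pd.DataFrame(
        rows, columns=["gene_id", "mark", "region_class", "peak_direction", "peak_id"]
    )


@dataclass
class ConcordanceResult:
    records: pd.DataFrame  # gene_id, mark, region_class, peak_direction, expression_direction, concordant
    categories: dict[str, str]  # gene -> promoter_only|enhancer_only|both|neither
    category_counts: dict[str, int]
    percent_concordant: OverlapFraction  # share of genes with category != neither


def is_concordant(peak_direction: str, expression_direction: str, polarity: str) -> bool:
    """Active marks are concordant when moving with expression; repressive against."""
    same = peak_direction == expression_direction
    return same if polarity == "active" else not same


def classify_concordance(
    assignments: pd.DataFrame,
    gene_diff: pd.DataFrame,
    polarity: Mapping[str, str] = DEFAULT_POLARITY,
    exclude_marks: Sequence[str] = DEFAULT_EXCLUDED_MARKS,
) -> ConcordanceResult:
    """Concordance calls and the promoter/enhancer/both/neither partition.

    Only genes with a non-ns direction in ``gene_diff`` are considered;
    each assignment record gets a concordant flag; a gene's category is
    computed from its *concordant* records only (discordant records do not
    cancel a concordant one), and every differential gene lands in exactly
    one of the four categories — genes with no concordant record, or no
    record at all, are "neither".
    """
    sig = gene_diff.loc[gene_diff["direction"].isin(["up", "down"])]
    expr_dir = dict(zip(sig["feature_id"], sig["direction"]))

    assign = assignments.loc[~assignments["mark"].isin(exclude_marks)].copy()
    unknown = set(assign["mark"]) - set(polarity)
    if unknown:
        raise KeyError(f"marks missing from polarity map: {sorted(unknown)}")
    assign = assign.loc[assign["gene_id"].isin(expr_dir)]

    records = assign.copy()
    records["expression_direction"] = records["gene_id"].map(expr_dir)
    records["concordant"] = [
        is_concordant(pd_, ed, polarity[m])
        for pd_, ed, m in zip(
            records["peak_direction"], records["expression_direction"], records["mark"]
        )
    ]

    concordant_regions: dict[str, set[str]] = {}
    conc = records.loc[records["concordant"]]
    for gene, region in zip(conc["gene_id"], conc["region_class"]):
        concordant_regions.setdefault(gene, set()).add(region)

    categories: dict[str, str] = {}
    for gene in expr_dir:
        regions = concordant_regions.get(gene, set())
        if regions == {"promoter"}:
            categories[gene] = "promoter_only"
        elif regions == {"enhancer"}:
            categories[gene] = "enhancer_only"
        elif regions == {"promoter", "enhancer"}:
            categories[gene] = "both"
        else:
            categories[gene] = "neither"

    counts = {c: 0 for c in CATEGORIES}
    for cat in categories.values():
        counts[cat] += 1
    n_concordant = len(categories) - counts["neither"]
    pct = (
        overlap_fraction(n_concordant, len(categories))
        if categories
        else OverlapFraction(0.0, 0, 0)
    )
    return ConcordanceResult(
        records=records.reset_index(drop=True),
        categories=categories,
        category_counts=counts,
        percent_concordant=pct,
    )


@dataclass
class LinkedEnhancerStats:
    per_gene: pd.Series  # gene -> number of linked anchors carrying >= 1 DEP
    mean_all: float  # mean over every queried gene
    mean_hit: float  # mean over genes with >= 1 affected anchor


def linked_enhancer_stats(
    anchors: Sequence[EnhancerAnchor],
    deps: pd.DataFrame,
    genes: Iterable[str],
) -> LinkedEnhancerStats:
    """Per-gene count of linked anchors that carry at least one peak."""
    dep_trees: dict[str, IntervalTree] = {}
    for r in deps.itertuples(index=False):
        dep_trees.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end))

    hit_counts: dict[str, int] = {g: 0 for g in genes}
    for anchor in anchors:
        tree = dep_trees.get(anchor.interval.chrom)
        if tree is None or not tree.overlap(anchor.interval.start, anchor.interval.end):
            continue
        for gene in anchor.linked_genes:
            if gene in hit_counts:
                hit_counts[gene] += 1

    per_gene = pd.Series(hit_counts, dtype=int).sort_index()
    nonzero = per_gene[per_gene > 0]
    return LinkedEnhancerStats(
        per_gene=per_gene,
        mean_all=float(per_gene.mean()) if len(per_gene) else 0.0,
        mean_hit=float(nonzero.mean()) if len(nonzero) else 0.0,
    )


def anchors_to_frames(anchors: Sequence[EnhancerAnchor]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Anchors as a BED-like frame plus an (anchor_id, gene_id) link table."""
    bed = pd.DataFrame(
        [
            (a.interval.chrom, a.interval.start, a.interval.end, a.anchor_id,
             a.n_source_enhancers, ".")
            for a in anchors
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    links = pd.DataFrame(
        [(a.anchor_id, g) for a in anchors for g in sorted(a.linked_genes)],
        columns=["anchor_id", "gene_id"],
    )
    return bed, links
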