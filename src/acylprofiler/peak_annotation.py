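"""Peak -> genomic-feature classification and mark-related gene derivation.

Each peak is assigned to exactly one of six categories (promoter, 5'UTR,
CDS, 3'UTR, intron, intergenic) by maximal base-pair overlap; ties are broken
by the fixed precedence cds > five_prime_utr > three_prime_utr > intron >
promoter > intergenic, so the categories partition the peak set and the
reported percentages sum to 100.

"Mark-related genes" are genes whose body overlaps at least one peak of the
mark by >= 1 bp (optionally extended to promoters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

from .errors import ValidationError
from .genome_io import (ALL_CATEGORIES, GenomeAnnotation, Peak, PeakSet,
                        derive_intergenic, derive_promoters)
from .utils import pct, round_half_up

logger = logging.getLogger(__name__)

#: tie-break precedence for category assignment (highest first)
CATEGORY_PRECEDENCE = ("cds", "five_prime_utr", "three_prime_utr",
                      "intron", "promoter", "intergenic")


class FeatureIndex:
    """Merged per-category interval sets of an annotation, as PyRanges.

    Building the index is the expensive step; reuse it when classifying
    several peak sets against the same annotation.
    """

    def __init__(self, ann: GenomeAnnotation):
        self.ann = ann
        rows: dict[str, list[tuple[str, int, int]]] = {c: [] for c in CATEGORY_PRECEDENCE}
        for g in ann.genes:
            for cat, iv in g.features:
                rows[cat].append((iv.chrom, iv.start, iv.end))
        for p in derive_promoters(ann):
            rows["promoter"].append((p.chrom, p.start, p.end))
        for p in derive_intergenic(ann):
            rows["intergenic"].append((p.chrom, p.start, p.end))
        self.category_ranges: dict[str, pr.PyRanges | None] = {}
        for cat, items in rows.items():
            if not items:
                self.category_ranges[cat] = None
                continue
            df = pd.DataFrame(items, columns=["Chromosome", "Start", "End"])
            self.category_ranges[cat] = pr.PyRanges(df).merge()

    def intervals(self, category: str) -> list[tuple[str, int, int]]:
        g = self.category_ranges[category]
        if g is None:
            return []
        return list(g.df[["Chromosome", "Start", "End"]].itertuples(index=False, name=None))


def _overlap_bp_matrix(peaks: PeakSet, index: FeatureIndex) -> np.ndarray:
    """n_peaks x 6 matrix of overlap base pairs, columns in precedence order."""
    chroms = {p.interval.chrom for p in peaks}
    unknown = chroms - set(index.ann.chrom_lengths)
    if unknown:
        raise ValidationError(f"peak chromosome(s) absent from annotation: "
                              f"{sorted(unknown)}")
    df = pd.DataFrame({
        "Chromosome": [p.interval.chrom for p in peaks],
        "Start": [p.interval.start for p in peaks],
        "End": [p.interval.end for p in peaks],
        "PeakIdx": np.arange(len(peaks)),
    })
    query = pr.PyRanges(df)
    out = np.zeros((len(peaks), len(CATEGORY_PRECEDENCE)))
    for ci, cat in enumerate(CATEGORY_PRECEDENCE):
        subject = index.category_ranges[cat]
        if subject is None:
            continue
        joined = query.join(subject, report_overlap=True)
        if len(joined) == 0:
            continue
        j = joined.df
        sums = j.groupby("PeakIdx")["Overlap"].sum()
        out[sums.index.to_numpy(), ci] = sums.to_numpy()
    return out


def classify_peaks(peaks: PeakSet, ann: GenomeAnnotation,
                   index: FeatureIndex | None = None) -> list[str]:
    """Category per peak, by maximal overlap with precedence tie-break."""
    if len(peaks) == 0:
        return []
    if index is None:
        index = FeatureIndex(ann)
    bp = _overlap_bp_matrix(peaks, index)
    uncovered = int((bp.sum(axis=1) == 0).sum())
    if uncovered:
        # only possible when gene features under-span their gene record
        logger.warning("%d peak(s) overlap no category interval; "
                       "falling back to intergenic", uncovered)
    choice = np.argmax(bp, axis=1)  # first max wins == precedence order
    cats = [CATEGORY_PRECEDENCE[i] if bp[n, choice[n]] > 0 else "intergenic"
            for n, i in enumerate(choice)]
    return cats


def classify_peak(peak: Peak, ann: GenomeAnnotation,
                  index: FeatureIndex | None = None) -> str:
    """Classify a single peak (see :func:`classify_peaks`)."""
    ps = PeakSet(mark="_single", sample="", peaks=[peak])
    return classify_peaks(ps, ann, index=index)[0]


@dataclass
class CategoryReport:
    """Per-category peak counts and percentages plus genebody/exon rollups."""

    counts: dict[str, int]
    percentages: dict[str, float]
    rollups: dict[str, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, self.counts[c], self.percentages[c]) for c in ALL_CATEGORIES]
        rows.append(("exon (rollup)", sum(self.counts[c] for c in
                                          ("five_prime_utr", "cds", "three_prime_utr")),
                     self.rollups["exon_pct"]))
        rows.append(("genebody (rollup)",
                     sum(self.counts[c] for c in
                         ("five_prime_utr", "cds", "three_prime_utr", "intron")),
                     self.rollups["genebody_pct"]))
        return pd.DataFrame(rows, columns=["category", "count", "percent"])


def distribution_report(peaks: PeakSet, ann: GenomeAnnotation,
                        index: FeatureIndex | None = None) -> CategoryReport:
    """Genome-wide distribution of a mark across the six feature categories.

    Rollups: exon% = 5'UTR% + CDS% + 3'UTR%; genebody% = exon% + intron%.
    Percentages are reported half-up to 2 decimals; rollups are computed on
    the unrounded values and then rounded, so genebody% is exactly
    exon% + intron% up to the final rounding step.
    """
    if len(peaks) == 0:
        raise ValidationError("distribution_report on empty peak set")
    cats = classify_peaks(peaks, ann, index=index)
    counts = {c: 0 for c in ALL_CATEGORIES}
    for c in cats:
        counts[c] += 1
    total = len(peaks)
    raw = {c: 100.0 * counts[c] / total for c in ALL_CATEGORIES}
    exon_raw = raw["five_prime_utr"] + raw["cds"] + raw["three_prime_utr"]
    rollups = {"exon_pct": round_half_up(exon_raw),
               "genebody_pct": round_half_up(exon_raw + raw["intron"])}
    return CategoryReport(counts=counts,
                          percentages={c: round_half_up(v) for c, v in raw.items()},
                          rollups=rollups, total=total)


def assign_genes(peaks: PeakSet, ann: GenomeAnnotation,
                 exclude: set[str] | None = None,
                 include_promoter: bool = False) -> set[str]:
    """Gene ids whose body (optionally promoter) overlaps >= 1 bp of a peak."""
    if len(peaks) == 0:
        return set()
    exclude = exclude or set()
    rows = [(g.interval.chrom, g.interval.start, g.interval.end, g.gene_id)
            for g in ann.genes]
    if include_promoter:
        for g in ann.genes:
            gi = g.interval
            L = ann.chrom_lengths[gi.chrom]
            if gi.strand == "-":
                s, e = gi.end, min(gi.end + ann.promoter_flank, L)
            else:
                s, e = max(0, gi.start - ann.promoter_flank), gi.start
            if s < e:
                rows.append((gi.chrom, s, e, g.gene_id))
    if not rows:
        return set()
    genes = pr.PyRanges(pd.DataFrame(rows, columns=["Chromosome", "Start", "End",
                                                    "gene_id"]))
    query = pr.PyRanges(pd.DataFrame({
        "Chromosome": [p.interval.chrom for p in peaks],
        "Start": [p.interval.start for p in peaks],
        "End": [p.interval.end for p in peaks],
    }))
    hit = genes.overlap(query)
    ids = set() if len(hit) == 0 else set(hit.df["gene_id"])
    return ids - exclude


@dataclass
class GeneSetComparison:
    """Exact set algebra between two gene (or peak-id) sets."""

    n_a: int
    n_b: int
    n_common: int
    specific_a: int
    specific_b: int
    pct_a_shared: float
    a_only: set[str] = field(default_factory=set, repr=False)
    b_only: set[str] = field(default_factory=set, repr=False)


def compare_sets(a: set[str], b: set[str]) -> GeneSetComparison:
    """Shared/specific counts; pct_a_shared = 100*|a & b|/|a| (2 decimals)."""
    common = a & b
    return GeneSetComparison(
        n_a=len(a), n_b=len(b), n_common=len(common),
        specific_a=len(a) - len(common), specific_b=len(b) - len(common),
        pct_a_shared=pct(len(common), len(a)) if a else 0.0,
        a_only=a - b, b_only=b - a)


def expressed_fraction(genes: set[str], expr) -> tuple[int, float]:
    """(count, percent) of *genes* with FPKM >= the table's expressed threshold.

    Genes absent from the table count as unexpressed and are logged.
    """
    missing = [g for g in genes if g not in expr.fpkm]
    if missing:
        logger.warning("%d gene(s) missing from expression table; counted as "
                       "unexpressed", len(missing))
    n = sum(1 for g in genes if expr.is_expressed(g))
    return n, (pct(n, len(genes)) if genes else 0.0)
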