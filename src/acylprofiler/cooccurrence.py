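"""Replicate merging and pairwise overlap statistics between mark peak sets.

Overlap semantics follow the BEDTools defaults the original analysis relied
on: any >= 1 bp overlap counts, and bookended intervals merge at max_gap=0
under the half-open convention.  Overlap fractions are query-anchored and
therefore intentionally asymmetric: ``frac[i][j]`` is the percentage of
mark-i peaks that touch at least one mark-j peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyranges as pr

from .errors import ValidationError
from .genome_io import GenomeAnnotation, GenomicInterval, Peak, PeakSet
from .utils import pct

logger = logging.getLogger(__name__)


def _to_ranges(ps: PeakSet, with_idx: bool = False) -> pr.PyRanges:
    df = pd.DataFrame({
        "Chromosome": [p.interval.chrom for p in ps],
        "Start": [p.interval.start for p in ps],
        "End": [p.interval.end for p in ps],
    })
    if with_idx:
        df["PeakIdx"] = np.arange(len(ps))
    return pr.PyRanges(df)


def merge_set(peaks: PeakSet, max_gap: int = 0) -> PeakSet:
    """Fuse peaks that overlap or lie within ``max_gap`` bp of each other.

    Bookended peaks merge at ``max_gap=0``.  Merged peak scores are the
    maximum over constituents (missing scores ignored); names record the
    constituent count.
    """
    if len(peaks) == 0:
        return PeakSet(mark=peaks.mark, sample=peaks.sample, peaks=[])
    df = peaks.to_frame()
    clustered = pr.PyRanges(df).cluster(slack=max_gap).df

    def _nanmax(s: pd.Series) -> float:
        return float(s.max()) if s.notna().any() else np.nan

    merged = []
    for i, (_, grp) in enumerate(clustered.groupby("Cluster", sort=True), start=1):
        iv = GenomicInterval(str(grp["Chromosome"].iloc[0]),
                             int(grp["Start"].min()), int(grp["End"].max()))
        fe, p, q = (_nanmax(grp[c]) for c in ("FoldEnrichment", "NegLog10P", "NegLog10Q"))
        merged.append(Peak(iv,
                           fold_enrichment=None if np.isnan(fe) else fe,
                           neg_log10_p=None if np.isnan(p) else p,
                           neg_log10_q=None if np.isnan(q) else q,
                           name=f"{peaks.mark}_merged_{i}(n={len(grp)})"))
    return PeakSet(mark=peaks.mark, sample=peaks.sample, peaks=merged)


def common_peaks(a: PeakSet, b: PeakSet, frame: str = "a") -> PeakSet:
    """Shared peaks between two sets (>= 1 bp overlap).

    ``frame`` selects the coordinate frame of the result: ``"a"`` returns
    the overlapping peaks of *a* (query-anchored, the default), ``"b"`` those
    of *b*, and ``"union"`` the merged union of both overlapping subsets.
    """
    if frame not in ("a", "b", "union"):
        raise ValueError(f"frame must be a|b|union, got {frame!r}")

    def _hits(query: PeakSet, subject: PeakSet) -> list[Peak]:
        if len(query) == 0 or len(subject) == 0:
            return []
        hit = _to_ranges(query, with_idx=True).overlap(_to_ranges(subject))
        if len(hit) == 0:
            return []
        idx = sorted(hit.df["PeakIdx"])
        return [query.peaks[i] for i in idx]

    if frame == "a":
        return PeakSet(mark=a.mark, sample=a.sample, peaks=_hits(a, b))
    if frame == "b":
        return PeakSet(mark=b.mark, sample=b.sample, peaks=_hits(b, a))
    both = PeakSet(mark=f"{a.mark}|{b.mark}", sample=a.sample,
                   peaks=_hits(a, b) + _hits(b, a))
    return merge_set(both)


def overlap_fraction(query: PeakSet, subject: PeakSet) -> float:
    """Percentage of query peaks overlapping >= 1 bp of the subject set."""
    if len(query) == 0:
        raise ValidationError("overlap_fraction with empty query set")
    n_hit = len(common_peaks(query, subject, frame="a"))
    return pct(n_hit, len(query))


@dataclass
class OverlapMatrix:
    """Ordered mark labels and the query-anchored overlap percentage matrix."""

    marks: list[str]
    frac: np.ndarray  # frac[i, j] = % of mark-i peaks overlapping mark j

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frac, index=self.marks, columns=self.marks)


def overlap_matrix(sets: list[PeakSet]) -> OverlapMatrix:
    """Pairwise overlap_fraction over every ordered pair of peak sets."""
    marks = [s.mark for s in sets]
    n = len(sets)
    frac = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            frac[i, j] = overlap_fraction(sets[i], sets[j])
    return OverlapMatrix(marks=marks, frac=frac)


def intergenic_overlap(query: PeakSet, subject: PeakSet,
                       ann: GenomeAnnotation, index=None) -> float:
    """Overlap fraction restricted to the query peaks classified intergenic.

    Used for the open-chromatin comparison: what share of the intergenic
    peaks of a mark co-locate with DNase hypersensitive sites.
    """
    from .peak_annotation import classify_peaks

    cats = classify_peaks(query, ann, index=index)
    inter = [p for p, c in zip(query.peaks, cats) if c == "intergenic"]
    if not inter:
        raise ValidationError("no intergenic peaks in query set (count 0)")
    sub = PeakSet(mark=query.mark, sample=query.sample, peaks=inter)
    return overlap_fraction(sub, subject)
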