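"""Domain types and readers/writers for the genomic formats the pipeline touches.

All coordinates are held internally in the BED convention: 0-based,
half-open ``[start, end)``.  GFF3 (1-based, closed) is converted on read and
restored on write, so a GFF3 -> internal -> GFF3 round trip is exact.

The gene feature model is per-gene, not per-transcript: when a gene has
several transcripts the longest one is taken as representative and its
5'UTR / CDS / intron / 3'UTR structure defines the gene's features.
"""

from __future__ import annotations

import json
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: feature categories a base inside a gene body can belong to
GENIC_CATEGORIES = ("five_prime_utr", "cds", "intron", "three_prime_utr")

#: all categories a peak can be assigned to
ALL_CATEGORIES = ("promoter", "five_prime_utr", "cds", "three_prime_utr",
                  "intron", "intergenic")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """One gene with its representative-transcript feature structure.

    ``features`` holds ``(category, interval)`` pairs with category in
    :data:`GENIC_CATEGORIES`; feature intervals are disjoint and their union
    is the representative transcript's span.
    """

    gene_id: str
    interval: GenomicInterval
    features: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base (strand-aware)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    def validate(self) -> None:
        for cat, iv in self.features:
            if cat not in GENIC_CATEGORIES:
                raise ValidationError(f"{self.gene_id}: unknown feature category {cat}")
            if iv.chrom != self.interval.chrom or iv.start < self.interval.start \
                    or iv.end > self.interval.end:
                raise ValidationError(
                    f"{self.gene_id}: feature {cat} {iv.start}-{iv.end} outside gene")
        ivs = sorted(iv for _, iv in self.features)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValidationError(f"{self.gene_id}: overlapping features")


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus gene models; source of derived intervals."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    promoter_flank: int = 1000

    def __post_init__(self) -> None:
        if self.promoter_flank <= 0:
            raise ValidationError("promoter_flank must be > 0")

    def validate(self) -> None:
        for g in self.genes:
            length = self.chrom_lengths.get(g.interval.chrom)
            if length is None:
                raise ValidationError(f"{g.gene_id}: unknown chromosome {g.interval.chrom}")
            if g.interval.end > length:
                raise ValidationError(f"{g.gene_id}: extends past chromosome end")
            g.validate()

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {c: [] for c in self.chrom_lengths}
        for g in self.genes:
            out[g.interval.chrom].append(g)
        return out


@dataclass
class Peak:
    """One scored peak-caller interval.

    MACS-style scores: fold enrichment over background, and -log10 of the
    p/q values; any of them may be missing (plain BED input)."""

    interval: GenomicInterval
    fold_enrichment: float | None = None
    neg_log10_p: float | None = None
    neg_log10_q: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        for label, v in (("fold_enrichment", self.fold_enrichment),
                         ("neg_log10_p", self.neg_log10_p),
                         ("neg_log10_q", self.neg_log10_q)):
            if v is not None and v < 0:
                raise ValidationError(f"peak {self.name}: negative {label} ({v})")


@dataclass
class PeakSet:
    """Named, sorted collection of peaks for one mark/sample."""

    mark: str
    sample: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        """Columns Chromosome/Start/End plus scores — the pyranges layout."""
        return pd.DataFrame({
            "Chromosome": [p.interval.chrom for p in self.peaks],
            "Start": [p.interval.start for p in self.peaks],
            "End": [p.interval.end for p in self.peaks],
            "Name": [p.name for p in self.peaks],
            "FoldEnrichment": [np.nan if p.fold_enrichment is None else p.fold_enrichment
                               for p in self.peaks],
            "NegLog10P": [np.nan if p.neg_log10_p is None else p.neg_log10_p
                          for p in self.peaks],
            "NegLog10Q": [np.nan if p.neg_log10_q is None else p.neg_log10_q
                          for p in self.peaks],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mark: str, sample: str = "") -> "PeakSet":
        peaks = []
        for row in df.itertuples(index=False):
            peaks.append(Peak(
                interval=GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End)),
                fold_enrichment=None if pd.isna(row.FoldEnrichment) else float(row.FoldEnrichment),
                neg_log10_p=None if pd.isna(row.NegLog10P) else float(row.NegLog10P),
                neg_log10_q=None if pd.isna(row.NegLog10Q) else float(row.NegLog10Q),
                name=str(row.Name),
            ))
        return cls(mark=mark, sample=sample, peaks=peaks)


class CoverageTrack:
    """Run-length encoded per-base read depth plus the library size.

    ``total_mapped`` is the number of mapped reads the track represents; it
    is the denominator of the per-million normalisation used by the metagene
    profiles.
    """

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 total_mapped: float):
        if total_mapped <= 0:
            raise ValidationError("total_mapped must be > 0")
        self.total_mapped = float(total_mapped)
        self.segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if np.any(values < 0):
                raise ValidationError(f"negative coverage on {chrom}")
            if np.any(starts >= ends):
                raise ValidationError(f"empty coverage segment on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping coverage segments on {chrom}")
            self.segments[chrom] = (starts, ends, values)
            # prefix integral of depth at segment breakpoints for O(log n) mass queries
            seg_mass = (ends - starts) * values
            self._cum[chrom] = (starts, np.concatenate(([0.0], np.cumsum(seg_mass))))

    def mass(self, chrom: str, start, end):
        """Integrated depth (depth summed over bases) on [start, end).

        Vectorised: *start*/*end* may be arrays.
        """
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if chrom not in self.segments:
            return np.zeros(len(start))
        s, e, v = self.segments[chrom]
        _, cum = self._cum[chrom]

        def point(x):
            # integral of depth over [0, x)
            x = np.clip(x, 0, None)
            i = np.searchsorted(s, x, side="right")
            out = cum[i].copy()
            # subtract the uncovered tail of the segment x falls inside
            inside = i > 0
            j = i[inside] - 1
            out[inside] -= np.maximum(e[j] - np.minimum(x[inside], e[j]), 0) * v[j]
            return out

        return point(end) - point(start)

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValidationError("mean_depth over empty interval")
        return float(self.mass(chrom, start, end)[0]) / (end - start)


@dataclass
class ExpressionTable:
    """gene_id -> FPKM with the expressed/silent threshold (default 1)."""

    fpkm: dict[str, float]
    expressed_threshold: float = 1.0

    def __post_init__(self) -> None:
        for g, v in self.fpkm.items():
            if v < 0:
                raise ValidationError(f"negative FPKM for {g}")

    def is_expressed(self, gene_id: str) -> bool:
        return self.fpkm.get(gene_id, 0.0) >= self.expressed_threshold


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, "
                                 f"got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid 1-based coordinates "
                                 f"{start}..{end}")


def _utr_type(ft: str) -> str | None:
    ft = ft.lower()
    if ft in ("five_prime_utr", "5'utr"):
        return "five_prime_utr"
    if ft in ("three_prime_utr", "3'utr"):
        return "three_prime_utr"
    return None


def _subtract(iv: tuple[int, int], others: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """iv minus union of others, all half-open tuples."""
    pieces = [iv]
    for o in sorted(others):
        nxt = []
        for s, e in pieces:
            if o[1] <= s or o[0] >= e:
                nxt.append((s, e))
                continue
            if s < o[0]:
                nxt.append((s, o[0]))
            if o[1] < e:
                nxt.append((o[1], e))
        pieces = nxt
    return [p for p in pieces if p[0] < p[1]]


def read_gff3(path: str | Path, promoter_flank: int = 1000) -> GenomeAnnotation:
    """Load a GFF3 gene annotation into the internal 0-based convention.

    Chromosome lengths come from ``##sequence-region`` directives; when a
    chromosome lacks one, the rightmost feature end is used and a warning
    logged.  Introns are derived as the gaps between the representative
    (longest) transcript's exons; exonic sequence outside the CDS is
    classified as UTR by its position relative to the CDS when explicit UTR
    records are absent.
    """
    path = Path(path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")

    chrom_lengths: dict[str, int] = {}
    for d in db.directives:
        if d.startswith("sequence-region"):
            parts = d.split()
            # "sequence-region chrom start end" (1-based closed)
            chrom_lengths[parts[1]] = int(parts[3])

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gi = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        if transcripts:
            rep = max(transcripts, key=lambda t: (t.end - t.start, t.id))
            container = rep
        else:
            container = gene
        exons = sorted((c.start - 1, c.end) for c in db.children(container, featuretype="exon"))
        cdss = sorted((c.start - 1, c.end) for c in db.children(container, featuretype="CDS"))
        utrs: list[tuple[str, tuple[int, int]]] = []
        for c in db.children(container):
            ut = _utr_type(c.featuretype)
            if ut is not None:
                utrs.append((ut, (c.start - 1, c.end)))
        for s, e in exons + cdss + [iv for _, iv in utrs]:
            if s < gi.start or e > gi.end:
                raise ValidationError(
                    f"{gene.id}: child feature {s}-{e} outside parent gene")
        if not exons:
            exons = [(container.start - 1, container.end)]

        features: list[tuple[str, GenomicInterval]] = []
        # introns: gaps between consecutive exons
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 < s2:
                features.append(("intron", GenomicInterval(gi.chrom, e1, s2, gi.strand)))
        if cdss and not utrs:
            # infer UTRs: exonic minus CDS, 5' vs 3' by strand
            cds_lo, cds_hi = cdss[0][0], cdss[-1][1]
            for s, e in exons:
                for ps, pe in _subtract((s, e), cdss):
                    if pe <= cds_lo:
                        cat = "five_prime_utr" if gi.strand == "+" else "three_prime_utr"
                    elif ps >= cds_hi:
                        cat = "three_prime_utr" if gi.strand == "+" else "five_prime_utr"
                    else:  # exonic gap inside the CDS span: treat as intron-like CDS gap
                        cat = "cds"
                    features.append((cat, GenomicInterval(gi.chrom, ps, pe, gi.strand)))
            for s, e in cdss:
                features.append(("cds", GenomicInterval(gi.chrom, s, e, gi.strand)))
        elif cdss:
            utr_tuples = [iv for _, iv in utrs]
            for s, e in cdss:
                features.append(("cds", GenomicInterval(gi.chrom, s, e, gi.strand)))
            for cat, (s, e) in utrs:
                features.append((cat, GenomicInterval(gi.chrom, s, e, gi.strand)))
            # exonic bases in neither CDS nor UTR are counted as cds
            for s, e in exons:
                for ps, pe in _subtract((s, e), cdss + utr_tuples):
                    features.append(("cds", GenomicInterval(gi.chrom, ps, pe, gi.strand)))
        else:
            # non-coding gene: exons carry no CDS/UTR split; count the exonic
            # span under cds so the feature partition stays complete
            for s, e in exons:
                features.append(("cds", GenomicInterval(gi.chrom, s, e, gi.strand)))

        gm = GeneModel(gene_id=gene.id, interval=gi,
                       features=sorted(features, key=lambda f: f[1].start))
        genes.append(gm)

    seen_chroms = {g.interval.chrom for g in genes}
    for chrom in sorted(seen_chroms - set(chrom_lengths)):
        inferred = max(g.interval.end for g in genes if g.interval.chrom == chrom)
        logger.warning("no ##sequence-region for %s; using rightmost feature end %d",
                       chrom, inferred)
        chrom_lengths[chrom] = inferred

    ann = GenomeAnnotation(chrom_lengths=chrom_lengths,
                           genes=sorted(genes, key=lambda g: (g.interval.chrom,
                                                              g.interval.start)),
                           promoter_flank=promoter_flank)
    ann.validate()
    return ann


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation back to GFF3 (1-based closed), sorted, LF endings."""
    lines = ["##gff-version 3"]
    for chrom in sorted(ann.chrom_lengths):
        lines.append(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}")
    for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
        gi = g.interval
        attrs = f"ID={g.gene_id}"
        lines.append("\t".join([gi.chrom, "acylprofiler", "gene", str(gi.start + 1),
                                str(gi.end), ".", gi.strand, ".", attrs]))
        mrna_id = f"{g.gene_id}.1"
        lines.append("\t".join([gi.chrom, "acylprofiler", "mRNA", str(gi.start + 1),
                                str(gi.end), ".", gi.strand, ".",
                                f"ID={mrna_id};Parent={g.gene_id}"]))
        # exons = merged non-intron features
        exonic = sorted((iv.start, iv.end) for cat, iv in g.features if cat != "intron")
        merged: list[list[int]] = []
        for s, e in exonic:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for i, (s, e) in enumerate(merged, 1):
            lines.append("\t".join([gi.chrom, "acylprofiler", "exon", str(s + 1), str(e),
                                    ".", gi.strand, ".",
                                    f"ID={mrna_id}.exon{i};Parent={mrna_id}"]))
        type_map = {"cds": "CDS", "five_prime_utr": "five_prime_UTR",
                    "three_prime_utr": "three_prime_UTR"}
        counters = {t: 0 for t in type_map.values()}
        for cat, iv in sorted(g.features, key=lambda f: f[1].start):
            if cat == "intron":
                continue
            t = type_map[cat]
            counters[t] += 1
            phase = "0" if t == "CDS" else "."
            lines.append("\t".join([gi.chrom, "acylprofiler", t, str(iv.start + 1),
                                    str(iv.end), ".", gi.strand, phase,
                                    f"ID={mrna_id}.{t}{counters[t]};Parent={mrna_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# derived annotation intervals
# ---------------------------------------------------------------------------

def derive_promoters(ann: GenomeAnnotation) -> list[GenomicInterval]:
    """Strand-aware promoters: ``promoter_flank`` bp directly upstream of each
    TSS, truncated at chromosome boundaries."""
    out: list[GenomicInterval] = []
    for g in ann.genes:
        gi = g.interval
        L = ann.chrom_lengths[gi.chrom]
        if gi.strand == "-":
            s, e = gi.end, min(gi.end + ann.promoter_flank, L)
        else:
            s, e = max(0, gi.start - ann.promoter_flank), gi.start
        if s >= e:
            logger.warning("gene %s: promoter fully truncated at chromosome boundary",
                           g.gene_id)
            continue
        if e - s < ann.promoter_flank:
            logger.warning("gene %s: promoter truncated to %d bp", g.gene_id, e - s)
        out.append(GenomicInterval(gi.chrom, s, e, gi.strand))
    return sorted(out)


def derive_intergenic(ann: GenomeAnnotation) -> list[GenomicInterval]:
    """Complement of (gene bodies union promoters) on every chromosome."""
    covered: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.chrom_lengths}
    for g in ann.genes:
        covered[g.interval.chrom].append((g.interval.start, g.interval.end))
    for p in derive_promoters(ann):
        covered[p.chrom].append((p.start, p.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(ann.chrom_lengths):
        L = ann.chrom_lengths[chrom]
        pos = 0
        for s, e in sorted(covered[chrom]):
            if s > pos:
                out.append(GenomicInterval(chrom, pos, s))
            pos = max(pos, e)
        if pos < L:
            out.append(GenomicInterval(chrom, pos, L))
    return out


# ---------------------------------------------------------------------------
# peak files (BED family)
# ---------------------------------------------------------------------------

_DIALECT_COLS = {"bed": 3, "narrowPeak": 10, "broadPeak": 9}


def read_peaks(path: str | Path, dialect: str = "broadPeak",
               mark: str | None = None, sample: str = "") -> PeakSet:
    """Read a BED / ENCODE narrowPeak / broadPeak file into a sorted PeakSet.

    narrowPeak/broadPeak column 7 is fold enrichment, 8 is -log10(p),
    9 is -log10(q); the MACS placeholder ``-1`` maps to missing.
    """
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown peak dialect {dialect!r}; "
                         f"expected one of {sorted(_DIALECT_COLS)}")
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = cols[3] if len(cols) > 3 and cols[3] else "."
            fe = p = q = None
            if dialect in ("narrowPeak", "broadPeak") and len(cols) >= 9:
                def _score(x: str) -> float | None:
                    v = float(x)
                    return None if v < 0 else v
                fe, p, q = _score(cols[6]), _score(cols[7]), _score(cols[8])
            peaks.append(Peak(GenomicInterval(chrom, start, end), fold_enrichment=fe,
                              neg_log10_p=p, neg_log10_q=q, name=name))
    return PeakSet(mark=mark or path.stem, sample=sample, peaks=peaks)


def write_peaks(ps: PeakSet, path: str | Path, dialect: str = "broadPeak") -> None:
    """Write a PeakSet as sorted BED3/broadPeak with LF endings."""
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    lines = []
    for p in ps.peaks:
        iv = p.interval
        if dialect == "bed":
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}")
            continue
        def _fmt(v: float | None) -> str:
            return "-1" if v is None else format(v, "g")
        fields = [iv.chrom, str(iv.start), str(iv.end), p.name, "0", ".",
                  _fmt(p.fold_enrichment), _fmt(p.neg_log10_p), _fmt(p.neg_log10_q)]
        if dialect == "narrowPeak":
            fields.append("-1")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# coverage, expression, reports
# ---------------------------------------------------------------------------

def read_coverage(path: str | Path, total_mapped: float | None = None) -> CoverageTrack:
    """Read a bedGraph into a CoverageTrack.

    ``total_mapped`` may be given explicitly or via a ``#total_mapped=N``
    comment at the top of the file (written by this package's writers);
    otherwise it defaults to the integrated depth mass divided by the
    20 bp nominal read length, with a warning.
    """
    path = Path(path)
    per_chrom: dict[str, list[list]] = {}
    file_total: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#total_mapped="):
                    file_total = float(line.split("=", 1)[1])
                continue
            if line.startswith(("track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, s, e, v = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if s >= e:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative coverage {v}")
            per_chrom.setdefault(chrom, [[], [], []])
            per_chrom[chrom][0].append(s)
            per_chrom[chrom][1].append(e)
            per_chrom[chrom][2].append(v)
    segments = {c: (np.array(s), np.array(e), np.array(v))
                for c, (s, e, v) in per_chrom.items()}
    tm = total_mapped if total_mapped is not None else file_total
    if tm is None:
        mass = sum(((e - s) * v).sum() for s, e, v in segments.values())
        tm = max(mass / 20.0, 1.0)
        logger.warning("no total_mapped available; inferred %.0f from depth mass", tm)
    return CoverageTrack(segments, total_mapped=tm)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    lines = [f"#total_mapped={track.total_mapped:g}"]
    for chrom in sorted(track.segments):
        s, e, v = track.segments[chrom]
        for i in range(len(s)):
            if v[i] != 0:
                lines.append(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(path: str | Path, expressed_threshold: float = 1.0) -> ExpressionTable:
    """Read a two-column TSV (gene_id, fpkm; '#' comments, optional header)."""
    path = Path(path)
    fpkm: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and cols[0].lower() in ("gene_id", "gene", "id"):
                continue
            gene, raw = cols[0], cols[1]
            try:
                value = float(raw)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric FPKM {raw!r}") from exc
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative FPKM for {gene}")
            if gene in fpkm:
                raise ValidationError(f"{path}: duplicate gene_id {gene!r}")
            fpkm[gene] = value
    return ExpressionTable(fpkm=fpkm, expressed_threshold=expressed_threshold)


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    lines = ["gene_id\tfpkm"]
    for g in sorted(expr.fpkm):
        lines.append(f"{g}\t{expr.fpkm[g]:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(obj, path: str | Path) -> None:
    """Write a report: DataFrames go to TSV with stable column order, other
    JSON-serialisable objects to JSON with sorted keys.  LF endings."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default)
                        + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
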