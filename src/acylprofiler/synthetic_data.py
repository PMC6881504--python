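"""Seed-deterministic simulator of toy genomes and the data around them.

Every generator output is a pure function of :class:`SimConfig`.  Each
generator draws from its own named substream of the global seed, so adding
a new generator never perturbs the draws of an existing one.

What the generators emulate:

* ``simulate_genome`` — a multi-chromosome annotation with stranded,
  non-overlapping gene models (2-6 exons, UTR/CDS/intron structure) spaced
  at least one promoter flank apart.
* ``simulate_peaks`` — per-mark peak sets whose genomic-feature category
  mix is controlled exactly (each peak is placed wholly inside an interval
  of its drawn category), and whose pairwise co-occurrence with a primary
  mark is controlled as a net overlap fraction: for a pair (A, B) with
  target f, round(f*n) of the A peaks each receive a B peak nested inside
  them, and the remaining B peaks are placed rejecting any overlap with the
  unselected A peaks.  The default category mix echoes the genome-wide
  distribution observed for histone butyrylation in rice (≈39% CDS, 26%
  intron, 12% promoter, 12% intergenic, 7% 5'UTR, 3% 3'UTR).
* ``simulate_expression`` — FPKM positively coupled to the number of peaks
  on a gene body: log2(FPKM+1) = baseline + coupling * peak_count + noise,
  with a configurable fraction of genes silenced to 0.
* ``simulate_coverage`` — read depth from fixed-length reads: uniform
  Poisson background plus extra reads inside peaks.
* ``simulate_qpcr`` — Ct tables with a known input-vs-ChIP shift at truly
  enriched sites.
* ``simulate_term_map`` — a random gene -> GO-term map for the enrichment
  stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome_io import (CoverageTrack, GeneModel, GenomeAnnotation,
                        GenomicInterval, Peak, PeakSet, write_coverage,
                        write_expression, write_gff3, write_peaks,
                        ExpressionTable)

logger = logging.getLogger(__name__)

_STREAMS = {"genome": 1, "peaks": 2, "expression": 3, "coverage": 4,
            "qpcr": 5, "terms": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


#: category shares echoing the observed genome-wide mark distribution
DEFAULT_CATEGORY_MIX = {
    "cds": 0.39, "five_prime_utr": 0.07, "three_prime_utr": 0.03,
    "intron": 0.26, "promoter": 0.12, "intergenic": 0.13,
}

#: overlap targets echoing the strongest observed mark co-occurrences
DEFAULT_COOCCURRENCE = {
    ("Kbu", "H3K9ac"): 0.80,
    ("Kbu", "H3K23ac"): 0.84,
    ("Kbu", "DHS"): 0.60,
}


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults are the standard study conditions."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 1200
    gene_length_range: tuple[int, int] = (1500, 4000)
    promoter_flank: int = 1000
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    marks: tuple[str, ...] = ("Kbu", "H3K9ac", "H3K23ac", "DHS")
    n_peaks: int = 2000
    peak_length_range: tuple[int, int] = (150, 400)
    cooccurrence: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COOCCURRENCE))
    # peak score laws: ln(fold_enrichment) ~ N(mu, sigma); -log10 q ~ Exp(scale)
    fe_lognorm_mu: float = 2.0
    fe_lognorm_sigma: float = 0.6
    neglog10q_scale: float = 40.0
    # expression model
    expression_coupling: float = 2.0
    expression_baseline: float = 1.0
    expression_noise_sd: float = 1.0
    silent_fraction: float = 0.2
    # coverage model
    read_length: int = 20
    background_rate: float = 0.002      # background read starts per bp
    reads_per_peak: float = 30.0        # mean extra reads per peak
    # qPCR model
    n_qpcr_sites: int = 12              # per class
    ct_shift: float = 1.5               # mean Ct(input) - Ct(ChIP) at enriched sites
    ct_sd: float = 0.3
    # GO term map
    n_terms: int = 30
    term_size_range: tuple[int, int] = (20, 120)

    def validate(self) -> None:
        if self.n_chroms <= 0 or self.n_genes <= 0 or self.n_peaks <= 0:
            raise ConfigError("counts must be > 0")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("category_mix must sum to 1")
        from .genome_io import ALL_CATEGORIES
        unknown = set(self.category_mix) - set(ALL_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown peak categories: {sorted(unknown)}")
        if any(not (0.0 <= v <= 1.0) for v in self.category_mix.values()):
            raise ConfigError("category_mix probabilities must lie in [0, 1]")
        if any(not (0.0 <= v <= 1.0) for v in self.cooccurrence.values()):
            raise ConfigError("cooccurrence targets must lie in [0, 1]")
        if not (0.0 <= self.silent_fraction <= 1.0):
            raise ConfigError("silent_fraction must lie in [0, 1]")
        a_marks = {a for a, _ in self.cooccurrence}
        b_marks = {b for _, b in self.cooccurrence}
        if a_marks & b_marks:
            raise ConfigError("a mark cannot be both anchor and subject of "
                              "co-occurrence targets")
        for pair in self.cooccurrence:
            for m in pair:
                if m not in self.marks:
                    raise ConfigError(f"co-occurrence names unknown mark {m!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cooccurrence"] = {f"{a}|{b}": v for (a, b), v in self.cooccurrence.items()}
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _gene_features(rng: np.random.Generator, chrom: str, start: int, end: int,
                   strand: str) -> list[tuple[str, GenomicInterval]]:
    """Random 2-6 exon structure with UTRs at the transcript ends."""
    length = end - start
    n_ex = int(rng.integers(2, 7))
    min_exon, min_intron = 60, 40
    while n_ex > 2 and n_ex * min_exon + (n_ex - 1) * min_intron > length:
        n_ex -= 1
    n_seg = 2 * n_ex - 1
    mins = np.array([min_exon if i % 2 == 0 else min_intron for i in range(n_seg)])
    spare = length - int(mins.sum())
    if spare < 0:
        raise ConfigError(f"gene of {length} bp too short for {n_ex} exons")
    extra = rng.multinomial(spare, np.full(n_seg, 1.0 / n_seg))
    seg_len = mins + extra
    bounds = start + np.concatenate(([0], np.cumsum(seg_len)))

    exons = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]
    introns = [(int(bounds[i]), int(bounds[i + 1])) for i in range(1, n_seg, 2)]

    first, last = exons[0], exons[-1]
    utr_a = int(min(rng.integers(30, 120), first[1] - first[0] - 20))
    utr_b = int(min(rng.integers(20, 80), last[1] - last[0] - 20))
    # genomic-left UTR piece is 5' on +, 3' on -
    left_cat, right_cat = (("five_prime_utr", "three_prime_utr") if strand == "+"
                           else ("three_prime_utr", "five_prime_utr"))
    features: list[tuple[str, GenomicInterval]] = []
    features.append((left_cat, GenomicInterval(chrom, first[0], first[0] + utr_a, strand)))
    features.append((right_cat, GenomicInterval(chrom, last[1] - utr_b, last[1], strand)))
    for i, (s, e) in enumerate(exons):
        cs, ce = s, e
        if i == 0:
            cs = s + utr_a
        if i == len(exons) - 1:
            ce = e - utr_b
        if cs < ce:
            features.append(("cds", GenomicInterval(chrom, cs, ce, strand)))
    for s, e in introns:
        features.append(("intron", GenomicInterval(chrom, s, e, strand)))
    return sorted(features, key=lambda f: f[1].start)


def simulate_genome(cfg: SimConfig) -> GenomeAnnotation:
    """Place non-overlapping stranded genes with spacing >= promoter_flank."""
    cfg.validate()
    rng = _rng(cfg.seed, "genome")
    lo, hi = cfg.gene_length_range
    per_chrom = [cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms
                                                else 0)
                 for i in range(cfg.n_chroms)]
    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    genes: list[GeneModel] = []
    gid = 0
    for ci, k in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        lens = rng.integers(lo, hi + 1, size=k)
        reserved = int(lens.sum()) + cfg.promoter_flank * (k + 1)
        if reserved > cfg.chrom_length:
            raise ConfigError(
                f"cannot place {k} genes of up to {hi} bp with {cfg.promoter_flank} bp "
                f"spacing on a {cfg.chrom_length} bp chromosome; reduce n_genes or "
                "gene_length_range")
        spare = cfg.chrom_length - reserved
        gaps = rng.multinomial(spare, np.full(k + 1, 1.0 / (k + 1))) + cfg.promoter_flank
        pos = 0
        for i in range(k):
            pos += int(gaps[i])
            start, end = pos, pos + int(lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneModel(
                gene_id=f"gene{gid:05d}",
                interval=GenomicInterval(chrom, start, end, strand),
                features=_gene_features(rng, chrom, start, end, strand)))
            pos = end
    ann = GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes,
                           promoter_flank=cfg.promoter_flank)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

class _CategoryPools:
    """Length-weighted samplers over the per-category interval pools."""

    def __init__(self, ann: GenomeAnnotation, categories):
        from .peak_annotation import FeatureIndex

        index = FeatureIndex(ann)
        self.pools: dict[str, list[tuple[str, int, int]]] = {}
        self.weights: dict[str, np.ndarray] = {}
        for cat in categories:
            ivs = index.intervals(cat)
            if not ivs:
                raise ConfigError(f"category {cat!r} requested by category_mix is "
                                  "absent from the annotation")
            self.pools[cat] = ivs
            w = np.array([e - s for _, s, e in ivs], dtype=float)
            self.weights[cat] = w / w.sum()

    def draw(self, rng: np.random.Generator, cat: str,
             peak_len_range: tuple[int, int]) -> tuple[str, int, int]:
        chrom, s, e = self.pools[cat][
            rng.choice(len(self.pools[cat]), p=self.weights[cat])]
        plen = min(int(rng.integers(*peak_len_range)) if peak_len_range[0]
                   < peak_len_range[1] else peak_len_range[0], e - s)
        plen = max(plen, 1)
        start = int(rng.integers(s, e - plen + 1))
        return chrom, start, start + plen


def _scores(rng: np.random.Generator, cfg: SimConfig) -> tuple[float, float, float]:
    fe = float(rng.lognormal(cfg.fe_lognorm_mu, cfg.fe_lognorm_sigma))
    q = float(rng.exponential(cfg.neglog10q_scale))
    p = q + float(rng.exponential(5.0))
    return fe, p, q


def _overlaps_any(chrom: str, start: int, end: int,
                  by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    if chrom not in by_chrom:
        return False
    starts, ends = by_chrom[chrom]
    i = np.searchsorted(starts, end, side="left")
    # any interval among the first i ends after `start`?
    return bool(i > 0 and (ends[:i] > start).any())


def _interval_index(peaks: list[tuple[str, int, int]]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in peaks:
        by.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in by.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        # running max of ends keeps the any-overlap query correct for nested intervals
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        out[chrom] = (starts, ends)
    return out


class _SelfAvoider:
    """Incremental same-chromosome overlap checker for peak placement."""

    def __init__(self, max_len: int):
        self.max_len = max_len
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        ivs = self.by_chrom.get(chrom)
        if not ivs:
            return False
        # candidates: intervals with start in [start - max_len, end)
        lo = bisect.bisect_left(ivs, (start - self.max_len, -1))
        hi = bisect.bisect_left(ivs, (end, -1))
        return any(e > start for _, e in ivs[lo:hi])

    def add(self, chrom: str, start: int, end: int) -> None:
        import bisect

        bisect.insort(self.by_chrom.setdefault(chrom, []), (start, end))


def simulate_peaks(cfg: SimConfig, ann: GenomeAnnotation) -> dict[str, PeakSet]:
    """Per-mark peak sets with controlled category mix and co-occurrence.

    Peaks of one mark never overlap each other (as with a real peak
    caller's output).  Marks never named as a co-occurrence subject are
    placed purely by ``category_mix``.  A subject mark B of a pair (A, B)
    with target f is generated conditionally on A: a fraction f of the A
    peaks, selected at random stratified by feature category, each receives
    one nested B peak, and the remaining B peaks are placed by the category
    mix while rejecting any overlap with the unselected A peaks — so the
    realised fraction of A peaks touching B equals the target both overall
    and within every feature category.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "peaks")
    cats = list(cfg.category_mix)
    probs = np.array([cfg.category_mix[c] for c in cats])
    pools = _CategoryPools(ann, cats)
    max_len = cfg.peak_length_range[1]

    subject_targets: dict[str, list[tuple[str, float]]] = {}
    for (a, b), f in cfg.cooccurrence.items():
        subject_targets.setdefault(b, []).append((a, f))

    def _free_placement(n: int, own: _SelfAvoider, avoid=None):
        """Place n peaks by category mix; returns (categories, coords)."""
        placed = []
        drawn_cats = [cats[i] for i in rng.choice(len(cats), size=n, p=probs)]
        for cat in drawn_cats:
            for _ in range(200):
                cand = pools.draw(rng, cat, cfg.peak_length_range)
                if own.overlaps(*cand):
                    continue
                if avoid is None or not _overlaps_any(*cand, avoid):
                    break
            else:
                logger.warning("rejection sampling exhausted; keeping overlapping "
                               "placement in %s", cat)
            own.add(*cand)
            placed.append(cand)
        return drawn_cats, placed

    out: dict[str, PeakSet] = {}
    anchor_coords: dict[str, list[tuple[str, int, int]]] = {}
    anchor_cats: dict[str, list[str]] = {}
    anchor_selected: dict[tuple[str, str], np.ndarray] = {}

    # pass 1: anchor marks and marks with no co-occurrence role
    for mark in cfg.marks:
        if mark in subject_targets:
            continue
        mark_cats, coords = _free_placement(cfg.n_peaks, _SelfAvoider(max_len))
        anchor_coords[mark] = coords
        anchor_cats[mark] = mark_cats
        peaks = []
        for i, (chrom, s, e) in enumerate(coords, 1):
            fe, p, q = _scores(rng, cfg)
            peaks.append(Peak(GenomicInterval(chrom, s, e), fold_enrichment=fe,
                              neg_log10_p=p, neg_log10_q=q, name=f"{mark}_{i}"))
        out[mark] = PeakSet(mark=mark, sample="sim", peaks=peaks)

    # pass 2: subject marks, conditional on their anchors
    for mark in cfg.marks:
        if mark not in subject_targets:
            continue
        coords: list[tuple[str, int, int]] = []
        avoid_all: list[tuple[str, int, int]] = []
        own = _SelfAvoider(max_len)
        for a_mark, f in subject_targets[mark]:
            if a_mark not in anchor_coords:
                raise ConfigError(f"anchor mark {a_mark!r} missing for {mark!r}")
            a_coords = anchor_coords[a_mark]
            a_cat = np.array(anchor_cats[a_mark])
            # stratify the selection by anchor category so the overlap
            # fraction holds within every feature class, not just overall
            sel = np.zeros(len(a_coords), dtype=bool)
            for cat in cats:
                idx_cat = np.flatnonzero(a_cat == cat)
                k = int(round(f * len(idx_cat)))
                if k:
                    sel[rng.choice(idx_cat, size=k, replace=False)] = True
            anchor_selected[(a_mark, mark)] = sel
            for (chrom, s, e), take in zip(a_coords, sel):
                if not take:
                    avoid_all.append((chrom, s, e))
                    continue
                plen = min(int(rng.integers(*cfg.peak_length_range)), e - s)
                start = int(rng.integers(s, e - plen + 1))
                coords.append((chrom, start, start + plen))
                own.add(chrom, start, start + plen)
        n_rest = cfg.n_peaks - len(coords)
        if n_rest < 0:
            raise ConfigError(f"mark {mark!r}: co-occurrence targets require more "
                              f"than n_peaks={cfg.n_peaks} peaks")
        avoid = _interval_index(avoid_all)
        coords.extend(_free_placement(n_rest, own=own, avoid=avoid)[1])
        peaks = []
        for i, (chrom, s, e) in enumerate(coords, 1):
            fe, p, q = _scores(rng, cfg)
            peaks.append(Peak(GenomicInterval(chrom, s, e), fold_enrichment=fe,
                              neg_log10_p=p, neg_log10_q=q, name=f"{mark}_{i}"))
        out[mark] = PeakSet(mark=mark, sample="sim", peaks=peaks)
    return out


# ---------------------------------------------------------------------------
# expression, coverage, qPCR, terms
# ---------------------------------------------------------------------------

def simulate_expression(cfg: SimConfig, ann: GenomeAnnotation,
                        kbu: PeakSet) -> ExpressionTable:
    """FPKM coupled to gene-body peak count; a silent fraction forced to 0."""
    import pyranges as pr

    rng = _rng(cfg.seed, "expression")
    genes = sorted(ann.genes, key=lambda g: g.gene_id)
    counts = np.zeros(len(genes))
    if len(kbu) > 0:
        gdf = pr.PyRanges(pd.DataFrame({
            "Chromosome": [g.interval.chrom for g in genes],
            "Start": [g.interval.start for g in genes],
            "End": [g.interval.end for g in genes],
            "GeneIdx": np.arange(len(genes)),
        }))
        pdf = pr.PyRanges(pd.DataFrame({
            "Chromosome": [p.interval.chrom for p in kbu],
            "Start": [p.interval.start for p in kbu],
            "End": [p.interval.end for p in kbu],
        }))
        j = gdf.join(pdf)
        if len(j) > 0:
            c = j.df.groupby("GeneIdx").size()
            counts[c.index.to_numpy()] = c.to_numpy()
    log2 = (cfg.expression_baseline + cfg.expression_coupling * counts
            + rng.normal(0.0, cfg.expression_noise_sd, size=len(genes)))
    fpkm = np.maximum(np.exp2(log2) - 1.0, 0.0)
    silent = rng.random(len(genes)) < cfg.silent_fraction
    fpkm[silent] = 0.0
    return ExpressionTable(fpkm={g.gene_id: float(v) for g, v in zip(genes, fpkm)})


def _depth_rle(read_starts: np.ndarray, read_len: int, L: int):
    """RLE depth profile from read start positions on one chromosome."""
    if len(read_starts) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty(0))
    starts = np.clip(read_starts, 0, L - read_len)
    events = np.concatenate([starts, starts + read_len])
    deltas = np.concatenate([np.ones(len(starts)), -np.ones(len(starts))])
    order = np.argsort(events, kind="stable")
    events, deltas = events[order], deltas[order]
    uniq, idx = np.unique(events, return_index=True)
    depth_at = np.add.reduceat(deltas, idx)
    depth = np.cumsum(depth_at)
    seg_s, seg_e, seg_v = uniq[:-1], uniq[1:], depth[:-1]
    keep = seg_v > 0
    return seg_s[keep], seg_e[keep], seg_v[keep].astype(float)


def simulate_coverage(cfg: SimConfig, peaks: PeakSet,
                      ann: GenomeAnnotation) -> CoverageTrack:
    """Poisson background reads plus extra reads concentrated inside peaks."""
    rng = _rng(cfg.seed, "coverage")
    segments = {}
    total = 0
    peak_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        peak_by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end))
    for chrom in sorted(ann.chrom_lengths):
        L = ann.chrom_lengths[chrom]
        n_bg = int(rng.poisson(cfg.background_rate * L))
        starts = [rng.integers(0, max(L - cfg.read_length, 1), size=n_bg)]
        total += n_bg
        for s, e in peak_by_chrom.get(chrom, []):
            n = int(rng.poisson(cfg.reads_per_peak))
            hi = max(e - cfg.read_length, s + 1)
            starts.append(rng.integers(s, hi, size=n))
            total += n
        all_starts = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        segments[chrom] = _depth_rle(np.sort(all_starts), cfg.read_length, L)
    if total == 0:
        total = 1
    return CoverageTrack(segments, total_mapped=total)


def simulate_qpcr(cfg: SimConfig, sites: list[tuple[str, str]]) -> pd.DataFrame:
    """Ct table for labelled sites: class "peak" sites are truly enriched.

    Ct_chip = Ct_input - ct_shift + noise at enriched sites and
    Ct_input + noise otherwise, with noise ~ N(0, ct_sd).
    """
    rng = _rng(cfg.seed, "qpcr")
    rows = []
    for site_id, site_class in sites:
        ct_in = float(rng.uniform(22.0, 28.0))
        noise = float(rng.normal(0.0, cfg.ct_sd))
        shift = cfg.ct_shift if site_class == "peak" else 0.0
        rows.append({"site_id": site_id, "class": site_class,
                     "ct_input": round(ct_in, 4),
                     "ct_chip": round(ct_in - shift + noise, 4)})
    return pd.DataFrame(rows)


def default_qpcr_sites(cfg: SimConfig) -> list[tuple[str, str]]:
    return ([(f"peak_site_{i + 1:02d}", "peak") for i in range(cfg.n_qpcr_sites)]
            + [(f"non_peak_site_{i + 1:02d}", "non_peak")
               for i in range(cfg.n_qpcr_sites)])


def simulate_term_map(cfg: SimConfig, ann: GenomeAnnotation) -> dict[str, set[str]]:
    """Random gene -> GO-term map over the annotation's genes."""
    rng = _rng(cfg.seed, "terms")
    gene_ids = sorted(g.gene_id for g in ann.genes)
    term_map: dict[str, set[str]] = {}
    lo, hi = cfg.term_size_range
    for t in range(cfg.n_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(lo, min(hi, len(gene_ids)) + 1))
        for g in rng.choice(gene_ids, size=size, replace=False):
            term_map.setdefault(str(g), set()).add(term)
    return term_map


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig):
    """Run every generator once; returns a dict of all artifacts."""
    ann = simulate_genome(cfg)
    peaks = simulate_peaks(cfg, ann)
    primary = cfg.marks[0]
    expr = simulate_expression(cfg, ann, peaks[primary])
    cov = simulate_coverage(cfg, peaks[primary], ann)
    qpcr = simulate_qpcr(cfg, default_qpcr_sites(cfg))
    terms = simulate_term_map(cfg, ann)
    return {"annotation": ann, "peaks": peaks, "expression": expr,
            "coverage": cov, "qpcr": qpcr, "term_map": terms}


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full simulated dataset readable by every pipeline reader."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_all(cfg)
    ann: GenomeAnnotation = data["annotation"]
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.gff3"
    write_gff3(ann, paths["genome"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    paths["chrom_sizes"].write_text(
        "".join(f"{c}\t{L}\n" for c, L in sorted(ann.chrom_lengths.items())))
    for mark, ps in data["peaks"].items():
        paths[f"peaks_{mark}"] = outdir / f"{mark}.broadPeak"
        write_peaks(ps, paths[f"peaks_{mark}"], dialect="broadPeak")
    paths["coverage"] = outdir / "coverage.bedGraph"
    write_coverage(data["coverage"], paths["coverage"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression(data["expression"], paths["expression"])
    paths["qpcr"] = outdir / "qpcr.tsv"
    data["qpcr"].to_csv(paths["qpcr"], sep="\t", index=False, lineterminator="\n")
    paths["terms"] = outdir / "go_terms.tsv"
    with open(paths["terms"], "w") as fh:
        for g in sorted(data["term_map"]):
            for t in sorted(data["term_map"][g]):
                fh.write(f"{g}\t{t}\n")
    paths["config"] = outdir / "sim_config.json"
    paths["config"].write_text(cfg.to_json() + "\n")
    return paths
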