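"""Expression-stratified metagene density profiles and combination testing.

The metagene profile averages normalised read density in 20 bp bins across
TSS +/- 1 kb, oriented in the direction of transcription, over the genes of
each expression group.  Density is reads per kilobase per million mapped
reads: with ``c`` the read count falling in a bin (estimated as the mean
per-base depth over the bin), density = c / 0.02 kb / (total_mapped / 1e6).

Expression groups follow the six-way split used for the stratified
profiles: genes with FPKM = 0 form a "silent" class and the remaining genes
are cut into five equal-size quantile groups from the top 20% down.

The modification-combination analysis partitions genes by presence of two
marks (both / first-only / other-only / neither) and compares FPKM
distributions between partitions with the two-sample Kolmogorov-Smirnov
test, reporting the R-style floor "< 2.2e-16" for vanishing p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import CoverageTrack, ExpressionTable, GenomeAnnotation

logger = logging.getLogger(__name__)

#: R prints p-values below this as "< 2.2e-16"; the combination analysis
#: flags significance at the same level
P_FLOOR_DISPLAY = 2.2e-16

QUANTILE_LABELS = ("top20", "q20_40", "q40_60", "q60_80", "q80_100")
SILENT_LABEL = "silent"


def expression_groups(expr: ExpressionTable, k: int = 6) -> dict[str, str]:
    """Assign each gene to an expression class.

    Genes with FPKM exactly 0 form the silent class; the remaining genes are
    split into ``k - 1`` equal-size groups by descending FPKM (ties broken
    by gene id for determinism).  ``k != 6`` is allowed but logged, since six
    classes (5 quantiles + silent) is the configuration the stratified
    profiles were designed around.
    """
    if not expr.fpkm:
        raise ValidationError("expression_groups on empty table")
    if k < 2:
        raise ValidationError("need k >= 2 expression groups")
    if k != 6:
        logger.warning("expression_groups with k=%d (non-default configuration)", k)
    silent = sorted(g for g, v in expr.fpkm.items() if v == 0)
    expressed = sorted((g for g, v in expr.fpkm.items() if v > 0),
                       key=lambda g: (-expr.fpkm[g], g))
    n_q = k - 1
    labels = (list(QUANTILE_LABELS) if n_q == 5
              else [f"q{i + 1}_of_{n_q}" for i in range(n_q)])
    out: dict[str, str] = {g: SILENT_LABEL for g in silent}
    for chunk, label in zip(np.array_split(np.array(expressed, dtype=object), n_q),
                            labels):
        for g in chunk:
            out[str(g)] = label
    return out


@dataclass
class MetageneProfile:
    """groups x bins matrix of normalised read density around TSSs."""

    groups: list[str]
    bin_starts: np.ndarray      # signed offsets of bin left edges, -1000..980
    density: np.ndarray         # shape (len(groups), n_bins)
    n_genes: dict[str, int]
    bin_size: int = 20

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.density, index=self.groups,
                          columns=[int(b) for b in self.bin_starts])
        df.index.name = "group"
        return df.reset_index()


def metagene_profile(cov: CoverageTrack, ann: GenomeAnnotation,
                     groups: dict[str, str], flank: int = 1000,
                     bin_size: int = 20) -> MetageneProfile:
    """Mean normalised density per expression group in bins around each TSS.

    Profiles are transcription-direction-aware (minus-strand windows are
    mirrored).  Genes truncated by chromosome ends contribute only the
    covered part of each bin; bins entirely off-chromosome are excluded from
    the group mean.
    """
    if cov.total_mapped <= 0:
        raise ValidationError("coverage track with non-positive total_mapped")
    if flank % bin_size != 0:
        raise ValidationError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)  # left edge in transcription coords
    per_million = cov.total_mapped / 1e6
    kb = bin_size / 1000.0

    group_labels = sorted(set(groups.values()))
    sums = {g: np.zeros(n_bins) for g in group_labels}
    counts = {g: np.zeros(n_bins) for g in group_labels}
    n_genes = {g: 0 for g in group_labels}

    for gene in ann.genes:
        label = groups.get(gene.gene_id)
        if label is None:
            continue
        n_genes[label] += 1
        t = gene.tss
        chrom = gene.interval.chrom
        L = ann.chrom_lengths[chrom]
        if gene.interval.strand == "-":
            # transcription offset o maps to genome base t - o
            starts = t - (offsets + bin_size) + 1
            ends = t - offsets + 1
        else:
            starts = t + offsets
            ends = t + offsets + bin_size
        cs = np.clip(starts, 0, L)
        ce = np.clip(ends, 0, L)
        width = ce - cs
        valid = width > 0
        mass = np.zeros(n_bins)
        if valid.any():
            mass[valid] = cov.mass(chrom, cs[valid], ce[valid])
        mean_depth = np.zeros(n_bins)
        mean_depth[valid] = mass[valid] / width[valid]
        sums[label][valid] += mean_depth[valid]
        counts[label][valid] += 1

    density = np.zeros((len(group_labels), n_bins))
    for gi, g in enumerate(group_labels):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_count = np.where(counts[g] > 0, sums[g] / np.maximum(counts[g], 1), 0.0)
        density[gi] = mean_count / kb / per_million
    return MetageneProfile(groups=group_labels, bin_starts=offsets, density=density,
                           n_genes=n_genes, bin_size=bin_size)


def kolmogorov_sf(x: float) -> float:
    """Survival function of the Kolmogorov distribution, Q(x) = P(K > x).

    Two complementary series: the Jacobi theta form for small x (where the
    alternating exponential series converges slowly) and the alternating
    exponential series otherwise; both truncated far below double precision.
    """
    if x <= 1e-8:
        return 1.0
    if x < 1.18:
        t = np.exp(-np.pi ** 2 / (8.0 * x * x))
        cdf = (np.sqrt(2.0 * np.pi) / x) * (t + t ** 9 + t ** 25 + t ** 49)
        return float(min(max(1.0 - cdf, 0.0), 1.0))
    s, sign = 0.0, 1.0
    for k in range(1, 200):
        term = sign * np.exp(-2.0 * k * k * x * x)
        s += term
        if abs(term) < 1e-18:
            break
        sign = -sign
    return float(min(max(2.0 * s, 0.0), 1.0))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum ECDF distance; the p-value comes from the
    asymptotic Kolmogorov distribution evaluated at sqrt(mn/(m+n)) * D,
    floored at the smallest positive normal float.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValidationError("ks_two_sample with empty sample")
    data_all = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, data_all, side="right") / m
    cdf_y = np.searchsorted(y, data_all, side="right") / n
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = m * n / (m + n)
    p = kolmogorov_sf(np.sqrt(en) * d)
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return d, p


def format_pvalue(p: float) -> str:
    """R-style display: values below 2.2e-16 print as '< 2.2e-16'."""
    return "< 2.2e-16" if p < P_FLOOR_DISPLAY else format(p, ".6g")


def five_number(values) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4])}


@dataclass
class GroupExpression:
    """One combination class with its FPKM five-number summary."""

    label: str
    n: int
    summary: dict[str, float] | None


@dataclass
class KsComparison:
    group_a: str
    group_b: str
    d: float | None
    p: float | None
    significant: bool | None

    @property
    def p_display(self) -> str:
        return "NA" if self.p is None else format_pvalue(self.p)


@dataclass
class CombinationResult:
    """Partition of the gene universe by two-mark presence plus KS tests."""

    groups: list[GroupExpression]
    tests: list[KsComparison]

    def group(self, label: str) -> GroupExpression:
        return next(g for g in self.groups if g.label == label)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        g = pd.DataFrame([
            {"group": gr.label, "n": gr.n,
             **(gr.summary or {k: np.nan for k in
                               ("min", "q1", "median", "q3", "max")})}
            for gr in self.groups])
        t = pd.DataFrame([
            {"group_a": c.group_a, "group_b": c.group_b,
             "D": np.nan if c.d is None else c.d,
             "p": np.nan if c.p is None else c.p,
             "p_display": c.p_display,
             "significant": c.significant}
            for c in self.tests])
        return g, t


def combination_analysis(kbu_genes: set[str], other_genes: set[str],
                         expr: ExpressionTable,
                         universe: set[str] | None = None) -> CombinationResult:
    """Compare FPKM between genes carrying one mark, the other, both or neither.

    The universe defaults to all genes in the expression table.  KS tests are
    run for (both vs kbu_only), (both vs other_only) and (kbu_only vs
    neither); a comparison with an empty side is reported NA with a warning.
    """
    if universe is None:
        universe = set(expr.fpkm)
    kbu = kbu_genes & universe
    other = other_genes & universe
    parts = {
        "all": universe,
        "both": kbu & other,
        "kbu_only": kbu - other,
        "other_only": other - kbu,
        "neither": universe - kbu - other,
    }
    values = {label: np.array([expr.fpkm.get(g, 0.0) for g in sorted(genes)])
              for label, genes in parts.items()}
    groups = [GroupExpression(label=label, n=len(v),
                              summary=five_number(v) if len(v) else None)
              for label, v in values.items()]

    tests = []
    for a, b in (("both", "kbu_only"), ("both", "other_only"),
                 ("kbu_only", "neither")):
        if len(values[a]) == 0 or len(values[b]) == 0:
            logger.warning("combination comparison %s vs %s skipped: empty group", a, b)
            tests.append(KsComparison(a, b, None, None, None))
            continue
        d, p = ks_two_sample(values[a], values[b])
        tests.append(KsComparison(a, b, d, p, p < P_FLOOR_DISPLAY))
    return CombinationResult(groups=groups, tests=tests)
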