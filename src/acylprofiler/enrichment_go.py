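"""High-confidence peak filtering and GO term over-representation.

High-confidence peaks are those whose peak-caller scores clear both of two
strict thresholds (fold enrichment > 10 and -log10(q) > 100 by default).
Term over-representation uses the one-sided hypergeometric upper tail
(equivalent to the one-sided Fisher exact test) against a user-supplied
gene -> GO-term map, with Benjamini-Hochberg FDR control across the tested
terms.  Terms are tested as given: no ancestor closure over the GO DAG is
applied unless the term map itself already encodes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, ValidationError
from .genome_io import GenomeAnnotation, PeakSet

logger = logging.getLogger(__name__)


@dataclass
class ConfidenceFilter:
    """Strict lower bounds on MACS-style peak scores."""

    min_fold_enrichment: float = 10.0
    min_neg_log10_q: float = 100.0

    def __post_init__(self) -> None:
        if self.min_fold_enrichment < 0 or self.min_neg_log10_q < 0:
            raise ValidationError("confidence thresholds must be >= 0")


def filter_high_confidence(peaks: PeakSet, f: ConfidenceFilter | None = None) -> PeakSet:
    """Retain peaks with fold_enrichment > min and -log10(q) > min (strict).

    Peaks missing either score are dropped and counted in the log; if every
    peak lacks scores the filter is meaningless and an error is raised.
    """
    f = f or ConfidenceFilter()
    scored = [p for p in peaks
              if p.fold_enrichment is not None and p.neg_log10_q is not None]
    if not scored:
        raise ValidationError("no peaks carry both fold_enrichment and "
                              "neg_log10_q; cannot apply confidence filter")
    dropped = len(peaks) - len(scored)
    if dropped:
        logger.warning("dropped %d peak(s) missing confidence scores", dropped)
    kept = [p for p in scored
            if p.fold_enrichment > f.min_fold_enrichment
            and p.neg_log10_q > f.min_neg_log10_q]
    return PeakSet(mark=peaks.mark, sample=peaks.sample, peaks=kept)


@dataclass
class GoResult:
    term_id: str
    term_name: str
    n_fg_in_term: int
    n_fg: int
    n_bg_in_term: int
    n_bg: int
    p: float
    fdr: float
    significant: bool


def go_enrichment(fg: set[str], bg: set[str],
                  term_map: Mapping[str, set[str]],
                  term_names: Mapping[str, str] | None = None,
                  alpha: float = 0.05) -> list[GoResult]:
    """One-sided over-representation of GO terms in *fg* against *bg*.

    *term_map* maps gene_id -> set of term ids.  Per term the p-value is
    P(X >= n_fg_in_term) for X hypergeometric with population n_bg,
    n_bg_in_term successes and n_fg draws; BH-FDR is applied across all
    tested terms and significance flagged at fdr <= alpha.  Terms with no
    foreground gene are skipped.
    """
    if not fg:
        raise ValidationError("empty foreground gene set")
    if not fg <= bg:
        raise ValidationError(f"foreground is not a subset of background "
                              f"({len(fg - bg)} foreground-only gene(s))")
    if not term_map:
        raise ValidationError("empty term map")
    term_names = term_names or {}

    genes_per_term: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in bg:
            continue
        for t in terms:
            genes_per_term.setdefault(t, set()).add(gene)

    n_bg, n_fg = len(bg), len(fg)
    rows = []
    for term, genes in sorted(genes_per_term.items()):
        k = len(genes & fg)
        if k == 0:
            continue
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_fg))
        rows.append((term, k, K, min(max(p, 0.0), 1.0)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [GoResult(term_id=term, term_name=term_names.get(term, ""),
                        n_fg_in_term=k, n_fg=n_fg, n_bg_in_term=K, n_bg=n_bg,
                        p=p, fdr=float(fdr), significant=bool(fdr <= alpha))
               for (term, k, K, p), fdr in zip(rows, fdrs)]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def go_results_frame(results: list[GoResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": r.term_id, "term_name": r.term_name,
        "n_fg_in_term": r.n_fg_in_term, "n_fg": r.n_fg,
        "n_bg_in_term": r.n_bg_in_term, "n_bg": r.n_bg,
        "p": r.p, "fdr": r.fdr, "significant": r.significant}
        for r in results])


def peaks_to_go_genes(peaks: PeakSet, ann: GenomeAnnotation,
                      f: ConfidenceFilter | None = None,
                      exclude: set[str] | None = None) -> set[str]:
    """High-confidence peak filter composed with gene assignment."""
    from .peak_annotation import assign_genes

    kept = filter_high_confidence(peaks, f)
    if len(kept) == 0:
        return set()
    return assign_genes(kept, ann, exclude=exclude)


def read_term_map(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene->term TSV (gene_id TAB term_id [TAB term_name])."""
    path = Path(path)
    term_map: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected gene_id TAB term_id")
            if lineno == 1 and cols[0].lower() in ("gene_id", "gene"):
                continue
            term_map.setdefault(cols[0], set()).add(cols[1])
            if len(cols) > 2 and cols[2]:
                names[cols[1]] = cols[2]
    return term_map, names
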