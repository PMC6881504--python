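"""ChIP-qPCR delta-Ct enrichment calling.

Input DNA is its own reference, so its normalised threshold cycle (qPCR1)
is 0 by definition.  The enrichment statistic qPCR2 is Ct(input) - Ct(ChIP):
fewer ChIP cycles than input means more immunoprecipitated template at the
site.  A site is called enriched when qPCR2 exceeds 1 cycle (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

SITE_CLASSES = ("peak", "non_peak")


@dataclass
class QpcrRecord:
    site_id: str
    site_class: str          # "peak" or "non_peak"
    ct_input: float
    ct_chip: float
    qpcr1: float             # always 0: input is the reference
    qpcr2: float             # cycles, ct_input - ct_chip
    enriched: bool

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValidationError(f"{self.site_id}: site_class must be one of "
                                  f"{SITE_CLASSES}")


def _mean(ct) -> float:
    if isinstance(ct, (int, float)):
        return float(ct)
    vals = [float(v) for v in ct]
    if not vals:
        raise ValidationError("empty Ct replicate list")
    return sum(vals) / len(vals)


def qpcr_enrichment(ct_input, ct_chip, threshold: float = 1.0,
                    site_id: str = ".", site_class: str = "peak") -> QpcrRecord:
    """Build a QpcrRecord from raw threshold cycles.

    Replicate Ct values (any iterable) are averaged before subtraction.
    The enrichment call uses a strict inequality: qPCR2 > threshold.
    """
    ci, cc = _mean(ct_input), _mean(ct_chip)
    if ci <= 0 or cc <= 0:
        raise ValidationError(f"{site_id}: Ct values must be positive "
                              f"(got input={ci}, chip={cc})")
    q2 = ci - cc
    return QpcrRecord(site_id=site_id, site_class=site_class,
                      ct_input=ci, ct_chip=cc,
                      qpcr1=0.0, qpcr2=q2, enriched=q2 > threshold)


@dataclass
class QpcrSummary:
    """Per-class enrichment counts with the full per-site table."""

    n_sites: dict[str, int]
    n_enriched: dict[str, int]
    frac_enriched: dict[str, float]
    table: pd.DataFrame


def validation_summary(records: Iterable[QpcrRecord]) -> QpcrSummary:
    """Count enriched sites per class; order of records is irrelevant."""
    records = list(records)
    n_sites = {c: 0 for c in SITE_CLASSES}
    n_enriched = {c: 0 for c in SITE_CLASSES}
    for r in records:
        n_sites[r.site_class] += 1
        n_enriched[r.site_class] += int(r.enriched)
    frac = {c: (n_enriched[c] / n_sites[c] if n_sites[c] else 0.0)
            for c in SITE_CLASSES}
    table = pd.DataFrame(
        [{"site_id": r.site_id, "site_class": r.site_class,
          "qPCR1": r.qpcr1, "qPCR2": r.qpcr2, "enriched": r.enriched}
         for r in sorted(records, key=lambda r: (r.site_class, r.site_id))])
    return QpcrSummary(n_sites=n_sites, n_enriched=n_enriched,
                       frac_enriched=frac, table=table)


def read_qpcr_table(path, threshold: float = 1.0) -> list[QpcrRecord]:
    """Read a TSV of site_id, class, ct_input, ct_chip (replicate columns
    ct_input2/ct_chip2 ... are averaged in when present)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"site_id", "class", "ct_input", "ct_chip"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    input_cols = [c for c in df.columns if c.startswith("ct_input")]
    chip_cols = [c for c in df.columns if c.startswith("ct_chip")]
    records = []
    for d in df.to_dict("records"):
        records.append(qpcr_enrichment(
            [d[c] for c in input_cols], [d[c] for c in chip_cols],
            threshold=threshold, site_id=str(d["site_id"]),
            site_class=str(d["class"])))
    return records


def write_qpcr_table(records: Iterable[QpcrRecord], path) -> None:
    validation_summary(records).table.to_csv(path, sep="\t", index=False,
                                             lineterminator="\n")
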