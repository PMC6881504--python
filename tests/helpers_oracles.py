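"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — per-base boolean masks, O(n*m)
scans, explicit enumeration — and shares no code with the implementations
it checks.
"""

import math

import numpy as np

from acylprofiler.genome_io import derive_intergenic, derive_promoters


def category_masks(ann):
    """Per-chromosome boolean mask per category, built base by base."""
    cats = ("cds", "five_prime_utr", "three_prime_utr", "intron",
            "promoter", "intergenic")
    masks = {c: {chrom: np.zeros(L, dtype=bool)
                 for chrom, L in ann.chrom_lengths.items()} for c in cats}
    for g in ann.genes:
        for cat, iv in g.features:
            masks[cat][iv.chrom][iv.start:iv.end] = True
    for p in derive_promoters(ann):
        masks["promoter"][p.chrom][p.start:p.end] = True
    for p in derive_intergenic(ann):
        masks["intergenic"][p.chrom][p.start:p.end] = True
    return masks


def classify_peak_bruteforce(chrom, start, end, masks):
    """Category with max per-base overlap, ties by fixed precedence."""
    order = ("cds", "five_prime_utr", "three_prime_utr", "intron",
             "promoter", "intergenic")
    best_cat, best_bp = "intergenic", -1
    for cat in order:
        bp = int(masks[cat][chrom][start:end].sum())
        if bp > best_bp:
            best_cat, best_bp = cat, bp
    return best_cat if best_bp > 0 else "intergenic"


def assign_genes_bruteforce(peaks, ann):
    out = set()
    for p in peaks:
        for g in ann.genes:
            if p.interval.overlaps(g.interval):
                out.add(g.gene_id)
    return out


def merge_bruteforce(intervals, max_gap=0):
    """Union-find style merge of (chrom, start, end) tuples."""
    by_chrom = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + max_gap:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    return out


def overlapping_indices_bruteforce(query, subject):
    """Indices of query peaks overlapping >= 1 bp of any subject peak."""
    hits = set()
    for i, p in enumerate(query):
        for q in subject:
            if p.interval.overlaps(q.interval):
                hits.add(i)
                break
    return hits


def ks_d_bruteforce(x, y):
    """Supremum ECDF distance via an explicit sweep over all data points."""
    pts = sorted(set(list(x) + list(y)))
    d = 0.0
    for t in pts:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        d = max(d, abs(fx - fy))
    return d


def hypergeom_tail_bruteforce(k, M, K, n):
    """P(X >= k) by explicit summation of the hypergeometric pmf."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        if n - j > M - K:
            continue
        total += (math.comb(K, j) * math.comb(M - K, n - j)) / math.comb(M, n)
    return total
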