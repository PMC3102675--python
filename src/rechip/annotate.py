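"""Peak categorization, TSS association and gene-list overlap testing.

Peaks called independently in the two conditions are reconciled into three
categories — On-only, Off-only and Both (reciprocally overlapping peaks
merged over their union) — and associated with genes whose TSS lies within
a distance cutoff (10 kb by default, measured TSS to nearest peak edge,
inclusive). Genes are then partitioned into the seven regions of the
three-set Venn diagram of their peak categories. miRNA loci get the same
treatment at a 2 kb cutoff against both the TSS and the locus interval.
Overlap between two gene lists is tested with the hypergeometric upper
tail over a stated universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "best_p", "summit_ratio", "condition"]


def _trees(peaks: pd.DataFrame) -> dict:
    trees: dict = {}
    for row in peaks.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.Index)
    return trees


def categorize_peaks(
    peaks_on: pd.DataFrame, peaks_off: pd.DataFrame, ratio_threshold: float = 2.0
) -> pd.DataFrame:
    """Reconcile the two conditions' peaks into On-only/Off-only/Both.

    A peak overlapping no peak of the other condition is condition-specific
    provided its summit-window depth-normalized cross-condition ratio
    exceeds ``ratio_threshold`` (the x2 difference criterion); reciprocally
    overlapping peaks become a single Both peak spanning their union. Peaks
    lacking a ``summit_ratio`` column (e.g. loaded from minimal files) skip
    the ratio check. Condition-specific peaks failing the ratio are
    reported with category ``filtered``.
    """
    frames = []
    trees_off = _trees(peaks_off)
    trees_on = _trees(peaks_on)
    consumed_off: set = set()

    def _ratio_ok(row) -> bool:
        if not hasattr(row, "summit_ratio") or pd.isna(row.summit_ratio):
            return True
        return row.summit_ratio > ratio_threshold

    for row in peaks_on.itertuples():
        hits = trees_off.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        if hits:
            start, end = row.start, row.end
            best_p = row.best_p
            summit = row.summit
            for h in hits:
                consumed_off.add(h.data)
                other = peaks_off.loc[h.data]
                start = min(start, other["start"])
                end = max(end, other["end"])
                if other["best_p"] < best_p:
                    best_p = other["best_p"]
                    summit = other["summit"]
            frames.append((row.chrom, start, end, summit, best_p, "Both"))
        else:
            cat = "On-only" if _ratio_ok(row) else "filtered"
            frames.append((row.chrom, row.start, row.end, row.summit, row.best_p, cat))
    for row in peaks_off.itertuples():
        if row.Index in consumed_off:
            continue
        hits = trees_on.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        if hits:
            # already represented through the On side merge
            continue
        cat = "Off-only" if _ratio_ok(row) else "filtered"
        frames.append((row.chrom, row.start, row.end, row.summit, row.best_p, cat))
    out = pd.DataFrame(
        frames, columns=["chrom", "start", "end", "summit", "best_p", "category"]
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _signed_edge_distance(start: int, end: int, tss: int) -> int:
    """Distance from TSS to the nearest peak edge; 0 when the peak covers it.

    Genomic sign convention: negative when the peak lies left of the TSS.
    """
    if end <= tss:
        return end - 1 - tss
    if start > tss:
        return start - tss
    return 0


def assign_genes(
    peaks: pd.DataFrame, annotation: pd.DataFrame, max_distance: int = 10_000
):
    """Assign categorized peaks to genes by TSS distance and build the Venn.

    A gene is assigned every peak whose interval intersects
    ``[TSS - max_distance, TSS + max_distance]`` (inclusive; a peak near
    several TSS is assigned to each). Returns ``(assignments, venn)``:
    one row per (gene, peak) pair with the signed edge distance, and the
    7-region Venn partition of genes by their category set, keyed e.g.
    ``"On-only"`` or ``"On-only+Both"``. Peaks with category ``filtered``
    are excluded.
    """
    peaks = peaks[peaks["category"] != "filtered"] if len(peaks) else peaks
    trees = _trees(peaks)
    rows = []
    venn: dict = {}
    for gene in annotation.itertuples():
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        # inclusive +-max_distance around the TSS, half-open query interval
        hits = tree.overlap(gene.tss - max_distance, gene.tss + max_distance + 1)
        cats = set()
        for h in sorted(hits):
            peak = peaks.loc[h.data]
            dist = _signed_edge_distance(peak["start"], peak["end"], gene.tss)
            rows.append((gene.gene_id, gene.tss, h.data, dist, peak["category"]))
            cats.add(peak["category"])
        if cats:
            key = "+".join(sorted(cats, key=["On-only", "Off-only", "Both"].index))
            venn[key] = venn.get(key, 0) + 1
    assignments = pd.DataFrame(
        rows, columns=["gene_id", "tss", "peak_index", "distance", "category"]
    )
    return assignments, venn


def mirna_proximity(
    peaks: pd.DataFrame, mirna_annotation: pd.DataFrame, max_distance: int = 2000
) -> pd.DataFrame:
    """miRNAs with a peak within ``max_distance`` of the TSS or the locus.

    A miRNA is a hit when any peak interval comes within ``max_distance``
    (inclusive) of its TSS, or intersects its genomic locus extended by
    ``max_distance`` on both sides. Returns one row per hit miRNA with the
    minimal |distance| to the TSS and the closest peak's category.
    """
    peaks = peaks[peaks["category"] != "filtered"] if len(peaks) else peaks
    rows = []
    for mir in mirna_annotation.itertuples():
        best = None
        for peak in peaks[peaks["chrom"] == mir.chrom].itertuples():
            tss_dist = _signed_edge_distance(peak.start, peak.end, mir.tss)
            near_tss = abs(tss_dist) <= max_distance
            locus_lo = getattr(mir, "locus_start", mir.tss) - max_distance
            locus_hi = getattr(mir, "locus_end", mir.tss + 1) + max_distance
            near_locus = peak.start <= locus_hi and peak.end > locus_lo
            if near_tss or near_locus:
                if best is None or abs(tss_dist) < abs(best[0]):
                    best = (tss_dist, peak.category)
        if best is not None:
            rows.append((mir.mirna_id, mir.chrom, mir.tss, best[0], best[1]))
    return pd.DataFrame(
        rows, columns=["mirna_id", "chrom", "tss", "distance", "category"]
    )


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two gene lists over a universe."""

    overlap: int
    n_a: int
    n_b: int
    n_universe: int
    p_value: float

    @property
    def fraction_a(self) -> float:
        return self.overlap / self.n_a if self.n_a else float("nan")

    @property
    def fraction_b(self) -> float:
        return self.overlap / self.n_b if self.n_b else float("nan")

    @property
    def fraction_min(self) -> float:
        m = min(self.n_a, self.n_b)
        return self.overlap / m if m else float("nan")


def overlap_significance(list_a, list_b, universe) -> OverlapResult:
    """Test whether two gene lists share more members than chance allows.

    ``P(X >= overlap)`` under the hypergeometric null of drawing ``|B|``
    genes from a universe of which ``|A|`` are marked. Symmetric in A and
    B. Several overlap fractions are exposed because the natural
    denominator (|A|, |B| or the smaller list) depends on the question.
    """
    a, b, u = set(list_a), set(list_b), set(universe)
    if not u:
        raise ValueError("universe must be non-empty")
    if not a <= u or not b <= u:
        raise ValueError("both lists must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapResult(overlap=k, n_a=len(a), n_b=len(b), n_universe=len(u), p_value=min(p, 1.0))
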