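"""Windowed Poisson peak calling for two-condition ChIP-seq.

The caller counts 5' read starts in overlapping 1000 bp windows stepped
every 50 bp, computes an upper-tail Poisson P-value per window against the
genome-average expected count, and keeps windows that pass three filters:

* P-value below ``1e-12``;
* window mapability above 25% (fraction of unique 32-mers, supplied as a
  precomputed track on the same grid);
* sense/antisense strand counts within 30% of each other.

Runs of overlapping or grid-adjacent significant windows are merged into
peaks (summit = start of the lowest-P window). Peaks are called
independently per condition and categorized afterwards (see
:mod:`rechip.annotate`); the x2 cross-condition difference criterion is
applied at categorization time by default, since enforcing it while
calling would preclude peaks shared by both conditions.

A random-read control re-runs the identical caller on the same number of
uniformly placed reads to estimate the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GridMismatchError

WINDOW = 1000
STEP = 50


def count_windows(
    reads: pd.DataFrame,
    chrom_sizes: pd.DataFrame,
    window: int = WINDOW,
    step: int = STEP,
):
    """Count 5' read starts in overlapping windows on a fixed grid.

    Windows start at every multiple of ``step`` and must lie fully inside
    the chromosome; a read contributes to every window containing its 5'
    start (``window/step`` windows in the interior). Per-strand tallies are
    retained for the strand-balance filter.

    Returns ``(stats, n_dropped)`` where ``stats`` has columns
    ``chrom, start, count, plus, minus`` and ``n_dropped`` counts reads
    rejected for lying beyond their chromosome (or on an unknown one).
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    k = window // step
    sizes = dict(zip(chrom_sizes["chrom"], chrom_sizes["size"]))
    frames = []
    n_dropped = 0
    by_chrom = dict(iter(reads.groupby("chrom", sort=False))) if len(reads) else {}
    for chrom, size in sizes.items():
        n_steps = size // step  # step bins covering [0, size)
        n_windows = (size - window) // step + 1
        if n_windows <= 0:
            continue
        plus = np.zeros(n_steps, dtype=np.int64)
        minus = np.zeros(n_steps, dtype=np.int64)
        sub = by_chrom.pop(chrom, None)
        if sub is not None and len(sub):
            pos = sub["start"].to_numpy(dtype=np.int64)
            ok = (pos >= 0) & (pos < size)
            n_dropped += int((~ok).sum())
            pos = pos[ok]
            strand = sub["strand"].to_numpy()[ok]
            for arr, mask in ((plus, strand == "+"), (minus, strand != "+")):
                np.add.at(arr, pos[mask] // step, 1)
        # window at grid index i spans step-bins i .. i+k-1
        cp = np.concatenate(([0], np.cumsum(plus)))
        cm = np.concatenate(([0], np.cumsum(minus)))
        wp = cp[k : n_windows + k] - cp[:n_windows]
        wm = cm[k : n_windows + k] - cm[:n_windows]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_windows) * step,
                    "count": wp + wm,
                    "plus": wp,
                    "minus": wm,
                }
            )
        )
    # reads on chromosomes absent from the size table are dropped too
    for sub in by_chrom.values():
        n_dropped += len(sub)
    if not frames:
        out = pd.DataFrame(columns=["chrom", "start", "count", "plus", "minus"])
        return out, n_dropped
    return pd.concat(frames, ignore_index=True), n_dropped


def poisson_pvalue(observed, expected):
    """Upper-tail Poisson probability ``P(X >= k)`` at rate ``expected``.

    Evaluated through the survival function so it stays accurate well
    below 1e-15. Vectorized over ``observed``.
    """
    lam = float(expected)
    if not lam > 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    k = np.asarray(observed)
    if np.any(k < 0):
        raise ValueError("observed count must be non-negative")
    p = stats.poisson.sf(k - 1, lam)  # sf(k-1) = P(X >= k)
    return float(p) if np.isscalar(observed) else p


def strand_balance(plus, minus):
    """Strand imbalance ``|plus - minus| / (plus + minus)`` and the 30% test.

    Returns ``(balance, passes)``; genuine binding enrichment gives
    near-balanced strands, so windows with imbalance above 0.30 fail
    (inclusive boundary: 0.30 passes). A window with zero reads has an
    undefined balance (NaN) and auto-fails.
    """
    plus = np.asarray(plus, dtype=float)
    minus = np.asarray(minus, dtype=float)
    total = plus + minus
    with np.errstate(invalid="ignore", divide="ignore"):
        balance = np.where(total > 0, np.abs(plus - minus) / total, np.nan)
    passes = np.where(total > 0, balance <= 0.30, False)
    if balance.ndim == 0:
        return float(balance), bool(passes)
    return balance, passes


def expected_per_window(
    total_reads: int, mapability: pd.DataFrame, window: int = WINDOW, map_threshold: float = 0.25
) -> float:
    """Genome-average expected count: reads per mappable non-overlapping window."""
    tiling = mapability[mapability["start"] % window == 0]
    n_mappable = int((tiling["mapability"] > map_threshold).sum())
    if n_mappable == 0:
        raise ValueError("no mappable windows; cannot form an expected count")
    return total_reads / n_mappable


def _merge_significant(windows: pd.DataFrame, window: int) -> pd.DataFrame:
    """Merge overlapping/adjacent significant windows into peaks."""
    peaks = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        pvals = sub["p_value"].to_numpy()
        ratios = sub["ratio"].to_numpy()
        run_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or starts[i] > starts[i - 1] + window:
                seg = slice(run_start, i)
                best = np.argmin(pvals[seg]) + run_start
                peaks.append(
                    (
                        chrom,
                        int(starts[run_start]),
                        int(starts[i - 1] + window),
                        int(starts[best]),
                        float(pvals[best]),
                        float(ratios[best]),
                    )
                )
                run_start = i
    return pd.DataFrame(
        peaks, columns=["chrom", "start", "end", "summit", "best_p", "summit_ratio"]
    )


def call_peaks(
    windows_on: pd.DataFrame,
    windows_off: pd.DataFrame,
    mapability: pd.DataFrame,
    p_threshold: float = 1e-12,
    diff_threshold: float = 2.0,
    map_threshold: float = 0.25,
    strand_max: float = 0.30,
    window: int = WINDOW,
    apply_diff_at_call: bool = False,
):
    """Call peaks per condition from counted windows.

    ``windows_on``/``windows_off`` are :func:`count_windows` outputs on the
    same grid; ``mapability`` is a per-window fraction on that grid. A
    window is significant for a condition when its Poisson P-value is
    below ``p_threshold``, its mapability exceeds ``map_threshold`` and its
    strand imbalance is at most ``strand_max``. The depth-normalized
    cross-condition ratio is recorded per window (and per peak summit) for
    the categorization stage; with ``apply_diff_at_call=True`` it is
    additionally required to exceed ``diff_threshold`` at call time.

    Returns ``(peaks_on, peaks_off, annotated_on, annotated_off)`` where
    the annotated frames carry per-window ``expected``, ``p_value``,
    ``mapability``, ``balance`` and ``ratio`` columns.
    """
    key_on = list(zip(windows_on["chrom"], windows_on["start"]))
    key_off = list(zip(windows_off["chrom"], windows_off["start"]))
    if key_on != key_off:
        raise GridMismatchError("On and Off conditions were counted on different grids")
    map_key = list(zip(mapability["chrom"], mapability["start"]))
    if map_key != key_on:
        raise GridMismatchError("mapability track is not on the window grid")

    def _total_reads(win: pd.DataFrame) -> int:
        # overlapping windows overcount by window/step; the non-overlapping
        # tiling (starts on the window grid) recovers the read total
        return int(win.loc[win["start"] % window == 0, "count"].sum())

    totals = {
        "on": max(_total_reads(windows_on), 1),
        "off": max(_total_reads(windows_off), 1),
    }
    results = {}
    annotated = {}
    for cond, own, other in (("on", windows_on, windows_off), ("off", windows_off, windows_on)):
        lam = expected_per_window(
            totals[cond], mapability, window=window, map_threshold=map_threshold
        )
        win = own.copy()
        win["expected"] = lam
        win["p_value"] = poisson_pvalue(win["count"].to_numpy(), lam)
        win["mapability"] = mapability["mapability"].to_numpy()
        balance, strand_ok = strand_balance(win["plus"].to_numpy(), win["minus"].to_numpy())
        win["balance"] = balance
        own_depth = totals[cond]
        other_depth = totals["off" if cond == "on" else "on"]
        own_norm = win["count"].to_numpy() / own_depth
        other_norm = other["count"].to_numpy() / other_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                other_norm > 0, own_norm / other_norm, np.where(own_norm > 0, np.inf, np.nan)
            )
        win["ratio"] = ratio
        sig = (
            (win["p_value"] < p_threshold)
            & (win["mapability"] > map_threshold)
            & strand_ok
        )
        if apply_diff_at_call:
            sig &= win["ratio"] > diff_threshold
        peaks = _merge_significant(win[sig], window=window)
        peaks["condition"] = cond
        results[cond] = peaks
        annotated[cond] = win
    return results["on"], results["off"], annotated["on"], annotated["off"]


def tss_profile(
    reads: pd.DataFrame,
    annotation: pd.DataFrame,
    span: int = 10_000,
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Aggregate read density in windows at fixed offsets from every TSS.

    For each offset ``o`` on a ``step`` grid in ``[-span, span]``, counts
    reads whose 5' start falls in the window of width ``window`` centered
    at ``TSS + o``, summed over all genes and strand-oriented (upstream of
    the gene is negative). Returns ``offset_bp, count, density`` with
    density normalized to sum to 1 (all-zero profiles stay zero).
    """
    if len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    offsets = np.arange(-span, span + 1, step)
    half = window // 2
    lo = -span - half
    n_bins = (2 * span + window) // step
    acc = np.zeros(n_bins, dtype=np.int64)
    k = window // step
    by_chrom = dict(iter(reads.groupby("chrom", sort=False))) if len(reads) else {}
    for chrom, genes in annotation.groupby("chrom", sort=False):
        sub = by_chrom.get(chrom)
        if sub is None or not len(sub):
            continue
        pos = np.sort(sub["start"].to_numpy(dtype=np.int64))
        for row in genes.itertuples():
            rel = pos - row.tss
            if row.strand == "-":
                rel = -rel
            sel = rel[(rel >= lo) & (rel < lo + n_bins * step)]
            if sel.size:
                acc += np.bincount((sel - lo) // step, minlength=n_bins)
    # sliding sum of k step-bins gives the count of the window centered at each offset
    c = np.concatenate(([0], np.cumsum(acc)))
    counts = c[k:] - c[: len(offsets)]
    counts = counts[: len(offsets)]
    total = counts.sum()
    density = counts / total if total > 0 else counts.astype(float)
    return pd.DataFrame({"offset_bp": offsets, "count": counts, "density": density})


def simulate_uniform_reads(
    n_per_condition: dict,
    chrom_sizes: pd.DataFrame,
    mapability: pd.DataFrame,
    rng: np.random.Generator,
    window: int = WINDOW,
    map_threshold: float = 0.25,
) -> dict:
    """Place reads uniformly over the mappable genome (random-read control).

    Positions falling in non-mappable 1 kb tiling windows are rejection-
    resampled so the control matches the mappable-genome background.
    """
    tiling = mapability[mapability["start"] % window == 0]
    low = {
        (r.chrom, r.start) for r in tiling.itertuples() if r.mapability <= map_threshold
    }
    sizes = list(zip(chrom_sizes["chrom"], chrom_sizes["size"]))
    total = sum(s for _, s in sizes)
    bounds = np.cumsum([s for _, s in sizes])
    out = {}
    for cond, n in n_per_condition.items():
        chroms = np.empty(n, dtype=object)
        starts = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.integers(0, total, size=(n - filled) * 2 + 16)
            ci = np.searchsorted(bounds, draw, side="right")
            for g, c in zip(draw, ci):
                pos = int(g - (bounds[c - 1] if c > 0 else 0))
                chrom = sizes[c][0]
                if (chrom, (pos // window) * window) in low:
                    continue
                chroms[filled] = chrom
                starts[filled] = pos
                filled += 1
                if filled == n:
                    break
        out[cond] = pd.DataFrame(
            {"chrom": chroms, "start": starts, "strand": rng.choice(["+", "-"], size=n)}
        )
    return out


@dataclass
class FDRResult:
    """Random-read false discovery estimate for the peak caller."""

    n_real_peaks: int
    n_random_peaks: int
    seed: int

    @property
    def fdr(self) -> float:
        """random peaks / real peaks; NaN when no real peaks were called."""
        if self.n_real_peaks == 0:
            return float("nan")
        return self.n_random_peaks / self.n_real_peaks


def estimate_fdr(
    reads_on: pd.DataFrame,
    reads_off: pd.DataFrame,
    chrom_sizes: pd.DataFrame,
    mapability: pd.DataFrame,
    seed: int,
    **caller_kwargs,
) -> FDRResult:
    """Estimate the caller's FDR with an equal-size uniform random control.

    Calls peaks on the real reads, then places the same number of reads per
    condition uniformly at random over the mappable genome, re-runs the
    identical caller, and reports random-control peaks over real peaks.
    Deterministic under ``seed``.
    """
    won, d1 = count_windows(reads_on, chrom_sizes)
    woff, d2 = count_windows(reads_off, chrom_sizes)
    p_on, p_off, _, _ = call_peaks(won, woff, mapability, **caller_kwargs)
    n_real = len(p_on) + len(p_off)

    rng = np.random.default_rng(seed)
    rand = simulate_uniform_reads(
        {"on": len(reads_on), "off": len(reads_off)}, chrom_sizes, mapability, rng
    )
    rwon, _ = count_windows(rand["on"], chrom_sizes)
    rwoff, _ = count_windows(rand["off"], chrom_sizes)
    rp_on, rp_off, _, _ = call_peaks(rwon, rwoff, mapability, **caller_kwargs)
    return FDRResult(n_real_peaks=n_real, n_random_peaks=len(rp_on) + len(rp_off), seed=seed)


# ---------------------------------------------------------------------------
# Model / Results facade


@dataclass
class OccupancyResults:
    """Fitted differential-occupancy results.

    Carries per-window statistics and merged peaks for both conditions,
    the categorized peak set, and (when an annotation was supplied to the
    model) the per-gene assignments and Venn partition.
    """

    model: "DifferentialOccupancyModel"
    peaks_on: pd.DataFrame
    peaks_off: pd.DataFrame
    windows_on: pd.DataFrame
    windows_off: pd.DataFrame
    n_dropped_on: int
    n_dropped_off: int
    categorized: pd.DataFrame = None
    gene_assignments: pd.DataFrame = None
    venn: dict = None

    def summary(self) -> str:
        lines = [
            "Differential occupancy (windowed Poisson caller)",
            "=" * 48,
            f"windows evaluated:      {len(self.windows_on)}",
            f"reads dropped (On/Off): {self.n_dropped_on}/{self.n_dropped_off}",
            f"peaks On:               {len(self.peaks_on)}",
            f"peaks Off:              {len(self.peaks_off)}",
        ]
        if self.categorized is not None and len(self.categorized):
            counts = self.categorized["category"].value_counts().to_dict()
            lines.append(f"categorized peaks:      {counts}")
        if self.venn is not None:
            lines.append(f"gene Venn partition:    {self.venn}")
        return "\n".join(lines)

    def estimate_fdr(self, seed: int, **caller_kwargs) -> FDRResult:
        kwargs = {**self.model._caller_kwargs(), **caller_kwargs}
        return estimate_fdr(
            self.model.reads_on,
            self.model.reads_off,
            self.model.chrom_sizes,
            self.model.mapability,
            seed=seed,
            **kwargs,
        )

    def tss_profile(self, condition: str = "on", span: int = 10_000) -> pd.DataFrame:
        reads = self.model.reads_on if condition.lower() == "on" else self.model.reads_off
        return tss_profile(reads, self.model.annotation, span=span)

    def plot_profile(self, condition: str = "on", span: int = 10_000, ax=None):
        """Read density around the TSS, the diagnostic view of enrichment."""
        import matplotlib.pyplot as plt

        prof = self.tss_profile(condition=condition, span=span)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(prof["offset_bp"], prof["density"])
        ax.set_xlabel("distance from TSS (bp)")
        ax.set_ylabel("read density")
        ax.set_title(f"TSS profile ({condition})")
        return ax


@dataclass
class DifferentialOccupancyModel:
    """Two-condition windowed Poisson occupancy model.

    Parameters mirror the caller defaults: 1000 bp windows every 50 bp,
    P < 1e-12, mapability > 0.25, strand imbalance <= 0.30, cross-condition
    ratio > 2 at categorization.
    """

    reads_on: pd.DataFrame
    reads_off: pd.DataFrame
    chrom_sizes: pd.DataFrame
    mapability: pd.DataFrame
    annotation: pd.DataFrame = None
    window: int = WINDOW
    step: int = STEP
    p_threshold: float = 1e-12
    diff_threshold: float = 2.0
    map_threshold: float = 0.25
    strand_max: float = 0.30
    apply_diff_at_call: bool = False
    gene_distance: int = 10_000

    def _caller_kwargs(self) -> dict:
        return dict(
            p_threshold=self.p_threshold,
            diff_threshold=self.diff_threshold,
            map_threshold=self.map_threshold,
            strand_max=self.strand_max,
            window=self.window,
            apply_diff_at_call=self.apply_diff_at_call,
        )

    def fit(self) -> OccupancyResults:
        from .annotate import assign_genes, categorize_peaks

        won, dropped_on = count_windows(
            self.reads_on, self.chrom_sizes, window=self.window, step=self.step
        )
        woff, dropped_off = count_windows(
            self.reads_off, self.chrom_sizes, window=self.window, step=self.step
        )
        p_on, p_off, a_on, a_off = call_peaks(won, woff, self.mapability, **self._caller_kwargs())
        categorized = categorize_peaks(p_on, p_off, ratio_threshold=self.diff_threshold)
        res = OccupancyResults(
            model=self,
            peaks_on=p_on,
            peaks_off=p_off,
            windows_on=a_on,
            windows_off=a_off,
            n_dropped_on=dropped_on,
            n_dropped_off=dropped_off,
            categorized=categorized,
        )
        if self.annotation is not None and len(self.annotation):
            assignments, venn = assign_genes(
                categorized, self.annotation, max_distance=self.gene_distance
            )
            res.gene_assignments = assignments
            res.venn = venn
        return res
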