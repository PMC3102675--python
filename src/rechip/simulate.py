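"""Seeded synthetic data with the structure the analysis stages assume.

Generates, without any external download:

* a gene annotation (TSS records) over a small multi-chromosome genome,
  with each gene assigned an occupancy class (``on_only`` / ``off_only`` /
  ``both`` / ``none``) and a binding-site center near its TSS;
* aligned-read collections for the two conditions: uniform background plus
  Gaussian read clouds around the active sites;
* a per-window mapability track with a configurable fraction of windows
  forced below the caller's 25% threshold;
* replicate two-channel probe intensities over 1.5 kb tiled promoter
  regions, a subset carrying a contiguous enriched sub-window;
* a two-group miRNA expression matrix with known multiplicative effects.

All generators are deterministic functions of ``SyntheticConfig.seed``:
identical config and seed give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# default caller grid; mapability must live on the same grid
WINDOW = 1000
STEP = 50

# minimal TSS spacing so neighbouring sites produce distinct peaks
MIN_GENE_SPACING = 20_000

# stream ids keep the per-purpose RNGs independent under one seed
_STREAM_ANNOTATION = 1
_STREAM_READS_ON = 2
_STREAM_READS_OFF = 3
_STREAM_MAPABILITY = 4
_STREAM_ARRAY = 5
_STREAM_MIRNA = 6
_STREAM_MIRNA_ANNOT = 7


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    The defaults describe the desk-scale study the test-suite and the
    acceptance run use: a 10 Mb genome (2 x 5 Mb), 120 genes of which 90
    carry binding sites (30 active in the On condition only, 30 in Off
    only, 30 in both), a uniform background of 0.005 reads/bp/condition
    (about 5 reads per 1 kb window) and 200 reads per active site.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 120
    n_mirnas: int = 40
    site_classes: dict = field(
        default_factory=lambda: {"on_only": 30, "off_only": 30, "both": 30, "none": 30}
    )
    background_rate: float = 0.005  # reads per bp per condition
    spike_reads: int = 200  # reads per active site per condition
    spike_spread: float = 200.0  # sd (bp) of read offsets around site center
    site_offset_range: int = 1500  # site center within +-range of the TSS
    low_map_fraction: float = 0.05  # windows forced below the 25% threshold
    read_length: int = 36
    # tiled promoter array: 1.5 kb regions, 50 bp probes, >=2 replicate spots
    array_regions: int = 148
    probes_per_region: int = 30
    array_replicates: int = 2
    array_spiked_regions: int = 20
    array_spike_probes: int = 5  # contiguous probes carrying the effect
    array_effect: float = 3.0  # log2 On/Off elevation of spiked windows
    array_noise_sd: float = 0.25  # log2 units, per spot per channel
    # miRNA expression: two groups, multiplicative effects, CV noise
    mirna_replicates: int = 4
    mirna_n_up: int = 10
    mirna_n_down: int = 10
    mirna_effect_range: tuple = (1.6, 4.0)  # fold, drawn uniformly
    mirna_noise_cv: float = 0.1

    def __post_init__(self):
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")
        total = sum(self.site_classes.values())
        if total != self.n_genes:
            raise ConfigurationError(
                f"site_classes counts sum to {total}, expected n_genes={self.n_genes}"
            )
        unknown = set(self.site_classes) - {"on_only", "off_only", "both", "none"}
        if unknown:
            raise ConfigurationError(f"unknown site classes: {sorted(unknown)}")
        if self.probes_per_region * 50 > 1500:
            raise ConfigurationError(
                "probes_per_region x 50 bp exceeds the 1.5 kb region length"
            )
        if self.mirna_n_up + self.mirna_n_down > self.n_mirnas:
            raise ConfigurationError("more affected miRNAs than n_mirnas")

    @property
    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def chrom_sizes_table(config: SyntheticConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": config.chrom_names, "size": [config.chrom_length] * config.n_chroms}
    )


def make_annotation(config: SyntheticConfig):
    """Place genes on the genome and assign each a site class.

    Returns ``(annotation, chrom_sizes)``. The annotation has one row per
    gene: ``gene_id, chrom, tss, strand, site_class, site_center``.
    ``site_center`` is the binding-site position used by
    :func:`simulate_reads`; it always lies within ``site_offset_range`` of
    the TSS. Deterministic under ``config.seed``.
    """
    sizes = chrom_sizes_table(config)
    if config.n_genes == 0:
        empty = pd.DataFrame(
            columns=["gene_id", "chrom", "tss", "strand", "site_class", "site_center"]
        )
        return empty, sizes
    if config.n_genes * MIN_GENE_SPACING > config.genome_length:
        raise ConfigurationError(
            f"cannot place {config.n_genes} genes with {MIN_GENE_SPACING} bp "
            f"spacing on a {config.genome_length} bp genome"
        )
    rng = _rng(config, _STREAM_ANNOTATION)
    # round-robin over chromosomes, evenly spaced slots with jitter
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    rows = []
    gid = 0
    margin = config.site_offset_range + 5 * int(config.spike_spread) + WINDOW
    for chrom, n in zip(config.chrom_names, per_chrom):
        if n == 0:
            continue
        slot = config.chrom_length / n
        jitter_max = max(1, min(int(slot / 4), 5000))
        for j in range(n):
            base = int((j + 0.5) * slot)
            tss = base + int(rng.integers(-jitter_max, jitter_max + 1))
            tss = int(np.clip(tss, margin, config.chrom_length - margin - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene_{gid:04d}", chrom, tss, strand))
            gid += 1
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    # every gene gets exactly one class; shuffled assignment
    labels = np.repeat(
        list(config.site_classes.keys()), list(config.site_classes.values())
    )
    rng.shuffle(labels)
    ann["site_class"] = labels
    offsets = rng.integers(
        -config.site_offset_range, config.site_offset_range + 1, size=len(ann)
    )
    ann["site_center"] = ann["tss"].to_numpy() + offsets
    return ann, sizes


def make_mirna_annotation(config: SyntheticConfig) -> pd.DataFrame:
    """miRNA loci (TSS plus a short hairpin interval) interleaved between genes."""
    rng = _rng(config, _STREAM_MIRNA_ANNOT)
    rows = []
    if config.n_mirnas == 0:
        return pd.DataFrame(
            columns=["mirna_id", "chrom", "tss", "strand", "locus_start", "locus_end"]
        )
    per_chrom = [config.n_mirnas // config.n_chroms] * config.n_chroms
    for i in range(config.n_mirnas % config.n_chroms):
        per_chrom[i] += 1
    mid = 0
    for chrom, n in zip(config.chrom_names, per_chrom):
        if n == 0:
            continue
        slot = config.chrom_length / n
        for j in range(n):
            # offset by a third of a slot to avoid sitting on gene TSS slots
            tss = int((j + 1 / 3) * slot) + int(rng.integers(-2000, 2001))
            tss = int(np.clip(tss, 5000, config.chrom_length - 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"sim-mir-{mid:03d}", chrom, tss, strand, tss, tss + 85))
            mid += 1
    return pd.DataFrame(
        rows, columns=["mirna_id", "chrom", "tss", "strand", "locus_start", "locus_end"]
    )


_ACTIVE = {"on": {"on_only", "both"}, "off": {"off_only", "both"}}


def simulate_reads(
    annotation: pd.DataFrame, config: SyntheticConfig, condition: str
) -> pd.DataFrame:
    """Aligned reads for one condition: uniform background plus site spikes.

    Background reads are placed uniformly (count ``round(background_rate x
    chrom_length)`` per chromosome) with random strand. Each site whose
    class is active in ``condition`` emits ``spike_reads`` reads at
    ``Normal(site_center, spike_spread)``, strands 50/50. Returns a
    DataFrame ``chrom, start, strand`` of 5' read-start positions (0-based),
    sorted by position.
    """
    cond = condition.lower()
    if cond not in _ACTIVE:
        raise ConfigurationError(f"condition must be 'on' or 'off', got {condition!r}")
    rng = _rng(config, _STREAM_READS_ON if cond == "on" else _STREAM_READS_OFF)
    hi = config.chrom_length - config.read_length
    chroms, starts, strands = [], [], []
    n_bg = int(round(config.background_rate * config.chrom_length))
    for chrom in config.chrom_names:
        if n_bg > 0:
            pos = rng.integers(0, hi + 1, size=n_bg)
            chroms.append(np.full(n_bg, chrom, dtype=object))
            starts.append(pos)
            strands.append(rng.choice(["+", "-"], size=n_bg))
    if config.spike_reads > 0 and len(annotation):
        active = annotation[annotation["site_class"].isin(_ACTIVE[cond])]
        for row in active.itertuples():
            pos = np.rint(
                rng.normal(row.site_center, config.spike_spread, size=config.spike_reads)
            ).astype(np.int64)
            np.clip(pos, 0, hi, out=pos)
            chroms.append(np.full(config.spike_reads, row.chrom, dtype=object))
            starts.append(pos)
            strands.append(rng.choice(["+", "-"], size=config.spike_reads))
    if not starts:
        return pd.DataFrame(columns=["chrom", "start", "strand"])
    reads = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": np.concatenate(starts),
            "strand": np.concatenate(strands),
        }
    )
    return reads.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_mapability(
    config: SyntheticConfig, window: int = WINDOW, step: int = STEP
) -> pd.DataFrame:
    """Per-window mapability on the caller's grid.

    A ``low_map_fraction`` of windows (Bernoulli per window) receive a
    value drawn uniformly below 0.25; all others are fully mappable (1.0).
    """
    rng = _rng(config, _STREAM_MAPABILITY)
    frames = []
    for chrom in config.chrom_names:
        starts = np.arange(0, config.chrom_length - window + 1, step)
        low = rng.random(starts.size) < config.low_map_fraction
        values = np.ones(starts.size)
        values[low] = rng.uniform(0.0, 0.25, size=int(low.sum()))
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "mapability": values}))
    return pd.concat(frames, ignore_index=True)


def simulate_array(config: SyntheticConfig):
    """Replicate two-channel probe intensities over tiled promoter regions.

    Each region is 1.5 kb tiled every 50 bp; each probe is spotted
    ``array_replicates`` times. Spiked regions carry a contiguous run of
    ``array_spike_probes`` probes whose On channel is elevated by
    ``array_effect`` log2 units. Channel noise is Normal(0, array_noise_sd)
    in log2, independent per spot and channel, on a flat nominal intensity
    of 1000 so that with zero noise the spiked log2 ratio is exactly the
    effect after median normalization.

    Returns ``(probes, truth)``: the long-format probe table
    (``probe_id, region_id, offset, replicate, signal_on, signal_off``) and
    a per-region truth table with the spiked sub-window coordinates.
    """
    rng = _rng(config, _STREAM_ARRAY)
    n_reg, n_probe, n_rep = (
        config.array_regions,
        config.probes_per_region,
        config.array_replicates,
    )
    region_ids = [f"region_{i:03d}" for i in range(n_reg)]
    spiked_idx = set(
        rng.choice(n_reg, size=min(config.array_spiked_regions, n_reg), replace=False).tolist()
    )
    max_start = max(0, n_probe - config.array_spike_probes)
    spike_starts = {i: int(rng.integers(0, max_start + 1)) for i in sorted(spiked_idx)}

    offsets = np.arange(n_probe) * 50
    base = 1000.0
    rows_truth = []
    reg_col, probe_col, off_col, rep_col = [], [], [], []
    on_col, off_sig_col = [], []
    for i, rid in enumerate(region_ids):
        effect = np.zeros(n_probe)
        if i in spiked_idx:
            s = spike_starts[i]
            effect[s : s + config.array_spike_probes] = config.array_effect
            rows_truth.append(
                (rid, True, int(offsets[s]), int(offsets[s + config.array_spike_probes - 1] + 50))
            )
        else:
            rows_truth.append((rid, False, -1, -1))
        for rep in range(1, n_rep + 1):
            noise_on = rng.normal(0.0, config.array_noise_sd, size=n_probe)
            noise_off = rng.normal(0.0, config.array_noise_sd, size=n_probe)
            reg_col.append(np.full(n_probe, rid, dtype=object))
            probe_col.append(np.array([f"{rid}_p{j:02d}" for j in range(n_probe)], dtype=object))
            off_col.append(offsets)
            rep_col.append(np.full(n_probe, rep))
            on_col.append(base * np.exp2(effect + noise_on))
            off_sig_col.append(base * np.exp2(noise_off))
    probes = pd.DataFrame(
        {
            "probe_id": np.concatenate(probe_col),
            "region_id": np.concatenate(reg_col),
            "offset": np.concatenate(off_col),
            "replicate": np.concatenate(rep_col),
            "signal_on": np.concatenate(on_col),
            "signal_off": np.concatenate(off_sig_col),
        }
    )
    truth = pd.DataFrame(
        rows_truth, columns=["region_id", "spiked", "spike_start", "spike_end"]
    )
    return probes, truth


def simulate_mirna(config: SyntheticConfig):
    """Two-group miRNA expression matrix with known fold effects.

    Baseline abundances are log-uniform between 200 and 20000 intensity
    units; ``mirna_n_up`` miRNAs have their On-group mean multiplied by a
    fold drawn from ``mirna_effect_range`` and ``mirna_n_down`` divided by
    one. Measurement noise is multiplicative with coefficient of variation
    ``mirna_noise_cv``.

    Returns ``(matrix, groups, truth)``: intensity matrix (miRNA x sample),
    a ``{"off": [...], "on": [...]}`` sample map, and the truth table with
    the signed true fold per miRNA (+1.0 for unaffected).
    """
    if config.mirna_replicates < 2:
        raise ConfigurationError("need >=2 replicates per group")
    rng = _rng(config, _STREAM_MIRNA)
    n = config.n_mirnas
    ids = [f"sim-mir-{i:03d}" for i in range(n)]
    baseline = 10.0 ** rng.uniform(np.log10(200), np.log10(20000), size=n)
    affected = rng.choice(n, size=config.mirna_n_up + config.mirna_n_down, replace=False)
    up, down = affected[: config.mirna_n_up], affected[config.mirna_n_up :]
    lo, hi = config.mirna_effect_range
    fold = np.ones(n)
    fold[up] = rng.uniform(lo, hi, size=up.size)
    fold[down] = 1.0 / rng.uniform(lo, hi, size=down.size)

    cols, data = [], []
    for g, mult in (("off", np.ones(n)), ("on", fold)):
        for r in range(1, config.mirna_replicates + 1):
            noise = 1.0 + config.mirna_noise_cv * rng.standard_normal(n)
            data.append(np.maximum(baseline * mult * noise, 1e-6))
            cols.append(f"{g}_{r}")
    matrix = pd.DataFrame(np.column_stack(data), index=pd.Index(ids, name="mirna_id"), columns=cols)
    groups = {
        "off": [c for c in cols if c.startswith("off_")],
        "on": [c for c in cols if c.startswith("on_")],
    }
    signed = np.where(fold >= 1.0, fold, -1.0 / fold)
    truth = pd.DataFrame(
        {
            "mirna_id": ids,
            "baseline": baseline,
            "true_fold": signed,
            "affected": fold != 1.0,
        }
    )
    return matrix, groups, truth
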