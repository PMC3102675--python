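"""End-to-end pipeline: simulate (optional) -> call -> annotate -> report.

``run_pipeline`` chains every stage on either user-supplied files or the
bundled synthetic generator, writes each stage's outputs into a run
directory, and returns a manifest listing every output with a sha256
content hash (so reruns under the same seed are verifiably identical).
Stages without inputs are skipped and noted in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import pandas as pd

from . import io as rio
from .array import TilingArrayModel
from .annotate import mirna_proximity
from .chipseq import DifferentialOccupancyModel
from .errors import ConfigurationError, RechipError
from .mirna import MiRNADifferentialModel
from .simulate import (
    SyntheticConfig,
    make_annotation,
    make_mirna_annotation,
    simulate_array,
    simulate_mapability,
    simulate_mirna,
    simulate_reads,
)

log = logging.getLogger("rechip")


@dataclass
class PipelineConfig:
    """All stage inputs and thresholds; defaults are the published values."""

    out_dir: str = "rechip_run"
    seed: int = 0
    synthetic: bool = True  # generate inputs when paths are not given
    # input paths (all optional when synthetic)
    reads_on: str = None
    reads_off: str = None
    chrom_sizes: str = None
    mapability: str = None
    annotation: str = None
    mirna_annotation: str = None
    probes: str = None
    mirna_matrix: str = None
    mirna_groups: str = None
    # ChIP-seq caller
    window: int = 1000
    step: int = 50
    p_threshold: float = 1e-12
    diff_threshold: float = 2.0
    map_threshold: float = 0.25
    strand_max: float = 0.30
    # association distances
    gene_distance: int = 10_000
    mirna_distance: int = 2_000
    # tiling array
    array_window: int = 250
    array_step: int = 50
    array_alpha: float = 0.01
    cv_max: float = 0.30
    # miRNA filter
    fold_min: float = 1.5
    abs_min: float = 100.0
    mirna_alpha: float = 0.05
    run_fdr: bool = True

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat ``key = value`` config file; explicit overrides win and are logged."""
        values: dict = {}
        known = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"{path}:{lineno}: expected key = value")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = _coerce(raw, getattr(cls, key, None))
        for key, val in overrides.items():
            if val is not None:
                if key in values and values[key] != val:
                    log.info("config override: %s = %r (file had %r)", key, val, values[key])
                values[key] = val
        return cls(**values)


def _coerce(raw: str, default):
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    for cast in (int, float):
        if isinstance(default, cast):
            return cast(raw)
    return raw


class StageError(RechipError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every runnable stage and return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.json").exists():
        raise ConfigurationError(f"{out} already holds a run; outputs are write-once")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"outputs": {}, "skipped": [], "config": asdict(config)}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": rio.sha256_of(path),
        }

    try:
        log.info("effective config: %s", asdict(config))
        syn = SyntheticConfig(seed=config.seed) if config.synthetic else None

        # --- inputs -------------------------------------------------------
        stage = "inputs"
        try:
            if config.reads_on and config.reads_off:
                reads_on = rio.read_bed(config.reads_on)
                reads_off = rio.read_bed(config.reads_off)
                sizes = rio.read_chrom_sizes(config.chrom_sizes)
                mapab = rio.read_mapability(config.mapability)
                annotation = (
                    rio.read_annotation(config.annotation) if config.annotation else None
                )
            elif syn is not None:
                indir = out / "inputs"
                indir.mkdir(exist_ok=True)
                annotation, sizes = make_annotation(syn)
                reads_on = simulate_reads(annotation, syn, "on")
                reads_off = simulate_reads(annotation, syn, "off")
                mapab = simulate_mapability(syn)
                rio.write_bed(reads_on, indir / "reads_on.bed")
                rio.write_bed(reads_off, indir / "reads_off.bed")
                rio.write_chrom_sizes(sizes, indir / "chrom.sizes")
                rio.write_tsv(mapab, indir / "mapability.tsv")
                rio.write_tsv(annotation, indir / "genes.tsv")
                for name in ("reads_on.bed", "reads_off.bed", "chrom.sizes",
                             "mapability.tsv", "genes.tsv"):
                    record(f"inputs/{name}", indir / name)
            else:
                raise ConfigurationError("no read inputs and synthetic generation disabled")
        except Exception as e:
            raise StageError(stage, e) from e

        # --- ChIP-seq calling + categorization + gene Venn ---------------
        stage = "chipseq"
        try:
            model = DifferentialOccupancyModel(
                reads_on,
                reads_off,
                sizes,
                mapab,
                annotation=annotation,
                window=config.window,
                step=config.step,
                p_threshold=config.p_threshold,
                diff_threshold=config.diff_threshold,
                map_threshold=config.map_threshold,
                strand_max=config.strand_max,
                gene_distance=config.gene_distance,
            )
            res = model.fit()
            rio.write_tsv(res.categorized, out / "peaks.tsv")
            record("peaks.tsv", out / "peaks.tsv")
            if res.gene_assignments is not None:
                rio.write_tsv(res.gene_assignments, out / "gene_assignments.tsv")
                record("gene_assignments.tsv", out / "gene_assignments.tsv")
                (out / "venn.json").write_text(json.dumps(res.venn, indent=1, sort_keys=True))
                record("venn.json", out / "venn.json")
            if annotation is not None and len(annotation):
                prof = res.tss_profile()
                rio.write_tsv(prof, out / "tss_profile.tsv")
                record("tss_profile.tsv", out / "tss_profile.tsv")
            log.info("chipseq: %s", res.summary().replace("\n", " | "))
            if config.run_fdr:
                fdr = res.estimate_fdr(seed=config.seed)
                (out / "fdr.json").write_text(
                    json.dumps(
                        {
                            "fdr": fdr.fdr,
                            "n_real_peaks": fdr.n_real_peaks,
                            "n_random_peaks": fdr.n_random_peaks,
                        }
                    )
                )
                record("fdr.json", out / "fdr.json")
        except Exception as e:
            raise StageError(stage, e) from e

        # --- miRNA proximity ----------------------------------------------
        stage = "mirna_proximity"
        try:
            mir_ann = None
            if config.mirna_annotation:
                mir_ann = rio.read_table(config.mirna_annotation)
            elif syn is not None:
                mir_ann = make_mirna_annotation(syn)
            if mir_ann is not None and len(mir_ann):
                hits = mirna_proximity(res.categorized, mir_ann, config.mirna_distance)
                rio.write_tsv(hits, out / "mirna_hits.tsv")
                record("mirna_hits.tsv", out / "mirna_hits.tsv")
            else:
                manifest["skipped"].append(stage)
        except Exception as e:
            raise StageError(stage, e) from e

        # --- tiling array --------------------------------------------------
        stage = "chipchip"
        try:
            probes = None
            if config.probes:
                probes = rio.read_table(config.probes)
            elif syn is not None:
                probes, _ = simulate_array(syn)
            if probes is not None:
                ares = TilingArrayModel(
                    probes,
                    window=config.array_window,
                    step=config.array_step,
                    alpha=config.array_alpha,
                    cv_max=config.cv_max,
                ).fit()
                rio.write_tsv(ares.window_stats, out / "array_windows.tsv")
                rio.write_tsv(
                    pd.DataFrame({"region_id": ares.bound_regions}), out / "array_bound.tsv"
                )
                record("array_windows.tsv", out / "array_windows.tsv")
                record("array_bound.tsv", out / "array_bound.tsv")
                log.info("chipchip: %s", ares.summary().replace("\n", " | "))
            else:
                manifest["skipped"].append(stage)
        except Exception as e:
            raise StageError(stage, e) from e

        # --- miRNA differential expression --------------------------------
        stage = "mirna_diff"
        try:
            matrix = groups = None
            if config.mirna_matrix and config.mirna_groups:
                matrix = rio.read_expression_matrix(config.mirna_matrix)
                groups = rio.read_group_map(config.mirna_groups)
            elif syn is not None:
                matrix, groups, _ = simulate_mirna(syn)
            if matrix is not None:
                names = sorted(groups)
                mres = MiRNADifferentialModel(
                    matrix,
                    groups[names[0]],
                    groups[names[1]],
                    fold_min=config.fold_min,
                    abs_min=config.abs_min,
                    alpha=config.mirna_alpha,
                ).fit()
                rio.write_tsv(mres.table, out / "mirna_diff.tsv")
                record("mirna_diff.tsv", out / "mirna_diff.tsv")
                log.info(
                    "mirna_diff: %d flagged (%d up, %d down)",
                    len(mres.flagged),
                    mres.n_up,
                    mres.n_down,
                )
            else:
                manifest["skipped"].append(stage)
        except Exception as e:
            raise StageError(stage, e) from e

        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
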