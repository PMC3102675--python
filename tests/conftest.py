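import pandas as pd
import pytest

from rechip import SyntheticConfig, make_annotation, simulate_mapability, simulate_reads


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def small_config():
    """One 2 Mb chromosome, 12 genes — fast enough for per-test generation."""
    return SyntheticConfig(
        seed=11,
        n_chroms=1,
        chrom_length=2_000_000,
        n_genes=12,
        site_classes={"on_only": 4, "off_only": 3, "both": 3, "none": 2},
        n_mirnas=8,
        mirna_n_up=2,
        mirna_n_down=2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ann, sizes = make_annotation(small_config)
    return {
        "config": small_config,
        "annotation": ann,
        "sizes": sizes,
        "reads_on": simulate_reads(ann, small_config, "on"),
        "reads_off": simulate_reads(ann, small_config, "off"),
        "mapability": simulate_mapability(small_config),
    }


def make_peaks(rows):
    """Peak frame from (chrom, start, end[, category]) tuples for tests."""
    cols = ["chrom", "start", "end", "summit", "best_p", "summit_ratio", "category"]
    out = []
    for r in rows:
        chrom, start, end = r[:3]
        cat = r[3] if len(r) > 3 else "On-only"
        out.append((chrom, start, end, start, 1e-20, 10.0, cat))
    return pd.DataFrame(out, columns=cols)
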