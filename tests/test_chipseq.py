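"""Window counting, Poisson tails, filters, peak calling, FDR control."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rechip import (
    DifferentialOccupancyModel,
    GridMismatchError,
    SyntheticConfig,
    call_peaks,
    count_windows,
    estimate_fdr,
    make_annotation,
    poisson_pvalue,
    simulate_mapability,
    simulate_reads,
    strand_balance,
    tss_profile,
)


def poisson_sf_oracle(k: int, lam: float) -> float:
    """Brute-force upper tail by log-pmf summation (independent of scipy)."""
    if k == 0:
        return 1.0
    logs = []
    i = k
    while True:
        lp = i * math.log(lam) - lam - math.lgamma(i + 1)
        logs.append(lp)
        if lp < logs[0] - 60:  # terms no longer contribute at double precision
            break
        i += 1
    m = max(logs)
    return math.exp(m) * sum(math.exp(lp - m) for lp in logs)


def uniform_reads(n, length, seed, chrom="chr1"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": rng.integers(0, length, size=n),
            "strand": rng.choice(["+", "-"], size=n),
        }
    )


def flat_mapability(length, chrom="chr1", window=1000, step=50):
    starts = np.arange(0, length - window + 1, step)
    return pd.DataFrame({"chrom": chrom, "start": starts, "mapability": 1.0})


class TestCountWindows:
    def test_empty_read_set_counts_zero_everywhere(self):
        sizes = pd.DataFrame({"chrom": ["chr1"], "size": [100_000]})
        win, dropped = count_windows(pd.DataFrame(columns=["chrom", "start", "strand"]), sizes)
        assert (win["count"] == 0).all() and dropped == 0
        assert len(win) == (100_000 - 1000) // 50 + 1

    def test_interior_read_hits_exactly_window_over_step_windows(self):
        sizes = pd.DataFrame({"chrom": ["chr1"], "size": [100_000]})
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "strand": ["+"]})
        win, _ = count_windows(reads, sizes)
        hit = win[win["count"] > 0]
        assert len(hit) == 1000 // 50 == 20
        assert (hit["count"] == 1).all() and (hit["plus"] == 1).all()
        # the windows are exactly those whose interval contains the read
        assert (hit["start"] <= 50_000).all() and (hit["start"] + 1000 > 50_000).all()

    def test_read_count_is_conserved_over_the_tiling(self):
        sizes = pd.DataFrame({"chrom": ["chr1"], "size": [1_000_000]})
        reads = uniform_reads(10_000, 1_000_000, seed=0)
        win, dropped = count_windows(reads, sizes)
        tiling = win[win["start"] % 1000 == 0]
        assert int(tiling["count"].sum()) + dropped == 10_000
        assert (win["plus"] + win["minus"]).equals(win["count"])

    def test_out_of_range_and_unknown_chrom_reads_are_dropped_with_count(self):
        sizes = pd.DataFrame({"chrom": ["chr1"], "size": [10_000]})
        reads = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chrMystery"], "start": [5_000, 99_999, 10],
             "strand": ["+", "+", "-"]}
        )
        win, dropped = count_windows(reads, sizes)
        assert dropped == 2
        assert int(win[win["start"] % 1000 == 0]["count"].sum()) == 1


class TestPoissonPvalue:
    def test_zero_observed_is_certain(self):
        assert poisson_pvalue(0, 5.0) == 1.0

    def test_matches_bruteforce_summation(self):
        # small example checked directly: P(X>=5 | lam=1) ~= 3.66e-3
        assert abs(poisson_pvalue(5, 1.0) - poisson_sf_oracle(5, 1.0)) < 1e-9
        assert poisson_pvalue(5, 1.0) == pytest.approx(3.6598e-3, rel=1e-4)
        for k, lam in [(60, 10.0), (100, 0.1), (30, 1.0)]:
            assert poisson_pvalue(k, lam) == pytest.approx(poisson_sf_oracle(k, lam), rel=1e-6)

    def test_deep_tail_stays_finite_and_positive(self):
        p = poisson_pvalue(150, 5.0)
        assert 0 < p < 1e-15
        assert p == pytest.approx(poisson_sf_oracle(150, 5.0), rel=1e-6)

    @given(k=st.integers(0, 80), lam=st.sampled_from([0.1, 1.0, 10.0]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_observed_count(self, k, lam):
        assert poisson_pvalue(k + 1, lam) <= poisson_pvalue(k, lam)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_pvalue(3, 0.0)


class TestStrandBalance:
    @pytest.mark.parametrize(
        "plus,minus,balance,passes",
        [(50, 50, 0.0, True), (70, 30, 0.4, False), (65, 35, 0.3, True), (100, 0, 1.0, False)],
    )
    def test_balance_formula_and_inclusive_boundary(self, plus, minus, balance, passes):
        b, ok = strand_balance(plus, minus)
        assert b == pytest.approx(balance)
        assert ok is passes

    def test_empty_window_auto_fails(self):
        b, ok = strand_balance(0, 0)
        assert math.isnan(b) and not ok


class TestCallPeaks:
    LENGTH = 1_000_000

    def _setup(self, reads_on, reads_off):
        sizes = pd.DataFrame({"chrom": ["chr1"], "size": [self.LENGTH]})
        mapab = flat_mapability(self.LENGTH)
        won, _ = count_windows(reads_on, sizes)
        woff, _ = count_windows(reads_off, sizes)
        return won, woff, mapab

    def _spike(self, center, n, seed, spread=150):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.clip(rng.normal(center, spread, n).astype(int), 0, self.LENGTH - 1),
                "strand": rng.choice(["+", "-"], size=n),
            }
        )

    def test_matched_uniform_conditions_yield_no_peaks(self):
        won, woff, mapab = self._setup(
            uniform_reads(5000, self.LENGTH, seed=1), uniform_reads(5000, self.LENGTH, seed=2)
        )
        pon, poff, _, _ = call_peaks(won, woff, mapab)
        assert len(pon) == 0 and len(poff) == 0

    def test_single_spike_yields_one_peak_containing_the_site(self):
        center = 400_000
        on = pd.concat(
            [uniform_reads(5000, self.LENGTH, seed=1), self._spike(center, 200, seed=3)]
        )
        won, woff, mapab = self._setup(on, uniform_reads(5000, self.LENGTH, seed=2))
        pon, poff, _, _ = call_peaks(won, woff, mapab)
        assert len(pon) == 1 and len(poff) == 0
        peak = pon.iloc[0]
        assert peak["start"] <= center < peak["end"]
        assert peak["end"] - peak["start"] >= 1000
        assert peak["summit_ratio"] > 2

    def test_low_mapability_suppresses_the_peak(self):
        center = 400_000
        on = pd.concat(
            [uniform_reads(5000, self.LENGTH, seed=1), self._spike(center, 200, seed=3)]
        )
        won, woff, mapab = self._setup(on, uniform_reads(5000, self.LENGTH, seed=2))
        mapab = mapab.copy()
        near = mapab["start"].between(center - 2500, center + 2500)
        mapab.loc[near, "mapability"] = 0.1
        pon, _, _, _ = call_peaks(won, woff, mapab)
        assert len(pon) == 0

    def test_single_strand_spike_fails_the_balance_filter(self):
        center = 400_000
        spike = self._spike(center, 200, seed=3)
        spike["strand"] = "+"
        on = pd.concat([uniform_reads(5000, self.LENGTH, seed=1), spike])
        won, woff, mapab = self._setup(on, uniform_reads(5000, self.LENGTH, seed=2))
        pon, _, _, _ = call_peaks(won, woff, mapab)
        assert len(pon) == 0

    def test_peaks_are_non_overlapping_and_long_enough(self):
        rng = np.random.default_rng(0)
        spikes = [self._spike(c, 150, seed=i) for i, c in
                  enumerate(rng.integers(50_000, self.LENGTH - 50_000, 8))]
        on = pd.concat([uniform_reads(5000, self.LENGTH, seed=1)] + spikes)
        won, woff, mapab = self._setup(on, uniform_reads(5000, self.LENGTH, seed=2))
        pon, _, _, _ = call_peaks(won, woff, mapab)
        assert len(pon) >= 1
        assert (pon["end"] - pon["start"] >= 1000).all()
        starts, ends = pon["start"].to_numpy(), pon["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()
        assert ((pon["summit"] >= pon["start"]) & (pon["summit"] < pon["end"])).all()

    def test_thresholds_move_peak_counts_monotonically(self):
        center = 400_000
        on = pd.concat(
            [uniform_reads(5000, self.LENGTH, seed=1), self._spike(center, 80, seed=3)]
        )
        won, woff, mapab = self._setup(on, uniform_reads(5000, self.LENGTH, seed=2))
        counts_p = [
            len(call_peaks(won, woff, mapab, p_threshold=p)[0])
            for p in (1e-30, 1e-12, 1e-4, 1e-2)
        ]
        assert counts_p == sorted(counts_p)  # looser P never loses peaks
        counts_m = [
            len(call_peaks(won, woff, mapab, map_threshold=m)[0]) for m in (0.0, 0.25, 0.99)
        ]
        assert counts_m == sorted(counts_m, reverse=True)

    def test_grid_mismatch_is_a_structural_error(self):
        won, woff, mapab = self._setup(
            uniform_reads(100, self.LENGTH, seed=1), uniform_reads(100, self.LENGTH, seed=2)
        )
        with pytest.raises(GridMismatchError):
            call_peaks(won, woff.iloc[:-5], mapab)
        with pytest.raises(GridMismatchError):
            call_peaks(won, woff, mapab.iloc[5:])


class TestTssProfile:
    def test_uniform_reads_give_a_flat_profile(self):
        ann = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)], "chrom": "chr1",
             "tss": np.linspace(50_000, 950_000, 20).astype(int), "strand": "+"}
        )
        prof = tss_profile(uniform_reads(200_000, 1_000_000, seed=4), ann, span=5000)
        assert prof["count"].max() / prof["count"].min() < 1.2

    def test_reads_at_tss_peak_at_offset_zero(self):
        ann = pd.DataFrame(
            {"gene_id": ["g0", "g1"], "chrom": "chr1", "tss": [100_000, 300_000],
             "strand": ["+", "-"]}
        )
        reads = pd.DataFrame(
            {"chrom": "chr1", "start": [100_000] * 30 + [300_000] * 30, "strand": "+"}
        )
        prof = tss_profile(reads, ann, span=3000)
        # every window containing the TSS ties for the max; offset 0 is one
        at_zero = prof.loc[prof["offset_bp"] == 0, "count"].iloc[0]
        assert at_zero == prof["count"].max() == 60
        assert prof["density"].sum() == pytest.approx(1.0)

    def test_profile_is_strand_oriented(self):
        # reads 2 kb left of a minus-strand gene appear at +2000 (downstream-negative flip)
        ann = pd.DataFrame({"gene_id": ["g"], "chrom": "chr1", "tss": [100_000],
                            "strand": ["-"]})
        reads = pd.DataFrame({"chrom": "chr1", "start": [98_000] * 10, "strand": "+"})
        prof = tss_profile(reads, ann, span=4000)
        at_flip = prof.loc[prof["offset_bp"] == 2000, "count"].iloc[0]
        assert at_flip == prof["count"].max() == 10
        assert prof.loc[prof["offset_bp"] == -2000, "count"].iloc[0] == 0

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            tss_profile(uniform_reads(10, 1000, seed=0), pd.DataFrame(), span=1000)


class TestFdrAndModel:
    def test_fdr_on_synthetic_data_is_deterministic_and_small(self, small_dataset):
        d = small_dataset
        r1 = estimate_fdr(d["reads_on"], d["reads_off"], d["sizes"], d["mapability"], seed=5)
        r2 = estimate_fdr(d["reads_on"], d["reads_off"], d["sizes"], d["mapability"], seed=5)
        assert (r1.n_real_peaks, r1.n_random_peaks) == (r2.n_real_peaks, r2.n_random_peaks)
        assert r1.n_real_peaks > 0
        assert r1.fdr < 0.01

    def test_zero_real_peaks_reports_undefined_fdr(self):
        sizes = pd.DataFrame({"chrom": ["chr1"], "size": [200_000]})
        mapab = flat_mapability(200_000)
        r = estimate_fdr(uniform_reads(500, 200_000, seed=1),
                         uniform_reads(500, 200_000, seed=2), sizes, mapab, seed=3)
        assert r.n_real_peaks == 0 and math.isnan(r.fdr)

    def test_model_facade_recovers_the_planted_classes(self, small_dataset):
        d = small_dataset
        res = DifferentialOccupancyModel(
            d["reads_on"], d["reads_off"], d["sizes"], d["mapability"],
            annotation=d["annotation"],
        ).fit()
        truth = d["annotation"]["site_class"].value_counts()
        cats = res.categorized["category"].value_counts()
        assert cats.get("On-only", 0) == truth.get("on_only", 0)
        assert cats.get("Off-only", 0) == truth.get("off_only", 0)
        assert cats.get("Both", 0) == truth.get("both", 0)
        assert "peaks On" in res.summary()
        assert res.venn is not None
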