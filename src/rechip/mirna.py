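"""miRNA differential expression: signed folds, the triple filter, timecourses.

Fold changes follow the signed convention common in microarray reports:
the ratio of the larger group mean to the smaller, negative when the test
condition is the lower one, so |fold| >= 1 always and a 2x drop prints as
-2.00 rather than 0.50. A miRNA is called differential when all three
criteria hold strictly: |fold| > 1.5, absolute mean difference > 100
intensity units, and P < 0.05 from a Welch two-sample t-test on log2
intensities (the group-comparison test is a documented package choice;
the thresholds are the standard triple filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def signed_fold_change(mean_ref: float, mean_test: float) -> float:
    """Signed fold change of ``mean_test`` relative to ``mean_ref``.

    ``+mean_test/mean_ref`` when the test mean is at least the reference,
    else ``-mean_ref/mean_test``; antisymmetric under swapping the two
    means, and |result| >= 1 by construction. Round to 2 decimals for
    display.
    """
    if not (mean_ref > 0 and mean_test > 0):
        raise ValueError(f"means must be positive, got ({mean_ref}, {mean_test})")
    if mean_test >= mean_ref:
        return mean_test / mean_ref
    return -mean_ref / mean_test


def welch_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t P-value on log2 intensities.

    Degenerate case: zero variance in both groups with equal means gives
    P = 1 (no evidence of difference).
    """
    a = np.log2(np.asarray(a, dtype=float))
    b = np.log2(np.asarray(b, dtype=float))
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def differential_filter(
    matrix: pd.DataFrame,
    group_a,
    group_b,
    fold_min: float = 1.5,
    abs_min: float = 100.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the |fold| > 1.5 / |diff| > 100 / P < 0.05 triple filter.

    ``matrix`` is miRNA x sample intensities; ``group_a`` (reference) and
    ``group_b`` (test) are column lists with >= 2 replicates each. Returns
    one row per miRNA with group means, ``signed_fold`` (test vs
    reference), ``abs_diff``, ``p_value``, ``passes_filter`` and
    ``direction`` ('up'/'down' for flagged miRNAs, '' otherwise).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    rows = []
    for i, mid in enumerate(matrix.index):
        fold = signed_fold_change(mean_a[i], mean_b[i])
        p = welch_pvalue(a[i], b[i])
        diff = abs(mean_a[i] - mean_b[i])
        flag = (abs(fold) > fold_min) and (diff > abs_min) and (p < alpha)
        rows.append(
            (
                mid,
                mean_a[i],
                mean_b[i],
                fold,
                diff,
                p,
                flag,
                ("up" if fold > 0 else "down") if flag else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "mean_ref",
            "mean_test",
            "signed_fold",
            "abs_diff",
            "p_value",
            "passes_filter",
            "direction",
        ],
    )


def timecourse_table(day_means: dict, reference_day: str) -> pd.DataFrame:
    """Signed fold per timepoint relative to a reference day.

    ``day_means`` maps timepoint label -> mean intensity (or a Series).
    The reference maps to +1.00; other days go through
    :func:`signed_fold_change`.
    """
    if reference_day not in day_means:
        raise ValueError(f"reference day {reference_day!r} not in table")
    ref = day_means[reference_day]
    rows = [
        (day, mean, 1.0 if day == reference_day else signed_fold_change(ref, mean))
        for day, mean in dict(day_means).items()
    ]
    return pd.DataFrame(rows, columns=["day", "mean", "signed_fold"])


def normalize_to_control(
    target: pd.Series, control: pd.Series, mode: str = "ratio"
) -> float:
    """Mean expression of a target normalized to a control gene per sample.

    ``mode="ratio"``: per-sample target/control, averaged. ``mode="ct"``:
    inputs are qPCR cycle thresholds, per-sample ``2**-(Ct_t - Ct_c)``,
    averaged. Samples missing the control are excluded with a warning.
    """
    target = pd.Series(target)
    control = pd.Series(control)
    common = target.index.intersection(control.index)
    paired = pd.DataFrame({"t": target[common], "c": control[common]}).dropna()
    missing = len(target.dropna()) - len(paired)
    if missing > 0:
        warnings.warn(f"{missing} sample(s) lack a control measurement; excluded")
    if not len(paired):
        raise ValueError("no samples with both target and control measurements")
    if mode == "ratio":
        vals = paired["t"] / paired["c"]
    elif mode == "ct":
        vals = 2.0 ** -(paired["t"] - paired["c"])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(vals.mean())


@dataclass
class MiRNAResults:
    """Fitted differential-expression results for one group comparison."""

    model: "MiRNADifferentialModel"
    table: pd.DataFrame

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["passes_filter"]]

    @property
    def n_up(self) -> int:
        return int((self.flagged["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.flagged["direction"] == "down").sum())

    def summary(self) -> str:
        m = self.model
        lines = [
            "miRNA differential expression (signed fold / triple filter)",
            "=" * 58,
            f"miRNAs tested:    {len(self.table)}",
            f"filter:           |fold| > {m.fold_min}, |diff| > {m.abs_min}, "
            f"P < {m.alpha} (Welch t on log2)",
            f"flagged:          {len(self.flagged)} ({self.n_up} up, {self.n_down} down)",
            "",
        ]
        show = self.flagged.sort_values("signed_fold", ascending=False)
        for r in show.itertuples():
            lines.append(
                f"  {r.mirna_id:<16} {r.mean_ref:>10.2f} {r.mean_test:>10.2f} "
                f"{r.signed_fold:>8.2f}  P={r.p_value:.4f}"
            )
        return "\n".join(lines)


@dataclass
class MiRNADifferentialModel:
    """Two-group miRNA expression comparison with the triple filter."""

    matrix: pd.DataFrame
    group_a: list
    group_b: list
    fold_min: float = 1.5
    abs_min: float = 100.0
    alpha: float = 0.05

    def fit(self) -> MiRNAResults:
        table = differential_filter(
            self.matrix,
            self.group_a,
            self.group_b,
            fold_min=self.fold_min,
            abs_min=self.abs_min,
            alpha=self.alpha,
        )
        return MiRNAResults(model=self, table=table)
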