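"""Paired safe-vs-unsafe comparison of every feature.

For each feature the safe and unsafe values are paired by (subject,
lifting index).  A Shapiro-Wilk test on the paired differences gates the
choice of test: differences compatible with normality go to the two-tailed
paired t-test, anything else to the two-tailed Wilcoxon signed-rank test.
Significance is declared at alpha = 0.05.  No multiple-testing correction
is applied across the 18 per-signal rows; the report notes this.

The published report format has one row per feature per signal (not per
axis); by default the three axis values of a lifting are averaged before
testing (``axis_mode="mean"``), with an x-axis-only alternative.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .features import FEATURE_NAMES

__all__ = ["StatTestRow", "paired_compare", "stats_report", "report_frame"]

log = logging.getLogger(__name__)

SIGNALS = {"acc": ("x", "y", "z"), "vel": ("x", "y", "z")}
_SIGNAL_PREFIX = {"acc": "a", "vel": "v"}


@dataclass(frozen=True)
class StatTestRow:
    """One report row: class summaries plus the gated paired test."""

    feature: str
    safe_mean: float
    safe_std: float
    unsafe_mean: float
    unsafe_std: float
    test_used: str           # "paired_t" | "wilcoxon_signed_rank"
    p_value: float
    significant: bool


def paired_compare(
    safe_values: np.ndarray,
    unsafe_values: np.ndarray,
    alpha: float = 0.05,
    feature: str = "",
) -> StatTestRow:
    """Normality-gated two-tailed paired test on one feature.

    Shapiro-Wilk runs on the paired differences (the quantity whose
    normality the paired t-test actually assumes).  All-zero differences are
    degenerate: the row reports p = 1 with a warning.
    """
    safe = np.asarray(safe_values, dtype=float)
    unsafe = np.asarray(unsafe_values, dtype=float)
    if safe.shape != unsafe.shape or safe.ndim != 1:
        raise DataError("paired samples must be 1-D and of equal length")
    if safe.size < 8:
        raise DataError("paired test needs at least 8 pairs")
    diff = unsafe - safe

    def _row(test: str, p: float) -> StatTestRow:
        return StatTestRow(
            feature=feature,
            safe_mean=float(safe.mean()),
            safe_std=float(safe.std(ddof=1)),
            unsafe_mean=float(unsafe.mean()),
            unsafe_std=float(unsafe.std(ddof=1)),
            test_used=test,
            p_value=float(p),
            significant=bool(p < alpha),
        )

    if np.all(diff == 0):
        log.warning("feature %s: all paired differences are zero", feature or "?")
        return _row("wilcoxon_signed_rank", 1.0)

    sw_p = sps.shapiro(diff).pvalue
    if sw_p >= alpha:
        p = sps.ttest_rel(unsafe, safe).pvalue
        return _row("paired_t", p)
    p = sps.wilcoxon(diff, alternative="two-sided").pvalue
    return _row("wilcoxon_signed_rank", p)


def _paired_frame(dataset: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the dataset into aligned safe/unsafe halves, paired by
    (subject, lifting_id)."""
    for sid, grp in dataset.groupby("subject"):
        present = set(grp["label"])
        if present != {"safe", "unsafe"}:
            raise DataError(f"subject {sid} lacks a class: has {sorted(present)}")
    safe = dataset[dataset["label"] == "safe"].sort_values(["subject", "lifting_id"])
    unsafe = dataset[dataset["label"] == "unsafe"].sort_values(["subject", "lifting_id"])
    ks = list(zip(safe["subject"], safe["lifting_id"]))
    ku = list(zip(unsafe["subject"], unsafe["lifting_id"]))
    if ks != ku:
        raise DataError("safe/unsafe liftings cannot be paired by (subject, lifting_id)")
    return safe.reset_index(drop=True), unsafe.reset_index(drop=True)


def stats_report(
    dataset: pd.DataFrame,
    alpha: float = 0.05,
    axis_mode: str = "mean",
) -> dict[str, list[StatTestRow]]:
    """One gated paired test per feature per signal.

    Returns ``{"acc": [...9 rows...], "vel": [...9 rows...]}``.  With
    ``axis_mode="mean"`` the x, y and z values of each lifting are averaged
    before testing; ``axis_mode="x"`` tests the longitudinal axis alone.
    """
    safe, unsafe = _paired_frame(dataset)
    report: dict[str, list[StatTestRow]] = {}
    for signal, prefix in _SIGNAL_PREFIX.items():
        rows = []
        for feat in FEATURE_NAMES:
            if axis_mode == "mean":
                cols = [f"{feat}_{prefix}{ax}" for ax in ("x", "y", "z")]
                sv = safe[cols].to_numpy().mean(axis=1)
                uv = unsafe[cols].to_numpy().mean(axis=1)
            elif axis_mode == "x":
                sv = safe[f"{feat}_{prefix}x"].to_numpy()
                uv = unsafe[f"{feat}_{prefix}x"].to_numpy()
            else:
                raise DataError(f"unknown axis_mode {axis_mode!r}")
            rows.append(paired_compare(sv, uv, alpha=alpha, feature=f"{feat}_{signal}"))
        report[signal] = rows
    return report


def report_frame(report: dict[str, list[StatTestRow]]) -> pd.DataFrame:
    """Flatten a stats report into a tidy DataFrame (one row per test)."""
    rows = []
    for signal, entries in report.items():
        for r in entries:
            d = asdict(r)
            d["signal"] = signal
            rows.append(d)
    return pd.DataFrame(rows)[
        ["signal", "feature", "safe_mean", "safe_std", "unsafe_mean",
         "unsafe_std", "test_used", "p_value", "significant"]
    ]
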