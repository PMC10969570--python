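"""Information-gain feature ranking.

The importance of a feature is the reduction in class-label entropy after
observing the feature, IG = H(Y) - sum_b p(b) H(Y | bin b), with the feature
discretized into equal-frequency bins (default 10).  Equal-frequency binning
depends only on the ranks of the values, so the ranking is invariant under
any strictly monotone transform of a feature.  Aggregate shares - per axis
(x/y/z), per signal (acceleration/angular velocity) and per feature family -
are each the summed member IG divided by the total IG over all 54 features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .features import CHANNEL_NAMES, FEATURE_COLUMNS, FEATURE_NAMES

__all__ = ["entropy", "information_gain", "rank_features"]

log = logging.getLogger(__name__)


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy (bits) of a label sequence."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to an equal-frequency bin; ties go to the lower bin."""
    values = np.asarray(values, dtype=float)
    inner = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    # side="left": a value equal to an edge is counted into the lower bin
    return np.searchsorted(inner, values, side="left")


def information_gain(
    feature_values: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """IG (bits) of one feature for the class labels.

    A single-class label vector has H(Y) = 0, hence IG = 0 (warned).
    """
    feature_values = np.asarray(feature_values, dtype=float)
    labels = np.asarray(labels)
    if feature_values.shape != labels.shape or feature_values.ndim != 1:
        raise DataError("feature values and labels must be 1-D of equal length")
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    h_y = entropy(labels)
    if h_y == 0:
        log.warning("single class in labels: information gain is 0 by definition")
        return 0.0
    bins = equal_frequency_bins(feature_values, n_bins)
    n = labels.size
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += (mask.sum() / n) * entropy(labels[mask])
    return max(h_y - cond, 0.0)


def rank_features(
    dataset: pd.DataFrame, n_bins: int = 10
) -> tuple[pd.DataFrame, dict]:
    """IG ranking of all 54 features plus aggregate shares.

    Returns ``(ranking, aggregates)``: the ranking sorted by IG descending
    with each feature's share of the total IG, and aggregates containing
    the share per axis, per signal, per feature family, and the count of
    features with non-zero IG.
    """
    labels = dataset["label"].to_numpy()
    igs = {
        col: information_gain(dataset[col].to_numpy(), labels, n_bins=n_bins)
        for col in FEATURE_COLUMNS
    }
    total = sum(igs.values())
    ranking = pd.DataFrame(
        {
            "feature": list(igs),
            "ig": list(igs.values()),
            "share": [v / total if total > 0 else 0.0 for v in igs.values()],
        }
    ).sort_values("ig", ascending=False, kind="mergesort").reset_index(drop=True)

    def _share(cols: list[str]) -> float:
        return sum(igs[c] for c in cols) / total if total > 0 else 0.0

    aggregates = {
        "total_ig": total,
        "n_nonzero": int(sum(v > 0 for v in igs.values())),
        "axis_share": {
            ax: _share([c for c in FEATURE_COLUMNS if c.endswith(ax)])
            for ax in ("x", "y", "z")
        },
        "signal_share": {
            "acc": _share([f"{f}_{ch}" for f in FEATURE_NAMES
                           for ch in CHANNEL_NAMES if ch.startswith("a")]),
            "vel": _share([f"{f}_{ch}" for f in FEATURE_NAMES
                           for ch in CHANNEL_NAMES if ch.startswith("v")]),
        },
        "family_share": {
            f: _share([f"{f}_{ch}" for ch in CHANNEL_NAMES]) for f in FEATURE_NAMES
        },
    }
    return ranking, aggregates
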