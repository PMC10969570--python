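"""Time- and frequency-domain features of one lifting segment.

Nine features per channel, computed on the raw (unfiltered) samples of each
region of interest:

time domain
    STD   sample standard deviation (N-1 denominator)
    MAV   mean absolute value
    PP    peak-to-peak amplitude, max - min
    ZCR   zero-crossing count: adjacent pairs with a strict sign flip
          (a pair containing an exact zero does not count)
    SSC   slope-sign-change count: strict local extrema over interior samples

frequency domain (on the total power spectrum S_i = |X_i|^2, where X is the
unnormalized DFT of the segment over all N bins)
    P     total power, mean of S_i over the N bins
    SE    spectral entropy of p_i = S_i / sum(S); by default divided by
          log2(N) so it lies in [0, 1]
    Kurt  excess kurtosis of the spectrum values (4th standardized moment
          minus 3, population denominator)
    Skew  skewness of the spectrum values (population denominator)

With 6 channels (ax, ay, az, vx, vy, vz) this yields the 54-column feature
vector of one lifting; a cohort of 15 subjects x 2 trials x 20 liftings
gives the canonical 600 x 54 supervised dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "FEATURE_NAMES",
    "CHANNEL_NAMES",
    "FEATURE_COLUMNS",
    "std",
    "mav",
    "pp",
    "zcr",
    "ssc",
    "power_spectrum",
    "total_power",
    "spectral_entropy",
    "spectral_kurtosis",
    "spectral_skewness",
    "feature_vector",
    "extract_features",
]

FEATURE_NAMES = ("STD", "MAV", "PP", "ZCR", "SSC", "P", "SE", "Kurt", "Skew")
CHANNEL_NAMES = ("ax", "ay", "az", "vx", "vy", "vz")
#: Column order of the supervised feature table: channel-major, feature-minor.
FEATURE_COLUMNS = tuple(f"{f}_{c}" for c in CHANNEL_NAMES for f in FEATURE_NAMES)


def _as1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size and not np.isfinite(x).all():
        raise DataError("segment contains non-finite samples")
    return x


# ---------------------------------------------------------------- time domain
def std(seg) -> float:
    """Sample standard deviation (N-1 denominator)."""
    x = _as1d(seg)
    if x.size < 2:
        raise DataError("STD needs at least 2 samples")
    return float(np.std(x, ddof=1))


def mav(seg) -> float:
    """Mean absolute value."""
    x = _as1d(seg)
    if x.size < 1:
        raise DataError("MAV needs at least 1 sample")
    return float(np.mean(np.abs(x)))


def pp(seg) -> float:
    """Peak-to-peak amplitude, max(x) - min(x)."""
    x = _as1d(seg)
    if x.size < 1:
        raise DataError("PP needs at least 1 sample")
    return float(np.max(x) - np.min(x))


def zcr(seg) -> int:
    """Count of adjacent sample pairs with a strict sign flip.

    Strict inequalities: a pair in which either sample is exactly zero does
    not count as a crossing.
    """
    x = _as1d(seg)
    if x.size < 2:
        raise DataError("ZCR needs at least 2 samples")
    a, b = x[:-1], x[1:]
    return int(np.count_nonzero(((a < 0) & (b > 0)) | ((a > 0) & (b < 0))))


def ssc(seg) -> int:
    """Count of strict local extrema over the interior samples.

    Plateaus (ties with a neighbour) break a run and are not counted.
    """
    x = _as1d(seg)
    if x.size < 3:
        raise DataError("SSC needs at least 3 samples")
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    return int(np.count_nonzero(((cur > prev) & (cur > nxt)) | ((cur < prev) & (cur < nxt))))


# ----------------------------------------------------------- frequency domain
def power_spectrum(seg) -> np.ndarray:
    """Total power spectrum: squared modulus of the DFT, all N bins."""
    x = _as1d(seg)
    if x.size < 8:
        raise DataError("power spectrum needs at least 8 samples")
    return np.abs(np.fft.fft(x)) ** 2


def total_power(ps: np.ndarray) -> float:
    """Mean of the power-spectrum values over the N bins."""
    ps = np.asarray(ps, dtype=float)
    return float(np.mean(ps))


def spectral_entropy(ps: np.ndarray, normalized: bool = True) -> float:
    """Shannon entropy of the normalized power spectrum.

    ``normalized=True`` divides by log2(N), bounding the result in [0, 1]
    (1 = perfectly flat spectrum).  Zero-power bins contribute nothing.
    """
    ps = np.asarray(ps, dtype=float)
    total = ps.sum()
    if total <= 0:
        raise DataError("spectral entropy undefined for an all-zero spectrum")
    p = ps / total
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    if normalized:
        h /= np.log2(ps.size)
    return h


def _spectrum_moments(ps: np.ndarray) -> tuple[np.ndarray, float, float]:
    ps = np.asarray(ps, dtype=float)
    mean = float(np.mean(ps))
    s = float(np.std(ps))  # population (N) denominator
    if s == 0:
        raise DataError("spectral moment undefined: flat spectrum (s = 0)")
    return ps, mean, s


def spectral_kurtosis(ps: np.ndarray, exponent: int = 4) -> float:
    """Excess kurtosis of the spectrum values.

    ``exponent`` controls the numerator power; 4 is the standard fourth
    central moment.  The alternative value 3 reproduces a literal reading of
    a third-power numerator over s^4 and is kept for comparison only.
    """
    ps, mean, s = _spectrum_moments(ps)
    m = float(np.mean((ps - mean) ** exponent))
    return m / s**4 - 3.0


def spectral_skewness(ps: np.ndarray) -> float:
    """Skewness (third standardized moment) of the spectrum values."""
    ps, mean, s = _spectrum_moments(ps)
    return float(np.mean((ps - mean) ** 3)) / s**3


# ------------------------------------------------------------------ assembly
def feature_vector(
    channel: np.ndarray, se_normalized: bool = True, kurt_exponent: int = 4
) -> dict[str, float]:
    """All nine features of one channel segment, keyed by feature name."""
    ps = power_spectrum(channel)
    return {
        "STD": std(channel),
        "MAV": mav(channel),
        "PP": pp(channel),
        "ZCR": float(zcr(channel)),
        "SSC": float(ssc(channel)),
        "P": total_power(ps),
        "SE": spectral_entropy(ps, normalized=se_normalized),
        "Kurt": spectral_kurtosis(ps, exponent=kurt_exponent),
        "Skew": spectral_skewness(ps),
    }


def extract_features(
    segments: list[np.ndarray],
    subject_ids: list[int],
    labels: list[str],
    lifting_ids: list[int] | None = None,
    *,
    se_normalized: bool = True,
    kurt_exponent: int = 4,
) -> pd.DataFrame:
    """Assemble the supervised feature table: one row per lifting.

    Each segment is an (n_i, 6) matrix of original samples.  Per-channel
    feature failures are re-raised with the segment identity attached.
    """
    if not (len(segments) == len(subject_ids) == len(labels)):
        raise DataError("segments, subject_ids and labels must have equal length")
    if lifting_ids is None:
        counter: dict[tuple[int, str], int] = {}
        lifting_ids = []
        for sid, lab in zip(subject_ids, labels):
            k = counter.get((sid, lab), 0)
            lifting_ids.append(k)
            counter[(sid, lab)] = k + 1

    rows = []
    for seg, sid, lab, lid in zip(segments, subject_ids, labels, lifting_ids):
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 2 or seg.shape[1] != 6:
            raise DataError(f"segment (subject {sid}, lifting {lid}) is not (n, 6)")
        row: dict[str, object] = {"subject": sid, "lifting_id": lid, "label": lab}
        for ci, cname in enumerate(CHANNEL_NAMES):
            try:
                fv = feature_vector(
                    seg[:, ci], se_normalized=se_normalized, kurt_exponent=kurt_exponent
                )
            except DataError as exc:
                raise DataError(
                    f"feature failure on subject {sid}, lifting {lid}, "
                    f"channel {cname}: {exc}"
                ) from exc
            for fname, val in fv.items():
                row[f"{fname}_{cname}"] = val
        rows.append(row)

    df = pd.DataFrame(rows, columns=["subject", "lifting_id", "label", *FEATURE_COLUMNS])
    return df
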