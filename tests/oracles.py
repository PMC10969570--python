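"""Independent brute-force oracles: direct loop transcriptions of the nine
segment features and of information gain, kept free of any liftsafe import
so they can disagree with the implementation."""

import math


def oracle_std(x):
    n = len(x)
    mean = sum(x) / n
    return math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))


def oracle_mav(x):
    return sum(abs(v) for v in x) / len(x)


def oracle_pp(x):
    return max(x) - min(x)


def oracle_zcr(x):
    count = 0
    for i in range(len(x) - 1):
        if (x[i] < 0 and x[i + 1] > 0) or (x[i] > 0 and x[i + 1] < 0):
            count += 1
    return count


def oracle_ssc(x):
    count = 0
    for i in range(1, len(x) - 1):
        if (x[i] > x[i - 1] and x[i] > x[i + 1]) or (x[i] < x[i - 1] and x[i] < x[i + 1]):
            count += 1
    return count


def oracle_spectrum(x):
    """Squared modulus of the DFT by the defining double sum."""
    n = len(x)
    out = []
    for k in range(n):
        re = sum(x[j] * math.cos(-2 * math.pi * k * j / n) for j in range(n))
        im = sum(x[j] * math.sin(-2 * math.pi * k * j / n) for j in range(n))
        out.append(re * re + im * im)
    return out


def oracle_total_power(s):
    return sum(s) / len(s)


def oracle_spectral_entropy(s, normalized=True):
    total = sum(s)
    h = 0.0
    for v in s:
        p = v / total
        if p > 0:
            h -= p * math.log2(p)
    if normalized:
        h /= math.log2(len(s))
    return h


def _pop_sd(s):
    n = len(s)
    mean = sum(s) / n
    return mean, math.sqrt(sum((v - mean) ** 2 for v in s) / n)


def oracle_spectral_kurtosis(s):
    n = len(s)
    mean, sd = _pop_sd(s)
    return sum((v - mean) ** 4 for v in s) / (n * sd**4) - 3.0


def oracle_spectral_skewness(s):
    n = len(s)
    mean, sd = _pop_sd(s)
    return sum((v - mean) ** 3 for v in s) / (n * sd**3)


def oracle_information_gain(bin_ids, labels):
    """IG from an explicit contingency table over pre-discretized values."""

    def h(seq):
        n = len(seq)
        ent = 0.0
        for c in set(seq):
            p = sum(1 for v in seq if v == c) / n
            ent -= p * math.log2(p)
        return ent

    n = len(labels)
    cond = 0.0
    for b in set(bin_ids):
        sub = [labels[i] for i in range(n) if bin_ids[i] == b]
        cond += len(sub) / n * h(sub)
    return h(labels) - cond
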