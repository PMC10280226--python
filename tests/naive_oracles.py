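"""Independent brute-force reference implementations used only by tests.

Each function is a direct pure-Python loop transcription of the feature and
ranking definitions, written without reference to the package's vectorized
code paths so the two can disagree.
"""

import math


def _mean(xs):
    return sum(xs) / len(xs)


def _sample_var(xs):
    m = _mean(xs)
    return sum((v - m) ** 2 for v in xs) / (len(xs) - 1)


def _quantile_hazen(sorted_xs, q):
    # plotting positions (i - 0.5) / n, linear interpolation, clamped ends
    n = len(sorted_xs)
    h = q * n + 0.5
    if h <= 1:
        return sorted_xs[0]
    if h >= n:
        return sorted_xs[-1]
    k = int(math.floor(h))
    frac = h - k
    return sorted_xs[k - 1] + frac * (sorted_xs[k] - sorted_xs[k - 1])


def naive_features(x):
    """The 25 descriptors of one epoch as a plain list, by direct loops."""
    n = len(x)
    xs = sorted(x)
    m = _mean(x)
    S2 = _sample_var(x)
    S = math.sqrt(S2)
    eps = 1e-12

    kurt = sum((v - m) ** 4 for v in x) / ((n - 1) * S ** 4) if S > 0 else float("nan")
    skew = sum((v - m) ** 3 for v in x) / ((n - 1) * S ** 3) if S > 0 else float("nan")
    iqr = _quantile_hazen(xs, 0.75) - _quantile_hazen(xs, 0.25)
    cv = (S / m) * 100 if m != 0 else float("nan")
    geo = math.exp(_mean([math.log(max(abs(v), eps)) for v in x]))
    harm = n / sum(1.0 / max(abs(v), eps) for v in x)

    d1 = [x[i] - x[i - 1] for i in range(1, n)]
    d2 = [d1[i] - d1[i - 1] for i in range(1, n - 1)]
    s1sq = _sample_var(d1)
    s2sq = _sample_var(d2)
    activity = S2
    mobility = s1sq / S2 if S2 > 0 else float("nan")
    if s1sq == 0:
        complexity = 0.0
    else:
        rad = (s2sq / s1sq) ** 2 - (s1sq / S2) ** 2
        complexity = math.sqrt(rad) if rad > 0 else 0.0

    if n % 2:
        med = xs[n // 2]
    else:
        med = 0.5 * (xs[n // 2 - 1] + xs[n // 2])
    mad = _mean([abs(v - m) for v in x])
    cm10 = _mean([(v - m) ** 10 for v in x])
    curve = sum(abs(x[i] - x[i - 1]) for i in range(1, n)) / n
    energy = _mean([v * v for v in x])
    rms = math.sqrt(energy)
    stderr = S / math.sqrt(n)
    shape = rms / _mean([math.sqrt(abs(v)) for v in x]) if any(x) else float("nan")
    svd = math.sqrt(sum(v * v for v in x))

    def trim(pct):
        k = int(math.floor(n * pct / 200.0 + 0.5))
        kept = xs[k: n - k]
        return _mean(kept)

    teager = sum(x[i - 1] ** 2 - x[i] * x[i - 2] for i in range(2, n)) / n

    return [kurt, skew, iqr, cv, geo, harm, activity, mobility, complexity,
            max(x), med, mad, min(x), cm10, m, curve, energy, rms, stderr, S,
            shape, svd, trim(25), trim(50), teager]


def naive_fisher(columns, labels):
    """Per-feature Fisher score and |point-biserial| R by direct loops.

    *columns* is a list of per-feature value lists; *labels* 0/1 ints.
    """
    out = []
    for col in columns:
        c0 = [v for v, y in zip(col, labels) if y == 0]
        c1 = [v for v, y in zip(col, labels) if y == 1]
        num = (_mean(c1) - _mean(c0)) ** 2
        den = _sample_var(c0) + _sample_var(c1)
        score = num / den if den > 0 else 0.0
        my, mx = _mean(labels), _mean(col)
        sxy = sum((v - mx) * (y - my) for v, y in zip(col, labels))
        sxx = sum((v - mx) ** 2 for v in col)
        syy = sum((y - my) ** 2 for y in labels)
        r = abs(sxy / math.sqrt(sxx * syy)) if sxx > 0 and syy > 0 else 0.0
        out.append((score, r))
    return out
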