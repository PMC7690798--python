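"""Independent, naively-coded recomputations used as test oracles.

Everything here is written from first principles (sorting for medians,
explicit sums for means and variances, explicit risk-set accumulation for
survival) so it shares no code path with the package implementation.
"""

from __future__ import annotations

import math

from scipy.stats import t as t_dist


def naive_median(xs):
    s = sorted(xs)
    n = len(s)
    m = n // 2
    return s[m] if n % 2 else (s[m - 1] + s[m]) / 2.0


def naive_mean(xs):
    return sum(xs) / len(xs)


def naive_pooled_t(a, b):
    """Pooled-variance two-sample t and two-sided p (df = na + nb - 2)."""
    na, nb = len(a), len(b)
    ma, mb = naive_mean(a), naive_mean(b)
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    if sp2 == 0:
        return (0.0, 1.0) if ma == mb else (math.copysign(math.inf, ma - mb), 0.0)
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, 2.0 * t_dist.sf(abs(t), df)


def naive_directional(split_on, contrast):
    """Median-split one list, contrast the other: (score, p, n_high, n_low).

    Returns None for degenerate or undersized splits.  Inputs must be
    missing-free and aligned.
    """
    med = naive_median(split_on)
    hi = [c for s, c in zip(split_on, contrast) if s > med]
    lo = [c for s, c in zip(split_on, contrast) if s <= med]
    if len(hi) < 2 or len(lo) < 2:
        return None
    t, p = naive_pooled_t(hi, lo)
    return naive_mean(hi) - naive_mean(lo), p, len(hi), len(lo)


def naive_gene_scores(expr, eff):
    """Both directional scores for one gene, dropping pairwise-missing samples."""
    pairs = [
        (x, y)
        for x, y in zip(expr, eff)
        if not (math.isnan(float(x)) or math.isnan(float(y)))
    ]
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(pairs) < 2:
        return None
    pred = naive_directional(xs, ys)
    desc = naive_directional(ys, xs)
    if pred is None or desc is None:
        return None
    return {"predictivity": pred, "descriptivity": desc}


def naive_pearson(a, b):
    n = len(a)
    ma, mb = naive_mean(a), naive_mean(b)
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def naive_km(times, events):
    """Product-limit estimate at distinct event times: list of (t, S(t))."""
    subjects = sorted(zip(times, events))
    event_times = sorted({t for t, e in subjects if e})
    out = []
    s = 1.0
    for t in event_times:
        n_at_risk = sum(1 for ti, _ in subjects if ti >= t)
        d = sum(1 for ti, e in subjects if e and ti == t)
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def naive_logrank(times_a, events_a, times_b, events_b):
    """Observed-minus-expected accumulation with hypergeometric variance."""
    all_events = sorted(
        {t for t, e in zip(times_a, events_a) if e}
        | {t for t, e in zip(times_b, events_b) if e}
    )
    o_minus_e = 0.0
    var = 0.0
    for t in all_events:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        da = sum(1 for x, e in zip(times_a, events_a) if e and x == t)
        db = sum(1 for x, e in zip(times_b, events_b) if e and x == t)
        n, d = na + nb, da + db
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2
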