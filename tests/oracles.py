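"""Naive, loop-based re-implementations of every panel index.

Deliberately written in the most direct way possible (explicit loops, no
shared helpers with the package) so they can serve as independent oracles.
All take a uniform GlucoseTrace and return the same units as the package.
"""

import math

MMOL = 18.016


def naive_mean(tr):
    return sum(tr.values) / len(tr.values)


def naive_std(tr):
    m = naive_mean(tr)
    return math.sqrt(sum((v - m) ** 2 for v in tr.values) / (len(tr.values) - 1))


def naive_tir(tr):
    return 100.0 * sum(1 for v in tr.values if 70 <= v <= 180) / len(tr.values)


def naive_acf(tr, K):
    g = list(tr.values)
    n = len(g)
    m = sum(g) / n
    denom = sum((x - m) ** 2 for x in g)
    out = []
    for k in range(1, K + 1):
        num = sum((g[t] - m) * (g[t + k] - m) for t in range(n - k))
        out.append(num / denom)
    return out


def naive_ac_metrics(tr, K):
    r = naive_acf(tr, K)
    mean = sum(r) / len(r)
    var = sum((x - mean) ** 2 for x in r) / (len(r) - 1)
    return mean, var


def naive_conga(tr, hours=1.0):
    lag = int(round(hours * 60 / tr.sampling_interval))
    d = [(tr.values[i + lag] - tr.values[i]) / MMOL
         for i in range(len(tr.values) - lag)]
    m = sum(d) / len(d)
    return math.sqrt(sum((x - m) ** 2 for x in d) / (len(d) - 1))


def naive_li(tr):
    # hourly values by direct linear interpolation of the raw trace
    t_end = tr.times[-1]
    hours = []
    h = tr.times[0]
    while h <= t_end + 1e-9:
        for i in range(len(tr.times) - 1):
            if tr.times[i] <= h <= tr.times[i + 1]:
                w = ((h - tr.times[i]) / (tr.times[i + 1] - tr.times[i])
                     if tr.times[i + 1] > tr.times[i] else 0.0)
                hours.append(tr.values[i] + w * (tr.values[i + 1] - tr.values[i]))
                break
        else:
            if abs(h - t_end) < 1e-9:
                hours.append(tr.values[-1])
        h += 60.0
    diffs = [((hours[i + 1] - hours[i]) / MMOL) ** 2 for i in range(len(hours) - 1)]
    return sum(diffs) / len(diffs)


def naive_jindex(tr):
    return 0.324 * ((naive_mean(tr) + naive_std(tr)) / MMOL) ** 2


def _f(g):
    return 1.509 * (math.log(g) ** 1.084 - 5.381)


def naive_hbgi(tr):
    scores = [10 * _f(v) ** 2 if _f(v) > 0 else 0.0 for v in tr.values]
    return sum(scores) / len(scores)


def naive_lbgi(tr):
    scores = [10 * _f(v) ** 2 if _f(v) < 0 else 0.0 for v in tr.values]
    return sum(scores) / len(scores)


def naive_grade(tr):
    scores = []
    for v in tr.values:
        s = 425 * (math.log10(math.log10(v / MMOL)) + 0.16) ** 2
        scores.append(min(s, 50.0))
    return sum(scores) / len(scores)


def naive_modd(tr):
    tol = tr.sampling_interval / 2.0
    diffs = []
    for i in range(len(tr.times)):
        for j in range(len(tr.times)):
            if abs(tr.times[j] - tr.times[i] - 1440.0) <= tol:
                diffs.append(abs(tr.values[j] - tr.values[i]) / MMOL)
                break
    return sum(diffs) / len(diffs)


def naive_mage(tr):
    """Independent transliteration of the Service-style MAGE algorithm."""
    g = list(tr.values)
    n = len(g)
    sd = naive_std(tr)
    if sd == 0 or n < 3:
        return 0.0
    # interior local extrema via three-point comparison, plateaus merged
    idx, sgn = [], []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and g[j + 1] == g[j]:
            j += 1
        if j + 1 < n:
            if g[i] > g[i - 1] and g[i] > g[j + 1]:
                idx.append(i), sgn.append(1)
            elif g[i] < g[i - 1] and g[i] < g[j + 1]:
                idx.append(i), sgn.append(-1)
        i = j + 1
    keep_i, keep_s = [], []
    for k in range(len(idx)):
        if keep_s and sgn[k] == keep_s[-1]:
            if (sgn[k] > 0 and g[idx[k]] > g[keep_i[-1]]) or \
               (sgn[k] < 0 and g[idx[k]] < g[keep_i[-1]]):
                keep_i[-1] = idx[k]
        else:
            keep_i.append(idx[k]), keep_s.append(sgn[k])
    if not keep_i:
        return 0.0
    vals = [g[i] for i in keep_i]
    while len(vals) >= 2:
        amps = [abs(vals[k + 1] - vals[k]) for k in range(len(vals) - 1)]
        kmin, amin = 0, amps[0]
        for k, a in enumerate(amps):
            if a < amin:
                kmin, amin = k, a
        if amin >= sd:
            break
        if len(vals) == 2:
            del vals[kmin + 1]
        elif kmin == 0:
            del vals[0]
        elif kmin == len(vals) - 2:
            del vals[-1]
        else:
            del vals[kmin:kmin + 2]
    amps = [abs(vals[k + 1] - vals[k]) for k in range(len(vals) - 1)]
    amps = [a for a in amps if a >= sd]
    if not amps:
        return 0.0
    return (sum(amps) / len(amps)) / MMOL


def naive_adrr(tr, min_hours=20.0):
    t0 = tr.times[0]
    n_days = int((tr.times[-1] - t0) // 1440) + 1
    totals = []
    for d in range(n_days):
        block = [i for i in range(len(tr.times))
                 if d * 1440 <= tr.times[i] - t0 < (d + 1) * 1440]
        if len(block) < 2:
            continue
        cov = (tr.times[block[-1]] - tr.times[block[0]]
               + tr.sampling_interval) / 60.0
        if cov < min_hours:
            continue
        lr = max(10 * _f(tr.values[i]) ** 2 if _f(tr.values[i]) < 0 else 0.0
                 for i in block)
        hr = max(10 * _f(tr.values[i]) ** 2 if _f(tr.values[i]) > 0 else 0.0
                 for i in block)
        totals.append(lr + hr)
    return sum(totals) / len(totals)


def naive_mvalue(tr):
    scores = [abs(10 * math.log10(v / 120.0)) ** 3 for v in tr.values]
    w = max(tr.values) - min(tr.values)
    return sum(scores) / len(scores) + w / 20.0


def naive_mag(tr):
    total = sum(abs(tr.values[i + 1] - tr.values[i])
                for i in range(len(tr.values) - 1)) / MMOL
    hours = (tr.times[-1] - tr.times[0]) / 60.0
    return total / hours
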