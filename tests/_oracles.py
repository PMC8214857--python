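"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops straight from the defining
formulas, deliberately sharing no code with the package, so that agreement
between package and oracle is evidence of correctness rather than of
shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


def naive_indicator_matrix(expr_values, gene_ids, pairs):
    """Double-loop order indicators: 1 iff expr[a] < expr[b], ties 0."""
    row = {g: i for i, g in enumerate(gene_ids)}
    n = expr_values.shape[1]
    out = np.zeros((len(pairs), n))
    for k, (a, b) in enumerate(pairs):
        for s in range(n):
            xa, xb = expr_values[row[a], s], expr_values[row[b], s]
            if math.isnan(xa) or math.isnan(xb):
                out[k, s] = np.nan
            else:
                out[k, s] = 1.0 if xa < xb else 0.0
    return out


def naive_mad(values):
    """Raw median absolute deviation of a 1-D array, by sorting."""
    med = float(np.median(values))
    return float(np.median([abs(v - med) for v in values]))


def naive_informative(indicators, f_min):
    """Row indices whose mean lies in [f_min, 1 - f_min], by explicit loop."""
    keep = []
    for i, row in enumerate(indicators):
        mean = sum(row) / len(row)
        if f_min <= mean <= 1 - f_min:
            keep.append(i)
    return keep


def naive_harrell_c(scores, time, event):
    """Pairwise enumeration of Harrell's concordance.

    A pair (i, j) with time_i < time_j is usable iff the earlier subject
    had an event; tied times are usable iff exactly one died (the death is
    called first). Concordant means the earlier event carries the higher
    score; score ties count 1/2.
    """
    n = len(scores)
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj, di, dj = time[i], time[j], event[i], event[j]
            si, sj = scores[i], scores[j]
            if ti == tj:
                if di and dj:
                    pass  # both died together: excluded, order undecidable
                elif di != dj:
                    den += 1
                    # the death should have the higher score than the survivor
                    dead_s, alive_s = (si, sj) if di else (sj, si)
                    num += 1.0 if dead_s > alive_s else (0.5 if dead_s == alive_s else 0.0)
                continue
            first, later = (i, j) if ti < tj else (j, i)
            if not event[first]:
                continue  # censored before the other: not comparable
            den += 1
            if scores[first] > scores[later]:
                num += 1.0
            elif scores[first] == scores[later]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def naive_km(time, event):
    """Product-limit estimate as (event_times, survival_values)."""
    order = np.argsort(time)
    t, e = np.asarray(time)[order], np.asarray(event)[order]
    s = 1.0
    times, surv = [], []
    for tt in sorted(set(t)):
        at_risk = int((t >= tt).sum())
        deaths = int(((t == tt) & (e == 1)).sum())
        if deaths:
            s *= 1 - deaths / at_risk
            times.append(tt)
            surv.append(s)
    return np.array(times), np.array(surv)


def naive_logrank_chi2(time, event, group):
    """Textbook two-sample log-rank: observed vs expected at each event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)  # 1 = group A
    o_minus_e = 0.0
    var = 0.0
    for tt in sorted(set(time[event == 1])):
        at_risk = time >= tt
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        d = int(((time == tt) & (event == 1)).sum())
        d1 = int(((time == tt) & (event == 1) & (group == 1)).sum())
        if n == 0 or d == 0:
            continue
        expected = d * n1 / n
        o_minus_e += d1 - expected
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def naive_rms(time, event, tau):
    """Area under the KM step function on [0, tau], rectangle by rectangle."""
    kt, ks = naive_km(time, event)
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in zip(kt, ks):
        if t >= tau:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    area += prev_s * (tau - prev_t)
    return area


def naive_censoring_km_left(time, event, t_query):
    """G(t-) for the censoring distribution, by its own product-limit loop."""
    time = np.asarray(time, float)
    cens = 1 - np.asarray(event, int)
    s = 1.0
    steps = []
    for tt in sorted(set(time[cens == 1])):
        at_risk = int((time >= tt).sum())
        d = int(((time == tt) & (cens == 1)).sum())
        s *= 1 - d / at_risk
        steps.append((tt, s))
    g = 1.0
    for tt, val in steps:
        if tt < t_query:
            g = val
        else:
            break
    return g


def naive_ipcw_auc(scores, time, event, horizon):
    """Cumulative/dynamic AUC at one horizon by explicit double loop.

    Cases: observed events at or before the horizon, weighted 1/G(T_i-);
    controls: subjects with follow-up beyond the horizon. Score ties 1/2.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = 0.0
    w_sum = 0.0
    n_ctrl = 0
    for j in range(len(scores)):
        if time[j] > horizon:
            n_ctrl += 1
    for i in range(len(scores)):
        if event[i] != 1 or time[i] > horizon:
            continue
        w = 1.0 / naive_censoring_km_left(time, event, time[i])
        w_sum += w
        for j in range(len(scores)):
            if time[j] <= horizon:
                continue
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / (w_sum * n_ctrl)


def efron_log_partial_likelihood(beta, X, time, event):
    """Efron-tie Cox log partial likelihood by direct summation.

    ``X`` is samples x covariates; ``beta`` a coefficient vector.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ beta
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for tt in sorted(set(time[event == 1])):
        D = np.flatnonzero((time == tt) & (event == 1))
        R = np.flatnonzero(time >= tt)
        d = len(D)
        sum_r = np.exp(eta[R]).sum()
        sum_d = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        for ell in range(d):
            ll -= math.log(sum_r - (ell / d) * sum_d)
    return ll


def numeric_score_and_information(X, time, event, h=1e-4):
    """U(0) and I(0) of the Efron log partial likelihood, by central differences."""
    f = lambda b: efron_log_partial_likelihood([b], X, time, event)
    u = (f(h) - f(-h)) / (2 * h)
    info = -(f(h) - 2 * f(0.0) + f(-h)) / (h * h)
    return u, info
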