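"""Independent brute-force oracles used to cross-check the estimators.

Everything here is deliberately naive (exhaustive pair enumeration, manual
grouping, Newton-Raphson from scratch) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def auc_brute(pred, outcome):
    """Exhaustive case-control pair counting; ties count 1/2."""
    pred = list(map(float, pred))
    cases = [p for p, y in zip(pred, outcome) if y]
    controls = [p for p, y in zip(pred, outcome) if not y]
    total = 0.0
    for pc in cases:
        for pn in controls:
            total += 1.0 if pc > pn else (0.5 if pc == pn else 0.0)
    return total / (len(cases) * len(controls))


def harrell_c_brute(pred, time, event):
    """Exhaustive comparable-pair enumeration.

    Pair (i, j) is comparable iff the earlier exit is an event; with tied
    exits, iff exactly one is an event (the event counts as earlier).  The
    pair is concordant when the earlier event carries the higher prediction.
    """
    n = len(pred)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                if event[i] == event[j]:
                    continue
                first = i if event[i] else j
            elif time[i] < time[j]:
                if not event[i]:
                    continue
                first = i
            else:
                if not event[j]:
                    continue
                first = j
            other = j if first == i else i
            den += 1
            if pred[first] > pred[other]:
                num += 1.0
            elif pred[first] == pred[other]:
                num += 0.5
    if den == 0:
        return None
    return num / den


def decile_groups_brute(pred, n_groups=10):
    """Manual equal-count grouping: stable rank, remainder to lowest groups."""
    n = len(pred)
    order = sorted(range(n), key=lambda i: (pred[i], i))
    base, rem = divmod(n, n_groups)
    groups = []
    start = 0
    for g in range(n_groups):
        size = base + 1 if g < rem else base
        groups.append(order[start : start + size])
        start += size
    return groups


def classification_brute(values, outcome, cut_low, cut_high):
    """Manual three-category percentages of population and of cases."""
    cats = []
    for v in values:
        if v < cut_low:
            cats.append("near-population")
        elif v < cut_high:
            cats.append("moderate")
        else:
            cats.append("high")
    n = len(values)
    n_cases = sum(1 for y in outcome if y)
    out = {}
    for cat in ("near-population", "moderate", "high"):
        in_cat = [i for i, c in enumerate(cats) if c == cat]
        cases_in = sum(1 for i in in_cat if outcome[i])
        out[cat] = (
            100.0 * len(in_cat) / n,
            100.0 * cases_in / n_cases if n_cases else float("nan"),
        )
    return out


def top_fraction_brute(pred, outcome, fraction):
    """Manual descending stable sort, ceil(fraction*n) taken, % cases captured."""
    n = len(pred)
    order = sorted(range(n), key=lambda i: (-pred[i], i))
    k = math.ceil(fraction * n)
    captured = sum(1 for i in order[:k] if outcome[i])
    n_cases = sum(1 for y in outcome if y)
    return 100.0 * captured / n_cases if n_cases else float("nan")


def logistic_irls(x, y, tol=1e-12, max_iter=200):
    """Newton-Raphson logistic regression with intercept; returns (b0, b1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def riemann_cumulative_risk(table, start, end, rr, step=1.0 / 365.0):
    """Fine-step Riemann-sum integration of 1 - exp(-rr * integral hazard)."""
    ages = np.arange(start, end, step)
    lam = np.array([table.hazard_at(a + step / 2.0) for a in ages[:-1]])
    lam = np.append(lam, table.hazard_at(ages[-1]))
    cum = float(np.sum(lam * step))
    # correct the final partial step
    overshoot = (ages[-1] + step) - end
    if overshoot > 0:
        cum -= float(lam[-1] * overshoot)
    return 1.0 - math.exp(-rr * cum)
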