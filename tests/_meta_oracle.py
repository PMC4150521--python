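"""Independent brute-force re-derivation of the pooling formulas.

Deliberately written as plain loops over (a, b, c, d) tuples, with no
imports from the package, so it can serve as an oracle for the
meta-analysis module.  Keep it dumb and readable.
"""

import math

from scipy.stats import chi2


def oracle_effect(a, b, c, d, correction=0.5):
    if 0 in (a, b, c, d):
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    log_or = math.log((a * d) / (b * c))
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return log_or, var


def oracle_pool(tables, correction=0.5):
    """Full pooling with model selection on a list of (a,b,c,d) tuples.

    Returns a dict with pooled_or, ci_low, ci_high, q, q_p, tau2, model.
    """
    effects = [oracle_effect(*t, correction=correction) for t in tables]
    k = len(effects)
    weights = [1.0 / v for _, v in effects]
    wsum = sum(weights)
    fixed_mean = sum(w * y for w, (y, _) in zip(weights, effects)) / wsum

    if k == 1:
        q, q_p, tau_raw = 0.0, 1.0, 0.0
    else:
        q = sum(w * (y - fixed_mean) ** 2 for w, (y, _) in zip(weights, effects))
        q_p = float(chi2.sf(q, k - 1))
        tau_raw = (q - (k - 1)) / (wsum - sum(w * w for w in weights) / wsum)

    if tau_raw <= 0 and q_p >= 0.10:
        model, tau2 = "fixed", 0.0
        mean, se = fixed_mean, wsum ** -0.5
    else:
        model, tau2 = "random", max(0.0, tau_raw)
        wstar = [1.0 / (v + tau2) for _, v in effects]
        mean = sum(w * y for w, (y, _) in zip(wstar, effects)) / sum(wstar)
        se = sum(wstar) ** -0.5

    return {
        "model": model,
        "pooled_or": math.exp(mean),
        "ci_low": math.exp(mean - 1.96 * se),
        "ci_high": math.exp(mean + 1.96 * se),
        "q": q,
        "q_p": q_p,
        "tau2": tau2,
        "k": k,
    }
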