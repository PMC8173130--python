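"""Independent reference computations used to cross-check the package.

Everything here is deliberately written from first principles (quadrature,
exhaustive enumeration, hand product-limit arithmetic) and never calls the
code paths it validates.
"""

import itertools

import numpy as np

from hypoximap.aif import evaluate_aif


def convolution_oracle(ktrans, ve, aif, times_s, dt_s=0.01):
    """Tofts tissue curve by fine-step trapezoidal convolution.

    C_t(t) = Ktrans * int_0^t C_a(u) exp(-k_ep (t - u)) du, evaluated on a
    0.01 s grid in minutes-consistent units.
    """
    kep = ktrans / ve  # min^-1
    out = np.zeros(len(times_s))
    for i, ti in enumerate(times_s):
        if ti == 0:
            continue
        tau = np.arange(0.0, ti + dt_s / 2, dt_s)
        f = evaluate_aif(aif, tau) * np.exp(-kep * (ti - tau) / 60.0)
        out[i] = ktrans * np.trapezoid(f, tau / 60.0)
    return out


def logrank_chi2(times, events, group):
    """Two-group log-rank chi-square with hypergeometric variance,
    accumulated over pooled event times with simultaneous tie handling."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group, dtype=bool)
    obs = exp = var = 0.0
    for ti in np.unique(t[e]):
        at_risk = t >= ti
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = (e & (t == ti)).sum()
        d1 = (e & (t == ti) & g).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var if var > 0 else 0.0


def logrank_permutation_distribution(times, events, n_group1):
    """Log-rank chi-square under every relabeling into groups of fixed size."""
    n = len(times)
    stats = []
    for idx in itertools.combinations(range(n), n_group1):
        g = np.zeros(n, dtype=bool)
        g[list(idx)] = True
        stats.append(logrank_chi2(times, events, g))
    return np.asarray(stats)


def product_limit(times, events):
    """Hand-rolled Kaplan-Meier: returns (event_times, survival)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    s = 1.0
    out_t, out_s = [], []
    for ti in np.unique(t[e]):
        n_risk = np.sum(t >= ti)
        d = np.sum(e & (t == ti))
        s *= 1.0 - d / n_risk
        out_t.append(ti)
        out_s.append(s)
    return np.asarray(out_t), np.asarray(out_s)


def brute_force_hf(ktrans, ve, rule):
    """Hypoxic fraction by explicit per-voxel loop over viable voxels."""
    n_h = n_v = 0
    for k, v in zip(np.ravel(ktrans), np.ravel(ve)):
        if not (np.isfinite(k) and np.isfinite(v)) or v > 1.0:
            continue
        n_v += 1
        if rule.strategy == "ktrans_only":
            hyp = k < rule.k0trans
        elif rule.strategy == "ve_only":
            hyp = v < rule.ve0
        elif rule.strategy == "conjunction":
            hyp = k < rule.k0trans and v < rule.ve0
        else:
            hyp = k / rule.k0trans + v / rule.ve0 < 1
        n_h += hyp
    return n_h / n_v if n_v else float("nan")
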