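"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the rule definitions directly — exact
rational arithmetic for the Fisher tail, a literal step-up loop for BH, and
a per-cell loop for outlier labeling — and shares no code path with the
package internals it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_enumeration(tumor_outliers, tumor_n, normal_outliers, normal_n):
    """Exact one-sided Fisher p by summing hypergeometric point masses.

    Margins fixed at (tumor_n, normal_n) columns and K = total outliers;
    the tail sums every table at least as tumor-enriched as observed.
    """
    K = tumor_outliers + normal_outliers
    N = tumor_n + normal_n
    denom = comb(N, tumor_n)
    total = Fraction(0)
    for k in range(tumor_outliers, min(tumor_n, K) + 1):
        if K - k > normal_n:
            continue
        total += Fraction(comb(K, k) * comb(N - K, tumor_n - k), denom)
    return float(total)


def bh_step_up(p_values):
    """Literal Benjamini-Hochberg step-up: adj_(i) = min_{j>=i} p_(j) * n / j."""
    p = list(p_values)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [None] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def brute_force_calls(values, groups, config):
    """Literal per-cell application of the outlier rules.

    ``values``: junctions x samples array (NaN = undefined);
    ``groups``: list of "tumor"/"normal" per column. Returns an array of
    {over, under, none, undefined} labels mirroring call_outliers.
    """
    eps = 1e-12
    values = np.asarray(values, dtype=float)
    n_j, n_s = values.shape
    normal_cols = [i for i, g in enumerate(groups) if g == "normal"]
    labels = np.full((n_j, n_s), "none", dtype=object)

    for j in range(n_j):
        normal_vals = [values[j, c] for c in normal_cols if not np.isnan(values[j, c])]
        if len(normal_vals) < 2:
            labels[j, :] = "undefined"
            continue
        for s in range(n_s):
            v = values[j, s]
            if np.isnan(v):
                labels[j, s] = "undefined"
                continue
            if groups[s] == "normal":
                ref = [values[j, c] for c in normal_cols if c != s and not np.isnan(values[j, c])]
            else:
                ref = normal_vals
            lo_q = np.quantile(ref, config.tail_quantile)
            hi_q = np.quantile(ref, 1 - config.tail_quantile)
            med = np.median(ref)
            iqr = hi_q - lo_q
            upper = hi_q + config.iqr_multiplier * iqr
            lower = lo_q - config.iqr_multiplier * iqr
            if (
                v > upper
                and v >= config.min_norm_expr
                and v >= config.fold_change_cutoff * max(med, eps)
            ):
                labels[j, s] = "over"
            elif (
                v < lower
                and med >= config.min_norm_expr
                and med >= config.fold_change_cutoff * max(v, eps)
            ):
                labels[j, s] = "under"
    return labels
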