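"""Textbook implementations of one-way ANOVA and Tukey-Kramer HSD.

Deliberately written from the sums-of-squares definitions (explicit python
arithmetic) so they form an independent cross-check of the package's
statistics layer.
"""

import math

from scipy.stats import f as f_dist
from scipy.stats import studentized_range


def anova_by_sums_of_squares(groups):
    """F and p from hand-computed between/within sums of squares."""
    all_values = [v for vals in groups.values() for v in vals]
    n = len(all_values)
    k = len(groups)
    grand = sum(all_values) / n
    ss_between = sum(len(vals) * (sum(vals) / len(vals) - grand) ** 2 for vals in groups.values())
    ss_within = sum(
        (v - sum(vals) / len(vals)) ** 2 for vals in groups.values() for v in vals
    )
    df_b, df_w = k - 1, n - k
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(f_dist.sf(f_stat, df_b, df_w))
    return f_stat, df_b, df_w, p


def tukey_kramer_pvalues(groups):
    """Adjusted p per pair from the studentized-range distribution."""
    names = list(groups)
    k = len(names)
    n = sum(len(v) for v in groups.values())
    ms_within = (
        sum((v - sum(vals) / len(vals)) ** 2 for vals in groups.values() for v in vals)
        / (n - k)
    )
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            diff = sum(a) / len(a) - sum(b) / len(b)
            se = math.sqrt(ms_within / 2 * (1 / len(a) + 1 / len(b)))
            q = abs(diff) / se
            out[(names[i], names[j])] = float(studentized_range.sf(q, k, n - k))
    return out
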