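"""Independent brute-force oracles, deliberately coded apart from the package.

The Welch t here follows the textbook formulas directly; the Mann-Whitney
oracle enumerates every labeling of the pooled sample. Both exist so the
pipeline's test statistics can be checked against an implementation that
shares no code path with them.
"""

import itertools
import math

from scipy.stats import t as t_dist


def welch_t_p(a, b):
    """Two-sided Welch t p-value from the definition."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * t_dist.sf(abs(t), df)


def student_t_p(a, b):
    """Two-sided pooled-variance t p-value from the definition."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2.0 * t_dist.sf(abs(t), df)


def _u_statistic(a, b):
    return sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )


def mannwhitney_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all C(n, na) labelings."""
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = _u_statistic(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(_u_statistic(grp_a, grp_b))
    n = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / n
    p_ge = sum(1 for u in us if u >= u_obs) / n
    return min(1.0, 2.0 * min(p_le, p_ge))
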