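"""Independent textbook oracles used by the test suite.

Deliberately naive implementations, kept separate from the package so they
cannot share code paths with what they check.
"""

import math

from scipy.stats import t as t_dist


def pooled_t_oracle(a, b):
    """Two-sample pooled-variance t test, written out longhand."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = (ma - mb) / se
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p
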