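"""Independent brute-force reference implementations of the metrics.

Plain Python loops, no numpy vectorisation: these serve as oracles for
the production metric functions and must stay independent of them.
"""

import math


def loop_rmse(td, te):
    total = 0.0
    for a, b in zip(td, te):
        total += (a - b) ** 2
    return math.sqrt(total / len(td))


def loop_nse(td, te):
    mean = sum(td) / len(td)
    num = 0.0
    den = 0.0
    for a, b in zip(td, te):
        num += (a - b) ** 2
        den += (a - mean) ** 2
    return 1.0 - num / den


def loop_mae(td, te):
    total = 0.0
    for a, b in zip(td, te):
        total += abs(a - b)
    return total / len(td)


def loop_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for a, b in zip(x, y):
        sxy += (a - mx) * (b - my)
        sxx += (a - mx) ** 2
        syy += (b - my) ** 2
    return sxy / math.sqrt(sxx * syy)
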