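"""Independent oracles used by the test suite.

These are deliberately simple brute-force implementations, kept separate
from the package so they cannot share code paths with what they check.
"""

import numpy as np


def wright_fisher_fixation_rate(n_pop, s, n_copies=1, n_runs=100_000, seed=0):
    """Forward Wright-Fisher simulation of a selected allele's fate.

    Haploid-style sampling: each generation the allele count is
    Binomial(N, p') with p' = p(1+s) / (1 + p*s).  Returns (fixation
    fraction, Monte-Carlo SE).
    """
    rng = np.random.default_rng(seed)
    counts = np.full(n_runs, n_copies, dtype=np.int64)
    active = np.ones(n_runs, dtype=bool)
    while active.any():
        p = counts[active] / n_pop
        p_sel = p * (1 + s) / (1 + p * s)
        counts[active] = rng.binomial(n_pop, p_sel)
        active = (counts > 0) & (counts < n_pop)
    frac = float(np.mean(counts == n_pop))
    se = float(np.sqrt(frac * (1 - frac) / n_runs))
    return frac, se


def excess_het_by_hand(dosages):
    """Excess ancestry heterozygosity of one individual, spelled out."""
    d = [x for x in dosages if x is not None and not np.isnan(x)]
    n = len(d)
    observed = sum(1 for x in d if x == 1) / n
    h = sum(d) / (2 * n)
    return observed - 2.0 * h * (1.0 - h)
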