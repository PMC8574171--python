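"""Independent test oracles (brute force / grid search), kept apart from the
implementation paths they check."""

import numpy as np


def grid_search_factor(x, mu, lo=0.01, hi=100.0, step=1e-4):
    """Coarse-to-fine grid minimization of the scale-factor RMSD objective."""
    x = np.asarray(x, float)
    mu = np.asarray(mu, float)
    on = x > 0

    def rmsd(f):
        return np.sqrt(np.mean((np.multiply.outer(f, x[on]) - mu[on]) ** 2, axis=-1))

    coarse = np.geomspace(lo, hi, 4000)
    best = coarse[np.argmin(rmsd(coarse))]
    fine = np.arange(max(lo, best * 0.9), best * 1.1, step)
    f = fine[np.argmin(rmsd(fine))]
    return float(f), float(rmsd(np.array([f]))[0])


def average_ranks(values):
    """Average ranks with ties, by direct enumeration."""
    values = list(values)
    ranks = []
    for v in values:
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(smaller + (equal + 1) / 2.0)
    return np.array(ranks)
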