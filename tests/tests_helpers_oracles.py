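"""Shared brute-force oracles, independent of the implementations they check."""

import itertools

import numpy as np

from starimpute.hmm import MISSING


def enumerate_posteriors(target, haps, rho, theta):
    """Posterior copying probabilities by summing over all K^M state paths."""
    haps = np.asarray(haps)
    K, M = haps.shape
    post = np.zeros((M, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=M):
        p = 1.0 / K
        for m in range(1, M):
            p *= rho / K + (1.0 - rho) * (path[m] == path[m - 1])
        for m in range(M):
            if target[m] != MISSING:
                p *= (1.0 - theta) if haps[path[m], m] == target[m] else theta
        total += p
        for m in range(M):
            post[m, path[m]] += p
    return post / total
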