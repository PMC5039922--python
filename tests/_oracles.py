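"""Independent brute-force oracles for the HMM (exhaustive path enumeration).

Kept deliberately separate from the package: computes marginal posteriors
and the best path by enumerating all 3^n state sequences with plain
probability products, never via forward-backward recursions.
"""

import itertools

import numpy as np


def enumerate_hmm(codes, T, pi, E):
    """Exact posteriors and MAP path by summing over every state path.

    codes: int observation codes (0, 1, 2=missing); T: (3,3) transitions;
    pi: initial distribution; E: (3,3) emissions indexed [state, code].
    Returns (posteriors (n,3), map_path (n,), loglik).  Paths are generated
    in lexicographic order with N first, so argmax ties prefer N-early
    paths.
    """
    codes = np.asarray(codes)
    n = len(codes)
    paths = np.array(list(itertools.product(range(3), repeat=n)), dtype=np.int64)
    joint = pi[paths[:, 0]] * E[paths[:, 0], codes[0]]
    for t in range(1, n):
        joint = joint * T[paths[:, t - 1], paths[:, t]] * E[paths[:, t], codes[t]]
    total = joint.sum()
    post = np.empty((n, 3))
    for t in range(n):
        for s in range(3):
            post[t, s] = joint[paths[:, t] == s].sum() / total
    best = paths[int(np.argmax(joint))]
    return post, best, float(np.log(total))


def pairwise_concordance_bruteforce(z):
    """Adjacent-pair concordance by explicit looping (no vectorization)."""
    obs = [v for v in z if v == v]  # drop NaN
    if len(obs) < 2:
        return float("nan")
    agree = 0
    pairs = 0
    for a, b in zip(obs, obs[1:]):
        pairs += 1
        if a == b:
            agree += 1
    return agree / pairs
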