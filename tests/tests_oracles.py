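"""Independent brute-force oracles shared by the unit and acceptance tests.

These re-derive expected results from first principles (exhaustive
enumeration) and deliberately share no code with the implementation.
"""

import itertools

import numpy as np


def brute_force_peaks(values, threshold=0.5, min_support=5):
    """Enumerate local maxima; count above-threshold samples whose
    steepest-ascent path (ties toward the left, plateaus represented by
    their leftmost sample) terminates at each; keep maxima with at least
    ``min_support`` supporters."""
    n = len(values)

    def climb(s):
        while True:
            left = values[s - 1] if s > 0 else -np.inf
            right = values[s + 1] if s < n - 1 else -np.inf
            here = values[s]
            if left > here and right > here:
                s = s - 1 if left >= right else s + 1
            elif left > here:
                s -= 1
            elif right > here:
                s += 1
            elif left == here and s > 0:
                s -= 1
            else:
                return s

    support = {}
    for s in range(n):
        if values[s] > threshold:
            m = climb(s)
            support[m] = support.get(m, 0) + 1
    return sorted(m for m, c in support.items() if c >= min_support)


def optimal_pair_count(det, ann, fs, tol_s=0.075):
    """Maximum one-to-one matching size by exhaustive search (instances of
    up to ~10 beats)."""
    det, ann = list(det), list(ann)
    for r in range(min(len(det), len(ann)), 0, -1):
        for ann_sub in itertools.combinations(range(len(ann)), r):
            for det_perm in itertools.permutations(range(len(det)), r):
                if all(abs(det[d] - ann[a]) / fs <= tol_s + 1e-12
                       for a, d in zip(ann_sub, det_perm)):
                    return r
    return 0
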