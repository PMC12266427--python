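"""Independent brute-force oracles for small pure-birth instances."""

from collections import Counter
from fractions import Fraction
from itertools import product


def enumerate_pure_birth_dd(i):
    """Exact E[D_{l,i}] as Fractions by enumerating all i! division choices.

    At step t there are t+1 cells and the divider is uniform among them,
    so every choice sequence has probability 1/i!.
    """
    totals = Counter()
    n_seq = 0
    for seq in product(*(range(t + 1) for t in range(i))):
        depths = [0]
        for c in seq:
            depths.append(depths[c] + 1)
            depths[c] = depths[-1]
        totals.update(depths)
        n_seq += 1
    return {ell: Fraction(cnt, n_seq) for ell, cnt in totals.items()}


def enumerate_mean_divisions(i):
    """Exact mean leaf depth E[T_i]/(i+1) as a Fraction, by enumeration."""
    dd = enumerate_pure_birth_dd(i)
    total = sum(ell * w for ell, w in dd.items())
    return total / (i + 1)
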