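"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (pure-Python loops, integer
hypergeometric enumeration) so they stay independent of the vectorized
library code paths they are used to check.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from nbescan.motif import build_pwm

NBE = "CUGAGGA"


@pytest.fixture(scope="session")
def pwm():
    """Default NBE PWM: match probability 0.85, uniform background."""
    return build_pwm(NBE, 0.85)


# ---------------------------------------------------------------- oracles

def brute_force_hamming_scan(sequence: str, pattern: str, max_mismatches: int
                             ) -> list[tuple[int, int]]:
    """Naive sliding-window Hamming scan; 1-based starts."""
    seq = sequence.upper().replace("U", "T")
    pat = pattern.upper().replace("U", "T")
    k = len(pat)
    out = []
    for start in range(len(seq) - k + 1):
        window = seq[start:start + k]
        mismatches = sum(
            1 for a, b in zip(window, pat)
            if a != b or a not in "ACGT"
        )
        if mismatches <= max_mismatches:
            out.append((start + 1, mismatches))
    return out


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration.

    All tables with the observed margins are enumerated; those with
    probability <= the observed table's contribute.  Numerators share a
    denominator, so the tie comparison is exact integer arithmetic.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs_num = comb(r1, a) * comb(r2, c1 - a)
    total = comb(n, c1)
    p_num = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= obs_num:
            p_num += num
    return p_num / total


def linear_scan_pvalue(score: float, null_scores: np.ndarray) -> float:
    """Add-one empirical p by direct counting (no sorting/searchsorted)."""
    n_ge = sum(1 for s in null_scores for _ in [0] if s >= score)
    return (1 + n_ge) / (len(null_scores) + 1)


def all_kmers(k: int):
    """All 4^k DNA k-mers."""
    from itertools import product
    for letters in product("ACGT", repeat=k):
        yield "".join(letters)
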