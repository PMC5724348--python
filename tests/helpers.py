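"""Brute-force oracles and small utilities shared across the test suite."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"


def random_dna(rng: np.random.Generator, n: int, alphabet: str = DNA) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _char_match(a: str, b: str) -> bool:
    # DNA-mode semantics: non-ACGT characters never match, themselves included
    return a == b and a in DNA


def naive_match_length(s1: str, s2: str, i: int, j: int) -> int:
    l = 0
    while i + l < len(s1) and j + l < len(s2) and _char_match(s1[i + l], s2[j + l]):
        l += 1
    return l


def naive_matching_stats(s1: str, s2: str):
    """Per-position longest exact match lengths and full partner sets.

    Quadratic scan; the independent oracle for the suffix-array search.
    """
    xs, partners = [], []
    for i in range(len(s1)):
        lengths = [naive_match_length(s1, s2, i, j) for j in range(len(s2))]
        best = max(lengths) if lengths else 0
        xs.append(best)
        partners.append(sorted(j for j, l in enumerate(lengths) if l == best) if best >= 1 else [])
    return xs, partners


def naive_extension_length(s1: str, s2: str, i: int, j: int, k: int):
    """Direct scan: characters before the (k+1)-st mismatch; (length, truncated)."""
    mism = 0
    l = 0
    while i + l < len(s1) and j + l < len(s2):
        if not _char_match(s1[i + l], s2[j + l]):
            mism += 1
            if mism > k:
                return l, False
        l += 1
    return l, True


def bins_within_3se(empirical_counts: np.ndarray, probs: np.ndarray, n: int, min_expected: float = 5.0):
    """Per-bin z-scores of an empirical histogram against a discrete law.

    Only bins with expected count >= ``min_expected`` are scored (binomial
    normality breaks down below that).  Returns the array of |z| values.
    """
    emp = empirical_counts / n
    se = np.sqrt(probs * (1.0 - probs) / n)
    mask = probs * n >= min_expected
    return np.abs((emp[mask] - probs[mask]) / se[mask])
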