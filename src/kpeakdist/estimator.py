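"""Distance estimation from the second peak of the extension-length spectrum.

The mode of the homologous component sits at ``m = ceil(k/(1-p) - 1)``, so an
observed second-peak position ``m_E`` inverts to the match-probability
estimate ``p_hat = (m_E + 1 - k) / (m_E + 1)`` with the bracket
``(m_E - k)/m_E <= p <= (m_E + 1 - k)/(m_E + 1)``.  The usual Jukes-Cantor
correction then yields substitutions per site.  All failure modes (no second
peak, saturation at p_hat <= 0.25) are statuses, never exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import theory
from .matchstats import MatchLengthSpectrum, SequencePair, collect_spectrum
from .spectrum import PeakCall, find_second_peak, smooth

__all__ = [
    "DistanceEstimate",
    "DistanceMatrix",
    "estimate_p",
    "p_bounds",
    "estimate_distance",
    "pairwise_matrix",
    "default_w",
    "default_k",
]

#: the operating point used throughout for 500 kb sequence pairs
DEFAULT_K = 90
DEFAULT_RATIO = 10.0
DEFAULT_X = 4
_REFERENCE_L = 500_000


def default_w(k: int) -> int:
    """Default smoothing window: nearest odd integer to k/3.

    Scales with the homologous peak width (which grows with k) and
    reproduces the w=31 operating point at k=90.
    """
    w = int(round(k / 3.0))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def default_k(L: int) -> int:
    """Heuristic mismatch count for sequences of length L.

    Log-scaling anchored at k=90 for L=500 kb; no principled selection rule
    is known, so treat this as a starting point only.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    return max(10, int(round(DEFAULT_K * math.log(L) / math.log(_REFERENCE_L))))


def estimate_p(m_E: int, k: int) -> float:
    """Match probability from the second-peak position: (m_E+1-k)/(m_E+1)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if m_E < k:
        raise ValueError(f"peak position m_E={m_E} below k={k} is impossible")
    return (m_E + 1 - k) / (m_E + 1)


def p_bounds(m_E: int, k: int) -> tuple[float, float]:
    """Bracket (m_E-k)/m_E <= p <= (m_E+1-k)/(m_E+1) around the peak mode."""
    if m_E < max(k, 1):
        raise ValueError(f"peak position m_E={m_E} below k={k} is impossible")
    return ((m_E - k) / m_E, (m_E + 1 - k) / (m_E + 1))


@dataclass
class DistanceEstimate:
    """Match probability and Jukes-Cantor distance from one spectrum."""

    status: str  # "ok" | "no_peak" | "saturated"
    p_hat: float | None = None
    d_hat: float | None = None
    m_E: int | None = None
    p_lower: float | None = None
    p_upper: float | None = None
    peak: PeakCall | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def estimate_distance(
    pair_spectrum: MatchLengthSpectrum,
    w: int | None = None,
    ratio: float = DEFAULT_RATIO,
    x: int = DEFAULT_X,
    k: int | None = None,
) -> DistanceEstimate:
    """smooth -> find second peak -> invert to p_hat -> Jukes-Cantor distance."""
    if k is None:
        k = pair_spectrum.k
    if w is None:
        w = default_w(k)
    smoothed = smooth(pair_spectrum, w)
    peak = find_second_peak(smoothed, ratio=ratio, x=x)
    if not peak.found:
        return DistanceEstimate("no_peak", peak=peak)
    m_e = int(peak.m_star)
    if m_e < k:
        # a peak left of k cannot come from a k-mismatch extension mode
        return DistanceEstimate("no_peak", peak=peak)
    p_hat = estimate_p(m_e, k)
    lo, hi = p_bounds(m_e, k)
    if p_hat <= 0.25:
        return DistanceEstimate("saturated", p_hat=p_hat, m_E=m_e, p_lower=lo, p_upper=hi, peak=peak)
    d_hat = theory.jukes_cantor_distance(p_hat)
    return DistanceEstimate("ok", p_hat=p_hat, d_hat=d_hat, m_E=m_e, p_lower=lo, p_upper=hi, peak=peak)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distance estimates; NaN marks failures."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_failed(self) -> int:
        iu = np.triu_indices(len(self.labels), 1)
        return int(np.isnan(self.values[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self, path, na: str = "NA", drop_failed: bool = False) -> None:
        from .io import write_phylip

        write_phylip(self, path, na=na, drop_failed=drop_failed)


@dataclass
class PairwiseRun:
    """Distance matrix plus per-pair diagnostics from an all-vs-all run."""

    matrix: DistanceMatrix
    diagnostics: pd.DataFrame = field(repr=False)


def pairwise_matrix(
    sequences,
    k: int | None = None,
    w: int | None = None,
    ratio: float = DEFAULT_RATIO,
    x: int = DEFAULT_X,
    pool_directions: bool = True,
    alphabet: str = "dna",
) -> PairwiseRun:
    """Full pipeline on every unordered pair of sequences.

    ``sequences`` is a list of ``(label, sequence)`` tuples (as produced by
    :func:`kpeakdist.io.read_fasta`).  Failed pairs are NaN in the matrix and
    carry their status in the diagnostics table.
    """
    sequences = list(sequences)
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [lab for lab, _ in sequences]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(sequences)
    values = np.zeros((n, n), dtype=float)
    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            lab1, s1 = sequences[a]
            lab2, s2 = sequences[b]
            pair = SequencePair(s1, s2, id1=lab1, id2=lab2, alphabet=alphabet)
            k_ab = k if k is not None else default_k(min(len(s1), len(s2)))
            spec = collect_spectrum(pair, k=k_ab, pool_directions=pool_directions)
            est = estimate_distance(spec, w=w, ratio=ratio, x=x, k=k_ab)
            d = est.d_hat if est.ok else np.nan
            values[a, b] = values[b, a] = d
            rows.append(
                {
                    "label1": lab1,
                    "label2": lab2,
                    "k": k_ab,
                    "n_extensions": spec.total,
                    "m_star": est.m_E,
                    "p_hat": est.p_hat,
                    "d_hat": est.d_hat if est.ok else np.nan,
                    "status": est.status,
                }
            )
    return PairwiseRun(DistanceMatrix(labels, values), pd.DataFrame(rows))
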