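"""Smoothing of extension-length histograms and second-peak detection.

The raw histogram N(m) is a mixture of a large background peak and a much
smaller homologous peak to its right.  A centered moving average of odd
width ``w`` suppresses sampling noise; the homologous peak is then the
highest local maximum strictly right of the global maximum that is (a) at
most ``global_max / ratio`` high and (b) higher than the smoothed value
``x`` bins to its left.  Failure to find such a peak is a valid outcome
(reported, not raised): for distant sequences the homologous peak is
swallowed by the background peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matchstats import MatchLengthSpectrum

__all__ = ["SmoothedSpectrum", "PeakCall", "smooth", "find_second_peak"]


@dataclass
class SmoothedSpectrum:
    """Moving-average-smoothed histogram, indexed by length m from 0."""

    counts: np.ndarray
    w: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.counts.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"m": self.lengths, "N": self.counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PeakCall:
    """Detected second peak, or an explicit not-found state."""

    found: bool
    m_star: int | None
    global_max_pos: int
    global_max_val: float
    peak_val: float | None = None


def smooth(raw, w: int) -> SmoothedSpectrum:
    """Centered moving average of odd width ``w``.

    At the array boundaries the window shrinks symmetrically to the available
    support, so a constant array is unchanged for any ``w`` and ``w=1`` is
    the identity.  A :class:`MatchLengthSpectrum` input is right-padded with
    ``w`` zero bins first (the left bins below m=k are already zero), which
    keeps the total mass exactly conserved in practice.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window width must be odd and >= 1, got {w}")
    if isinstance(raw, MatchLengthSpectrum):
        counts = np.concatenate([raw.counts.astype(float), np.zeros(w)])
    else:
        counts = np.asarray(raw, dtype=float)
    n = counts.size
    if n == 0:
        raise ValueError("cannot smooth an empty spectrum")
    idx = np.arange(n)
    half = np.minimum(w // 2, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    out = (csum[idx + half + 1] - csum[idx - half]) / (2 * half + 1)
    return SmoothedSpectrum(out, w)


def _plateau_local_maxima(c: np.ndarray):
    """Leftmost indices of local maxima, plateau-aware.

    A run of equal values is a local maximum if its value is >= both
    neighbouring run values with strict inequality on at least one side;
    missing neighbours (array ends) count as strictly lower.
    """
    n = c.size
    starts = np.flatnonzero(np.concatenate([[True], c[1:] != c[:-1]]))
    vals = c[starts]
    left = np.concatenate([[-np.inf], vals[:-1]])
    right = np.concatenate([vals[1:], [-np.inf]])
    is_max = (vals >= left) & (vals >= right) & ((vals > left) | (vals > right))
    return starts[is_max]


def find_second_peak(s: SmoothedSpectrum, ratio: float = 10.0, x: int = 4) -> PeakCall:
    """Locate the homologous peak right of the global (background) maximum.

    Among plateau-resolved local maxima at positions ``m > argmax``, keep
    those with ``N(m) <= global_max / ratio`` and ``N(m) > N(m - x)`` (the
    side constraints that reject shoulders of the background peak); return
    the highest, ties broken leftmost.  ``found=False`` when none qualifies.
    """
    c = np.asarray(s.counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty spectrum")
    g = int(np.argmax(c))
    gv = float(c[g])
    best = None
    for m in _plateau_local_maxima(c):
        m = int(m)
        if m <= g:
            continue
        if c[m] > gv / ratio:
            continue
        if m - x < 0 or not (c[m] > c[m - x]):
            continue
        if best is None or c[m] > c[best]:
            best = m
    if best is None:
        return PeakCall(False, None, g, gv)
    return PeakCall(True, best, g, gv, float(c[best]))
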