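"""Closed-form length distributions of exact and k-mismatch common substrings.

Under a gap-free Jukes-Cantor pair model, two equal-length DNA sequences of
length ``L`` match with per-site probability ``p`` at homologous positions
(``i == j``) and with a background probability ``q`` (0.25 for uniform base
composition) everywhere else.  This module provides

* the law of the longest exact match at a position (``exact_longest_pmf``),
* the law of the longest k-mismatch match (``kmismatch_longest_cdf``),
* the length law of the heuristic hit -- longest exact match plus a
  gap-free ``(k-1)``-mismatch extension (``theorem1_pmf``),
* the length law of the extension alone, a two-component negative-binomial
  mixture (``extension_pmf``) whose component modes ``m_H``/``m_B`` are given
  in closed form (``peak_positions``),
* the probability that the longest exact match at a position is the
  homologous one (``prob_homologous``),
* the Jukes-Cantor correction between match probability and substitutions
  per site.

Edge effects at sequence ends are ignored throughout: the probability of
matches of length ``m`` decays fast enough that for long sequences the
truncation error is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "ModelParams",
    "TheoreticalSpectrum",
    "PeakPositions",
    "SaturationError",
    "negbin_match_pmf",
    "exact_longest_pmf",
    "kmismatch_longest_cdf",
    "theorem1_pmf",
    "theorem1_spectrum",
    "extension_pmf",
    "extension_spectrum",
    "peak_positions",
    "prob_homologous",
    "jukes_cantor_distance",
    "jukes_cantor_match_prob",
    "estimate_background_q",
]

#: running-term threshold below which geometrically decaying sums are truncated
_SUM_TOL = 1e-15


class SaturationError(ValueError):
    """Match probability at or below 0.25: Jukes-Cantor distance undefined."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the gap-free Jukes-Cantor pair model.

    Parameters
    ----------
    p : float
        Per-site match probability at homologous positions.
    L : int
        Sequence length in nucleotides.
    k : int
        Number of mismatches allowed in an extension.
    q : float, optional
        Background per-site match probability; 0.25 under uniform base
        composition.
    """

    p: float
    L: int
    k: int
    q: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.q < self.p <= 1.0):
            raise ValueError(f"require 0 < q < p <= 1, got p={self.p}, q={self.q}")
        if self.L < 1:
            raise ValueError(f"require L >= 1, got L={self.L}")
        if not (0 <= self.k < self.L):
            raise ValueError(f"require 0 <= k < L, got k={self.k}, L={self.L}")

    @property
    def distance(self) -> float:
        """Jukes-Cantor distance corresponding to the match probability p."""
        return jukes_cantor_distance(self.p)


@dataclass
class PeakPositions:
    """Modes of the homologous (``m_H``) and background (``m_B``) components."""

    m_H: int
    m_B: int


@dataclass
class TheoreticalSpectrum:
    """Expected counts (or probabilities) per extension length m.

    ``total`` is always the element-wise sum of the ``homologous`` and
    ``background`` components.
    """

    lengths: np.ndarray
    homologous: np.ndarray
    background: np.ndarray
    total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.homologous = np.asarray(self.homologous, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.total = self.homologous + self.background

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "m": self.lengths,
                "total": self.total,
                "homologous": self.homologous,
                "background": self.background,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def negbin_match_pmf(n, match_prob: float, k: int):
    """P(longest run with exactly k mismatches at a fixed position pair = n).

    The length of the longest substring pair starting at a fixed ``(i, j)``
    with exactly ``k`` mismatches follows a negative binomial law::

        P(X = n) = C(n, k) * match_prob**(n-k) * (1 - match_prob)**(k+1)

    for ``n >= k`` and 0 otherwise.  Accepts scalar or array ``n``.
    """
    if not (0.0 < match_prob < 1.0):
        raise ValueError(f"match_prob must lie in (0, 1), got {match_prob}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    n = np.asarray(n)
    out = stats.nbinom.pmf(n - k, k + 1, 1.0 - match_prob)
    out = np.where(n < k, 0.0, out)
    return float(out) if out.ndim == 0 else out


def exact_longest_pmf(n, params: ModelParams):
    """P(longest exact match at a position = n), edge effects ignored.

    ``P(X_i < n) = (1 - q**n)**(L - n) * (1 - p**n)``; the pmf is the first
    difference of this cdf.
    """
    n = np.asarray(n)
    out = _exact_longest_cdf(n + 1, params) - _exact_longest_cdf(n, params)
    return float(out) if out.ndim == 0 else out


def _exact_longest_cdf(n, params: ModelParams):
    n = np.asarray(n, dtype=float)
    p, q, L = params.p, params.q, params.L
    cdf = (1.0 - q**n) ** (L - n) * (1.0 - p**n)
    return np.where(n > L, 1.0, cdf)


def kmismatch_longest_cdf(n, params: ModelParams):
    """P(longest k-mismatch match at a position < n), edge effects ignored.

    For ``n > k``::

        P(X_i^(k) < n) = (1 - S_q(n))**(L-n) * (1 - S_p(n))

    where ``S_x(n) = sum_{k' <= k} C(n, k') x**(n-k') (1-x)**k'`` is the
    probability that a fixed position pair matches over ``n`` sites with at
    most ``k`` mismatches.  Returns 0 for ``n <= k`` and 1 for ``n > L``.
    """
    n = np.asarray(n)
    p, q, L, k = params.p, params.q, params.L, params.k
    nf = n.astype(float)
    # S_x(n) = P(Binom(n, 1-x) <= k)
    s_q = stats.binom.cdf(k, n, 1.0 - q)
    s_p = stats.binom.cdf(k, n, 1.0 - p)
    cdf = (1.0 - s_q) ** (L - nf) * (1.0 - s_p)
    cdf = np.where(n <= k, 0.0, cdf)
    cdf = np.where(n > L, 1.0, cdf)
    return float(cdf) if cdf.ndim == 0 else cdf


def kmismatch_longest_pmf(n, params: ModelParams):
    """P(longest k-mismatch match at a position = n), via first differences."""
    n = np.asarray(n)
    out = kmismatch_longest_cdf(n + 1, params) - kmismatch_longest_cdf(n, params)
    return float(out) if out.ndim == 0 else out


def _log_binom(n, r):
    """log C(n, r); -inf where r > n or r < 0."""
    n = np.asarray(n, dtype=float)
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    return np.where((r < 0) | (r > n), -np.inf, out)


def theorem1_pmf(m, params: ModelParams):
    """Length law of the heuristic hit: exact match + (k-1)-mismatch extension.

    The hit at a position has length ``m = m1 + 1 + m2`` where ``m1`` is the
    longest exact match, one site is the first mismatch, and ``m2`` is the
    subsequent extension with exactly ``k - 1`` mismatches.  Conditioning on
    whether the partner is homologous gives the two summands::

        hom(m) = p**(m-k) (1-p)**(k+1)
                 * sum_{m1+m2=m-1} (1 - q**(m1+1))**(L-m1) C(m2, k-1)
        bg(m)  = sum_{m1+m2=m-1} [(1-q**(m1+1))**(L-m1) - (1-q**m1)**(L-m1)]
                 * (1 - p**m1) C(m2, k-1) q**(m2-k+1) (1-q)**k

    Returns ``(homologous, background)``; requires ``k >= 1``.
    """
    p, q, L, k = params.p, params.q, params.L, params.k
    if k < 1:
        raise ValueError("the heuristic-hit law requires k >= 1")
    m_arr = np.atleast_1d(np.asarray(m, dtype=np.int64))
    hom = np.zeros(m_arr.shape)
    bg = np.zeros(m_arr.shape)
    for idx, mm in enumerate(m_arr):
        if mm < k:
            continue
        m1 = np.arange(0, mm, dtype=np.int64)  # m2 = mm - 1 - m1
        m2 = mm - 1 - m1
        log_c = _log_binom(m2, k - 1)
        # probability of no background match of length > m1 anywhere
        log_no_bg = (L - m1).astype(float) * np.log1p(-(q ** (m1 + 1.0)))
        # homologous summand, fully in log space (C(m2, k-1) can overflow);
        # prefactor p**(m-k) per the product p**m1 * p**(m2-k+1) with
        # m1 + m2 = m - 1 (the only exponent that conserves total mass)
        log_pref = (mm - k) * math.log(p) + (k + 1.0) * math.log1p(-p)
        hom[idx] = math.exp(logsumexp(log_pref + log_no_bg + log_c))
        # background summand: bracketed difference kept in linear space
        with np.errstate(divide="ignore"):
            pow_hi = np.exp(log_no_bg)
            pow_lo = np.where(
                m1 == 0, 0.0, np.exp((L - m1).astype(float) * np.log1p(-(q**m1.astype(float))))
            )
        negbin = np.exp(log_c + (m2 - k + 1.0) * math.log(q) + k * math.log1p(-q))
        bg[idx] = float(np.sum((pow_hi - pow_lo) * (1.0 - p**m1.astype(float)) * negbin))
    if np.isscalar(m) or np.asarray(m).ndim == 0:
        return float(hom[0]), float(bg[0])
    return hom, bg


def theorem1_spectrum(
    params: ModelParams, lengths=None, expected_counts: bool = True
) -> TheoreticalSpectrum:
    """Heuristic-hit length spectrum over a range of lengths.

    With ``expected_counts=True`` the per-length probabilities are scaled by
    ``L`` (the expected number of hits of each length over a sequence pair).
    """
    if lengths is None:
        m_b = peak_positions(params).m_B
        lengths = np.arange(params.k, 4 * max(m_b, params.k) + 40)
    lengths = np.asarray(lengths, dtype=np.int64)
    hom, bg = theorem1_pmf(lengths, params)
    scale = float(params.L) if expected_counts else 1.0
    return TheoreticalSpectrum(lengths, scale * hom, scale * bg)


def extension_pmf(m, params: ModelParams):
    """Length law of the k-mismatch extension alone: a two-part mixture.

    ``P(ext = m) = P(j*=i) C(m,k) p**(m-k) (1-p)**(k+1)
                 + P(j*!=i) C(m,k) q**(m-k) (1-q)**(k+1)``

    where ``j*`` is the partner position of the longest exact match.  Returns
    the pair ``(H_k(m), B_k(m))`` of homologous and background components.
    """
    w = prob_homologous(params)
    hom = w * negbin_match_pmf(m, params.p, params.k)
    bg = (1.0 - w) * negbin_match_pmf(m, params.q, params.k)
    return hom, bg


def extension_spectrum(
    params: ModelParams, lengths=None, expected_counts: bool = True
) -> TheoreticalSpectrum:
    """Extension-length spectrum, decomposed into homologous/background parts."""
    if lengths is None:
        m_h = peak_positions(params).m_H
        lengths = np.arange(0, 2 * m_h + 10 * params.k + 40)
    lengths = np.asarray(lengths, dtype=np.int64)
    hom, bg = extension_pmf(lengths, params)
    scale = float(params.L) if expected_counts else 1.0
    return TheoreticalSpectrum(lengths, scale * hom, scale * bg)


def peak_positions(params: ModelParams) -> PeakPositions:
    """Modes of the two extension-length components, in closed form.

    The homologous component ``H_k`` increases while ``(m+1-k)/(m+1) <= p``,
    so its (leftmost) maximum sits at ``m_H = ceil(k/(1-p) - 1)``; the
    background maximum sits at ``m_B = ceil(k/(1-q) - 1)``.
    """
    p, q, k = params.p, params.q, params.k
    if k < 1:
        raise ValueError("peak positions require k >= 1")
    if p >= 1.0 or q >= 1.0:
        raise ValueError("peak position diverges as the match probability -> 1")
    return PeakPositions(m_H=_tolerant_ceil(k / (1.0 - p) - 1.0), m_B=_tolerant_ceil(k / (1.0 - q) - 1.0))


def _tolerant_ceil(x: float, eps: float = 1e-9) -> int:
    # guards against float noise pushing an exact integer ratio upwards
    return int(math.ceil(x - eps))


def prob_homologous(params: ModelParams) -> float:
    """P(j* = i): the longest exact match at a position is the homologous one.

    ``P(j* = i) = sum_{m>=1} (1 - q**m)**(L-1) p**m (1-p)``; the sum is
    truncated once the running term falls below 1e-15 (geometric decay in p
    bounds the remainder).
    """
    p, q, L = params.p, params.q, params.L
    if p >= 1.0:
        return 1.0
    # p**m (1-p) < _SUM_TOL bounds the term from above
    m_max = max(2, int(math.log(_SUM_TOL / (1.0 - p)) / math.log(p)) + 2)
    m = np.arange(1, m_max + 1, dtype=float)
    terms = (1.0 - q**m) ** (L - 1) * p**m * (1.0 - p)
    return float(terms[terms >= 0].sum())


def jukes_cantor_distance(p_hat: float) -> float:
    """Jukes-Cantor substitutions per site from a match probability.

    ``d = -(3/4) ln(1 - (4/3)(1 - p_hat))``; undefined (saturated) for
    ``p_hat <= 0.25``.
    """
    if p_hat <= 0.25:
        raise SaturationError(
            f"match probability {p_hat} <= 0.25: Jukes-Cantor distance undefined"
        )
    if p_hat > 1.0:
        raise ValueError(f"match probability must be <= 1, got {p_hat}")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * (1.0 - p_hat))


def jukes_cantor_match_prob(d: float) -> float:
    """Inverse Jukes-Cantor correction: per-site match probability at distance d."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return 1.0 - 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def estimate_background_q(freqs1, freqs2) -> float:
    """Background match probability from observed nucleotide frequencies.

    ``q = sum_b f1(b) * f2(b)`` over the four bases; equals 0.25 under
    uniform composition.
    """
    f1 = np.asarray(freqs1, dtype=float)
    f2 = np.asarray(freqs2, dtype=float)
    if f1.shape != (4,) or f2.shape != (4,):
        raise ValueError("expected two length-4 frequency vectors")
    return float(np.dot(f1, f2))
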