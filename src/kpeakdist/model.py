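"""Model/Results interface over the peak-distance pipeline.

:class:`PairDistanceModel` holds one sequence pair and the operating
parameters; ``fit()`` runs matching statistics, histogram smoothing and peak
detection, and returns a :class:`PairDistanceResults` carrying the estimate,
its Theorem-style bracket, diagnostics and a ``summary()`` table.
:class:`PairwiseDistanceModel` does the same for an all-vs-all sequence set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import estimator, io, theory
from .matchstats import SequencePair, build_esa, collect_spectrum
from .spectrum import smooth

__all__ = ["PairDistanceModel", "PairDistanceResults", "PairwiseDistanceModel", "PairwiseDistanceResults"]


class PairDistanceModel:
    """Peak-based distance estimator for one pair of DNA sequences.

    Parameters
    ----------
    s1, s2 : str
        Uppercase-normalized on input; non-ACGT characters never match.
    k : int, optional
        Mismatches allowed in extensions; defaults to a heuristic
        log-scaling of the sequence length (see :func:`estimator.default_k`).
    pool_directions : bool
        Sum the histograms with each sequence as query (default True).
    """

    def __init__(self, s1, s2, k=None, id1="seq1", id2="seq2", pool_directions=True, alphabet="dna"):
        self.pair = SequencePair(s1, s2, id1=id1, id2=id2, alphabet=alphabet)
        self.k = k if k is not None else estimator.default_k(min(len(s1), len(s2)))
        self.pool_directions = pool_directions

    @classmethod
    def from_fasta(cls, path, **kwargs):
        """Build from the first two records of a FASTA file."""
        records = io.read_fasta(path)
        if len(records) < 2:
            raise ValueError(f"{path}: need at least two records")
        (id1, s1), (id2, s2) = records[0], records[1]
        return cls(s1, s2, id1=id1, id2=id2, **kwargs)

    def fit(self, w=None, ratio=estimator.DEFAULT_RATIO, x=estimator.DEFAULT_X) -> "PairDistanceResults":
        w = w if w is not None else estimator.default_w(self.k)
        esa = build_esa(self.pair)
        spectrum = collect_spectrum(self.pair, k=self.k, pool_directions=self.pool_directions, esa=esa)
        smoothed = smooth(spectrum, w)
        est = estimator.estimate_distance(spectrum, w=w, ratio=ratio, x=x, k=self.k)
        return PairDistanceResults(self, spectrum, smoothed, est, w=w, ratio=ratio, x=x)


@dataclass
class PairDistanceResults:
    """Fitted estimate plus the spectra it was read from."""

    model: PairDistanceModel
    spectrum: object
    smoothed: object
    estimate: estimator.DistanceEstimate
    w: int
    ratio: float
    x: int

    @property
    def status(self) -> str:
        return self.estimate.status

    @property
    def p_hat(self):
        return self.estimate.p_hat

    @property
    def d_hat(self):
        return self.estimate.d_hat

    @property
    def m_star(self):
        return self.estimate.m_E

    def summary(self) -> str:
        est = self.estimate
        pair = self.model.pair
        lines = [
            "k-mismatch peak distance estimate",
            "=" * 46,
            f"sequences        {pair.id1} ({len(pair.s1)} nt) vs {pair.id2} ({len(pair.s2)} nt)",
            f"k (mismatches)   {self.model.k}",
            f"w (smoothing)    {self.w}",
            f"extensions       {self.spectrum.total}",
            f"status           {est.status}",
        ]
        if est.peak is not None:
            lines.append(f"background peak  m = {est.peak.global_max_pos} (height {est.peak.global_max_val:.1f})")
        if est.m_E is not None:
            lines.append(f"second peak      m* = {est.m_E}")
        if est.p_hat is not None:
            lines.append(f"match prob p^    {est.p_hat:.6f}  (bracket [{est.p_lower:.6f}, {est.p_upper:.6f}])")
        if est.ok:
            lines.append(f"JC distance d^   {est.d_hat:.6f} substitutions/site")
        return "\n".join(lines)

    def plot_spectrum(self, ax=None, theory_overlay: bool = False):
        """Raw and smoothed length histograms; optionally the fitted theory mixture."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.spectrum.lengths, self.spectrum.counts, lw=0.6, alpha=0.6, label="raw N(m)")
        ax.plot(self.smoothed.lengths, self.smoothed.counts, lw=1.5, label=f"smoothed (w={self.w})")
        if self.estimate.m_E is not None:
            ax.axvline(self.estimate.m_E, color="crimson", ls="--", lw=1, label=f"m* = {self.estimate.m_E}")
        if theory_overlay and self.estimate.ok:
            params = theory.ModelParams(
                p=self.estimate.p_hat, L=min(len(self.model.pair.s1), len(self.model.pair.s2)), k=self.model.k
            )
            ts = theory.extension_spectrum(params, lengths=self.spectrum.lengths)
            scale = self.spectrum.total / max(ts.total.sum(), 1e-300)
            ax.plot(ts.lengths, scale * ts.total, lw=1.0, ls=":", label="theory mixture")
        ax.set_xlabel("extension length m")
        ax.set_ylabel("count")
        ax.legend()
        return ax


class PairwiseDistanceModel:
    """All-vs-all peak-based distances for a set of labelled sequences."""

    def __init__(self, sequences, k=None, pool_directions=True, alphabet="dna"):
        self.sequences = list(sequences)
        self.k = k
        self.pool_directions = pool_directions
        self.alphabet = alphabet

    @classmethod
    def from_fasta(cls, path, **kwargs):
        return cls(io.read_fasta(path), **kwargs)

    def fit(self, w=None, ratio=estimator.DEFAULT_RATIO, x=estimator.DEFAULT_X) -> "PairwiseDistanceResults":
        run = estimator.pairwise_matrix(
            self.sequences,
            k=self.k,
            w=w,
            ratio=ratio,
            x=x,
            pool_directions=self.pool_directions,
            alphabet=self.alphabet,
        )
        return PairwiseDistanceResults(self, run.matrix, run.diagnostics)


@dataclass
class PairwiseDistanceResults:
    model: PairwiseDistanceModel
    matrix: estimator.DistanceMatrix
    diagnostics: object

    def to_phylip(self, path, **kwargs) -> None:
        self.matrix.to_phylip(path, **kwargs)

    def summary(self) -> str:
        n = len(self.matrix.labels)
        n_pairs = n * (n - 1) // 2
        lines = [
            "pairwise k-mismatch peak distances",
            "=" * 46,
            f"taxa             {n}",
            f"pairs            {n_pairs}",
            f"failed pairs     {self.matrix.n_failed}",
            "",
            self.diagnostics.to_string(index=False),
        ]
        return "\n".join(lines)
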