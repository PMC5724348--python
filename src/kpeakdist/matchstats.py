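"""Matching statistics and k-mismatch extension histograms via suffix arrays.

For every position ``i`` of a query sequence, the longest substring starting
at ``i`` that occurs anywhere in the other sequence is found with an enhanced
suffix array (suffix array + LCP array) over the concatenation of the two
sequences.  Every maximal partner position ``j*`` achieving that length is
enumerated, the gap-free extension starting one past the first mismatch is
scanned until the ``(k+1)``-st mismatch, and each distinct extension start
pair ``(i', j')`` contributes exactly one count to the length histogram.

The suffix array is built by numpy prefix doubling (O(n log n)); the LCP
array, the partner enumeration and the extension scans are numba-compiled.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SequencePair",
    "EnhancedSuffixArray",
    "ExactMatchRecord",
    "MatchLengthSpectrum",
    "build_esa",
    "longest_exact_matches",
    "k_mismatch_extension",
    "collect_spectrum",
    "sample_position_lengths",
]

_BASE_CODE = {"A": 65, "C": 67, "G": 71, "T": 84}
_MASK_BASE = 256  # first code for never-matching characters


def _encode(s1: str, s2: str, alphabet: str):
    """Integer-encode a pair of sequences.

    In ``"dna"`` mode, A/C/G/T map to fixed codes and every other character
    (N, ambiguity codes, gaps) receives a unique code so it never matches
    anything, itself included.  In ``"text"`` mode every character matches
    itself literally (used e.g. for plain-string examples).
    """
    if alphabet == "text":
        c1 = np.frombuffer(s1.encode("latin-1"), dtype=np.uint8).astype(np.int64)
        c2 = np.frombuffer(s2.encode("latin-1"), dtype=np.uint8).astype(np.int64)
        return c1, c2
    if alphabet != "dna":
        raise ValueError(f"alphabet must be 'dna' or 'text', got {alphabet!r}")
    out = []
    mask_counter = _MASK_BASE
    for s in (s1, s2):
        codes = np.frombuffer(s.encode("latin-1"), dtype=np.uint8).astype(np.int64)
        is_base = (codes == 65) | (codes == 67) | (codes == 71) | (codes == 84)
        n_mask = int((~is_base).sum())
        if n_mask:
            codes[~is_base] = np.arange(mask_counter, mask_counter + n_mask)
            mask_counter += n_mask
        out.append(codes)
    return out[0], out[1]


@dataclass
class SequencePair:
    """Two sequences to be compared, uppercase-normalized.

    ``alphabet="dna"`` masks non-ACGT characters so they never match;
    ``alphabet="text"`` compares characters literally.
    """

    s1: str
    s2: str
    id1: str = "seq1"
    id2: str = "seq2"
    alphabet: str = "dna"
    codes1: np.ndarray = field(init=False, repr=False)
    codes2: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.s1 = self.s1.upper()
        self.s2 = self.s2.upper()
        if len(self.s1) < 1 or len(self.s2) < 1:
            raise ValueError("sequences must be non-empty")
        self.codes1, self.codes2 = _encode(self.s1, self.s2, self.alphabet)

    @classmethod
    def from_codes(cls, c1: np.ndarray, c2: np.ndarray, id1="seq1", id2="seq2"):
        """Build directly from 0..3 base-code arrays (as the simulator emits)."""
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        s1 = lut[np.asarray(c1)].tobytes().decode("ascii")
        s2 = lut[np.asarray(c2)].tobytes().decode("ascii")
        return cls(s1, s2, id1=id1, id2=id2)


@dataclass
class ExactMatchRecord:
    """Longest exact match at query position ``i`` and all partner starts."""

    i: int
    length: int
    partners: list


@dataclass
class EnhancedSuffixArray:
    """Suffix array + LCP array over ``s1 <sep> s2``.

    The separator is lexicographically smaller than every sequence character
    and occurs once, so no common prefix ever spans it.  ``origin`` flags each
    text position as sequence 0, sequence 1 or separator (-1).
    """

    text: np.ndarray
    sa: np.ndarray
    lcp: np.ndarray
    rank: np.ndarray
    origin: np.ndarray
    len1: int
    len2: int

    def local_position(self, text_pos: int) -> int:
        """Map a concatenated-text position to its within-sequence position."""
        return text_pos if text_pos < self.len1 else text_pos - self.len1 - 1


def _suffix_array_doubling(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling with numpy sorts."""
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    _, rank = np.unique(codes, return_inverse=True)
    rank = rank.astype(np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - step] = rank[step:]
        sa = np.lexsort((key2, rank))
        r_sorted = rank[sa]
        k_sorted = key2[sa]
        changed = np.ones(n, dtype=np.int64)
        changed[1:] = (r_sorted[1:] != r_sorted[:-1]) | (k_sorted[1:] != k_sorted[:-1])
        new_sorted = np.cumsum(changed) - 1
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = new_sorted
        if new_sorted[-1] == n - 1:
            return sa
        step *= 2


@njit(cache=True)
def _kasai_lcp(codes, sa, rank):
    n = codes.size
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def build_esa(pair: SequencePair) -> EnhancedSuffixArray:
    """Enhanced suffix array over the concatenation ``s1 <sep> s2``."""
    c1, c2 = pair.codes1, pair.codes2
    n1, n2 = c1.size, c2.size
    text = np.concatenate([c1 + 1, np.zeros(1, dtype=np.int64), c2 + 1])
    sa = _suffix_array_doubling(text)
    rank = np.empty(text.size, dtype=np.int64)
    rank[sa] = np.arange(text.size)
    lcp = _kasai_lcp(text, sa, rank)
    origin = np.empty(text.size, dtype=np.int8)
    origin[:n1] = 0
    origin[n1] = -1
    origin[n1 + 1 :] = 1
    return EnhancedSuffixArray(text, sa, lcp, rank, origin, n1, n2)


@njit(cache=True)
def _matching_stats_ranks(sa, lcp, origin, other):
    """min-LCP to the nearest suffix of the *other* sequence, both directions.

    ``up[r]``/``down[r]`` is the minimum LCP value between rank r and the
    closest other-sequence suffix above/below, or -1 if none exists.
    """
    n = sa.size
    up = np.empty(n, dtype=np.int64)
    down = np.empty(n, dtype=np.int64)
    BIG = np.int64(1) << 60
    last = -1
    cur = BIG
    for r in range(n):
        if r > 0 and cur > lcp[r]:
            cur = lcp[r]
        up[r] = cur if last >= 0 else -1
        if origin[sa[r]] == other:
            last = r
            cur = BIG
    last = -1
    cur = BIG
    for r in range(n - 1, -1, -1):
        if r < n - 1 and cur > lcp[r + 1]:
            cur = lcp[r + 1]
        down[r] = cur if last >= 0 else -1
        if origin[sa[r]] == other:
            last = r
            cur = BIG
    return up, down


@njit(cache=True)
def _enumerate_partners(sa, lcp, origin, up, down, query, len1):
    """All (query position, partner position, match length) triples.

    Partners of a query position are every other-sequence suffix reachable in
    either suffix-array direction while the running LCP minimum stays at the
    match length X_i.  Positions with X_i == 0 contribute nothing.  Positions
    are local to their sequence; also returns X indexed by query position.
    """
    n = sa.size
    other = 1 - query
    n_query = 0
    for t in range(n):
        if origin[t] == query:
            n_query += 1
    x_by_query = np.zeros(n_query, dtype=np.int64)
    cap = 2 * n_query + 16
    qi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    cnt = 0
    for r in range(n):
        tp = sa[r]
        if origin[tp] != query:
            continue
        x = up[r]
        if down[r] > x:
            x = down[r]
        i_local = tp if query == 0 else tp - len1 - 1
        x_by_query[i_local] = x if x > 0 else 0
        if x < 1:
            continue
        # walk upwards while the running min stays at X
        cur = np.int64(1) << 60
        rr = r
        while rr > 0:
            if cur > lcp[rr]:
                cur = lcp[rr]
            if cur < x:
                break
            rr -= 1
            tq = sa[rr]
            if origin[tq] == other:
                if cnt == cap:
                    cap *= 2
                    qi2 = np.empty(cap, dtype=np.int64)
                    pj2 = np.empty(cap, dtype=np.int64)
                    qi2[:cnt] = qi
                    pj2[:cnt] = pj
                    qi = qi2
                    pj = pj2
                qi[cnt] = i_local
                pj[cnt] = tq if other == 0 else tq - len1 - 1
                cnt += 1
        # walk downwards
        cur = np.int64(1) << 60
        rr = r
        while rr < n - 1:
            if cur > lcp[rr + 1]:
                cur = lcp[rr + 1]
            if cur < x:
                break
            rr += 1
            tq = sa[rr]
            if origin[tq] == other:
                if cnt == cap:
                    cap *= 2
                    qi2 = np.empty(cap, dtype=np.int64)
                    pj2 = np.empty(cap, dtype=np.int64)
                    qi2[:cnt] = qi
                    pj2[:cnt] = pj
                    qi = qi2
                    pj = pj2
                qi[cnt] = i_local
                pj[cnt] = tq if other == 0 else tq - len1 - 1
                cnt += 1
    return x_by_query, qi[:cnt], pj[:cnt]


@njit(cache=True)
def _extension_lengths(cq, co, i_arr, j_arr, k):
    """Length of each k-mismatch extension: chars before the (k+1)-st mismatch.

    Extensions hitting a sequence end first are truncated at the observed
    length (flagged 1 in the second output).
    """
    m = i_arr.size
    out = np.empty(m, dtype=np.int64)
    trunc = np.zeros(m, dtype=np.uint8)
    nq = cq.size
    no = co.size
    for t in range(m):
        i = i_arr[t]
        j = j_arr[t]
        mism = 0
        l = 0
        hit_end = 1
        while i + l < nq and j + l < no:
            if cq[i + l] != co[j + l]:
                mism += 1
                if mism > k:
                    hit_end = 0
                    break
            l += 1
        out[t] = l
        trunc[t] = hit_end
    return out, trunc


def _partner_arrays(esa: EnhancedSuffixArray, query: int):
    up, down = _matching_stats_ranks(esa.sa, esa.lcp, esa.origin, 1 - query)
    return _enumerate_partners(esa.sa, esa.lcp, esa.origin, up, down, query, esa.len1)


def longest_exact_matches(esa: EnhancedSuffixArray, query: int = 0):
    """Per-position longest exact matches with ALL maximal partner starts.

    Returns one :class:`ExactMatchRecord` per query position, in order;
    positions whose longest match has length 0 carry an empty partner list.
    """
    x_by_query, qi, pj = _partner_arrays(esa, query)
    records = [ExactMatchRecord(i, int(x_by_query[i]), []) for i in range(x_by_query.size)]
    for i, j in zip(qi, pj):
        records[i].partners.append(int(j))
    for rec in records:
        rec.partners.sort()
    return records


def k_mismatch_extension(pair: SequencePair, i_start: int, j_start: int, k: int, query: int = 0):
    """Gap-free k-mismatch extension length from ``(i_start, j_start)``.

    Scans until just before the ``(k+1)``-st mismatch; returns
    ``(length, truncated)`` where ``truncated`` is True when a sequence end
    was reached first (out-of-bounds starts give length 0, truncated).
    """
    cq, co = (pair.codes1, pair.codes2) if query == 0 else (pair.codes2, pair.codes1)
    if i_start < 0 or j_start < 0:
        raise ValueError("extension start positions must be >= 0")
    if i_start >= cq.size or j_start >= co.size:
        return 0, True
    lengths, trunc = _extension_lengths(
        cq, co, np.array([i_start], dtype=np.int64), np.array([j_start], dtype=np.int64), k
    )
    return int(lengths[0]), bool(trunc[0])


@dataclass
class MatchLengthSpectrum:
    """Histogram N(m) of k-mismatch extension lengths for one sequence pair."""

    counts: np.ndarray
    k: int
    n_pairs_counted: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"m": self.lengths, "N": self.counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, k: int = 0):
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        m_max = int(df["m"].max())
        counts = np.zeros(m_max + 1, dtype=np.int64)
        counts[df["m"].to_numpy()] = df["N"].to_numpy()
        return cls(counts, k=k, n_pairs_counted=int(counts.sum()))


def _direction_lengths(pair: SequencePair, esa: EnhancedSuffixArray, query: int, k: int, dedup: bool):
    x_by_query, qi, pj = _partner_arrays(esa, query)
    len_other = esa.len2 if query == 0 else esa.len1
    len_query = esa.len1 if query == 0 else esa.len2
    x = x_by_query[qi]
    i_ext = qi + x + 1
    j_ext = pj + x + 1
    # a match truncated by a sequence end has no first mismatch, hence no
    # extension start; keeping these would pile an artifact spike at m=0
    in_bounds = (i_ext < len_query) & (j_ext < len_other)
    i_ext = i_ext[in_bounds]
    j_ext = j_ext[in_bounds]
    if dedup:
        keys = i_ext * np.int64(len_other + 2) + j_ext
        keys = np.unique(keys)
        i_ext = keys // (len_other + 2)
        j_ext = keys % (len_other + 2)
    cq, co = (pair.codes1, pair.codes2) if query == 0 else (pair.codes2, pair.codes1)
    lengths, _ = _extension_lengths(cq, co, i_ext, j_ext, k)
    return lengths


def collect_spectrum(
    pair: SequencePair,
    k: int,
    pool_directions: bool = True,
    dedup: bool = True,
    esa: EnhancedSuffixArray | None = None,
) -> MatchLengthSpectrum:
    """Histogram of k-mismatch extension lengths for a sequence pair.

    Every distinct extension start pair ``(i', j')`` is counted exactly once
    per query direction (``dedup=True``, the default; disabling it reproduces
    the repeat artifact of isolated spiked histogram values).  With
    ``pool_directions`` the histograms with each sequence as query are summed.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if esa is None:
        esa = build_esa(pair)
    all_lengths = [_direction_lengths(pair, esa, 0, k, dedup)]
    if pool_directions:
        all_lengths.append(_direction_lengths(pair, esa, 1, k, dedup))
    lengths = np.concatenate(all_lengths)
    counts = np.bincount(lengths) if lengths.size else np.zeros(1, dtype=np.int64)
    return MatchLengthSpectrum(counts, k=k, n_pairs_counted=int(lengths.size))


def sample_position_lengths(
    pair: SequencePair,
    positions,
    k: int,
    mode: str = "extension",
    esa: EnhancedSuffixArray | None = None,
) -> np.ndarray:
    """Per-position heuristic lengths at selected query positions of ``s1``.

    ``mode="extension"``: length of the k-mismatch extension starting one
    past the first mismatch after the longest exact match (the quantity whose
    law is the two-component negative-binomial mixture).
    ``mode="hit"``: total heuristic-hit length, longest exact match + 1 +
    the (k-1)-mismatch extension.  A single partner (the smallest start) is
    used, matching the single-j* assumption of the closed-form laws.
    Positions with no exact match return -1.
    """
    if mode not in ("extension", "hit"):
        raise ValueError("mode must be 'extension' or 'hit'")
    if esa is None:
        esa = build_esa(pair)
    x_by_query, qi, pj = _partner_arrays(esa, 0)
    first_partner = {}
    for i, j in zip(qi, pj):
        if i not in first_partner or j < first_partner[i]:
            first_partner[i] = j
    out = np.empty(len(positions), dtype=np.int64)
    k_ext = k if mode == "extension" else k - 1
    if k_ext < 0:
        raise ValueError("mode='hit' requires k >= 1")
    for t, i in enumerate(positions):
        x = int(x_by_query[i])
        if x < 1 or i not in first_partner:
            out[t] = -1
            continue
        j = first_partner[i]
        length, _ = k_mismatch_extension(pair, i + x + 1, j + x + 1, k_ext)
        out[t] = x + 1 + length if mode == "hit" else length
    return out
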