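# Methods

## Model

Two DNA sequences S1, S2 of equal length L are assumed to have diverged from
a common ancestor under a gap-free Jukes–Cantor process: substitutions are
independent across sites, all substitutions equally likely, no insertions or
deletions.  Positions i of S1 and j of S2 match with probability

* p (the *match probability*) if i = j — the positions are homologous;
* q (the *background probability*) otherwise; q = 0.25 under uniform base
  composition, and can be estimated from observed base frequencies as
  q = Σ_b f1(b)·f2(b) (`theory.estimate_background_q`).

The quantity of interest is the number of substitutions per site
d = −(3/4)·ln(1 − (4/3)(1 − p)), i.e. the Jukes–Cantor correction of 1 − p.
Edge effects at sequence ends are ignored throughout the closed-form laws;
the probability of long matches decays geometrically, so for L in the tens
of kilobases and up the truncation error is negligible.

## Length laws (`theory`)

For a fixed position pair, the longest substring pair with exactly k
mismatches has negative-binomial length law
C(n,k)·r^(n−k)·(1−r)^(k+1) with r ∈ {p, q}.  From this the module derives,
in closed form:

* the law of the longest exact match at a position, and its k-mismatch
  generalisation (cdf `(1 − S_q(n))^(L−n)·(1 − S_p(n))` with S_r the
  binomial tail; evaluated through `scipy.stats`);
* the law of the *heuristic hit* — longest exact match + first mismatch +
  (k−1)-mismatch extension — as a convolution over the split m = m1+1+m2,
  separated into homologous and background summands (`theorem1_pmf`).
  The homologous prefactor is p^(m−k)(1−p)^(k+1): this is what the term-wise
  product p^(m1)·p^(m2−k+1) with m1+m2 = m−1 gives, and the only exponent
  under which the law carries unit mass (verified numerically and by
  Monte-Carlo agreement within 3 SE per bin);
* the law of the *extension alone* (`extension_pmf`): a two-component
  negative-binomial mixture
  P(m) = P(j\*=i)·C(m,k)p^(m−k)(1−p)^(k+1) + P(j\*≠i)·C(m,k)q^(m−k)(1−q)^(k+1),
  with mixture weight P(j\*=i) = Σ_m (1−q^m)^(L−1)·p^m·(1−p)
  (`prob_homologous`; the sum is truncated when the running term drops below
  1e−15, bounded by geometric decay);
* the component modes m_H = ⌈k/(1−p) − 1⌉ and m_B = ⌈k/(1−q) − 1⌉
  (`peak_positions`).  When k/(1−r) is an exact integer the component has a
  two-point tie; the leftmost index is reported, and a 1e−9 tolerance in the
  ceiling guards against float noise flipping exact ratios.

Binomial coefficients are evaluated in log space (`gammaln`, `logsumexp`):
C(m2, k−1) alone overflows float64 long before the products do.

## Matching statistics (`matchstats`)

The suffix array of the concatenation `S1 <sep> S2` is built by numpy
prefix doubling (O(n log n); there is no suffix-array library in the
supported environment) and the LCP array by Kasai's algorithm.  The
separator is lexicographically smallest and unique, so no common prefix
spans it.  For each query suffix, the longest match in the other sequence is
the larger of the minimum-LCP values to the nearest other-sequence suffix
above and below in rank order; *all* partner positions achieving that length
are enumerated by walking outward while the running LCP minimum stays at the
match length.  The per-rank nearest-other minima are computed in two O(n)
passes; partner walks, Kasai and the extension scans are numba-compiled.

Coordinates are 0-based half-open internally; prose and reports use 1-based
positions.  Non-ACGT characters (N, ambiguity codes) receive unique codes
and therefore never match anything, themselves included, preventing spurious
matches through masked regions (`alphabet="text"` switches to literal
character comparison for non-DNA examples).  Reverse-complement matching is
out of scope.

For every query position i with match length X_i ≥ 1 and every partner j,
the extension start is (i′, j′) = (i + X_i + 1, j + X_i + 1) — one past the
first mismatch.  Each *distinct* (i′, j′) contributes exactly one count to
the histogram N(m): long shared substrings funnel many query positions to
the same extension start, and without this deduplication the histogram shows
isolated spiked values (reproduced as a regression test).  Two boundary
rules:

* a match truncated by a *sequence end* has no first mismatch and therefore
  no extension; such pairs are dropped (the short suffixes at the last few
  query positions otherwise contribute ~L/4 spurious zero-length counts —
  an artifact spike at m = 0 that can exceed the background peak);
* an extension that reaches a sequence end before its (k+1)-st mismatch is
  counted at its observed (truncated) length; for L ≫ m the bias is
  negligible.

Both query directions are computed and the two deduplicated histograms are
summed by default (`pool_directions=False` disables this), doubling the
signal available to peak detection without affecting peak positions.

## Peak detection and estimation (`spectrum`, `estimator`)

The raw histogram is smoothed with a centered moving average of odd width w;
at array boundaries the window shrinks symmetrically to the available
support (so a constant array is unchanged and w = 1 is the identity).
Histograms are right-padded with w zero bins before smoothing; since the
bins below m = k are empty as well, total mass is conserved in practice.
A strict mass-conservation identity holds whenever the nonzero support sits
at least w−1 bins from the array ends.

The homologous peak is searched for strictly right of the global maximum
(the background peak always lies left of the homologous one whenever p > q).
Among plateau-resolved local maxima (value ≥ both neighbours, strictly
greater on at least one side; plateaus resolved to their leftmost index),
a candidate m\* must satisfy two side constraints: N(m\*) ≤ global_max/ratio
(default ratio = 10) and N(m\*) > N(m\* − x) (default x = 4) — both reject
small side bumps on the background peak's shoulder.  The highest qualifying
candidate wins, ties broken leftmost.  No candidate ⇒ `no_peak`: a valid
outcome for distant pairs whose peaks have merged.

A called peak position m\* inverts to p̂ = (m\*+1−k)/(m\*+1), with the
bracket (m\*−k)/m\* ≤ p ≤ (m\*+1−k)/(m\*+1) reported alongside.  p̂ ≤ 0.25
is below Jukes–Cantor saturation and yields status `saturated` (never hit
under realistic conditions, but defined).  A peak left of k is impossible
for a k-mismatch extension mode and is treated as `no_peak`.

## Parameter choice

* **k** — peak separation m_H − m_B = k·(1/(1−p) − 1/(1−q)) grows linearly
  in k while peak widths grow as √k, so larger k separates better; the cost
  is longer extensions (runtime ∝ k) and, on real sequences with indels,
  a higher chance of mixed homologous/background segments.  The operating
  point k = 90 for 500 kb sequences is robust (estimates stable across
  k = 70…200).  The default for other lengths scales k with log L anchored
  at that point (`default_k`), clamped to ≥ 10 — a heuristic, clearly
  labelled as such.  A *linear* rescaling of k with L was measured to fail:
  at L = 100 kb and k = 18 the homologous peak merges into the background
  tail for d ≥ 0.6, while k ≈ 80–90 recovers d = 0.2…0.8 within ~2%.
* **w** — the window must be wide enough to suppress Poisson noise (w = 1
  finds noise maxima several bins off) but narrower than the homologous
  peak, which is swallowed when w greatly exceeds the peak width (w = 51 at
  k = 90 reproducibly loses the peak).  Default: nearest odd integer to
  k/3, matching the w = 31 operating point at k = 90 and scaling with the
  √k peak width.
* **ratio = 10, x = 4** — the published side-constraint values; they matter
  only near failure boundaries.

## Simulator (`simulate`)

A uniform-random ancestor is drawn and the full divergence applied to one
lineage (the process is reversible, so this equals splitting it): each site
is substituted with probability 1 − p, the replacement drawn uniformly from
the three other bases, making the per-site match probability exactly p and
the background rate exactly 0.25.  Replicates fold the replicate index into
a `SeedSequence` spawn key, so runs are bit-reproducible and parallel-safe.
The replicate study applies the reporting rule that mean/sd are withheld
unless ≥ 75% of replicates produced a distance.

What the simulator does *not* emulate: indels (a geometric-length indel
mode exists but is experimental and excluded from all validation), repeats,
GC skew, rate heterogeneity, rearrangements.  Passing tests therefore
demonstrate correctness *under the gap-free model the theory assumes*, not
performance on real genomes; on real data the method additionally relies on
extensions being short relative to indel-free segments.

## Problem sizes used in the test suite

Simulation-backed tests run at reduced but representative scale, chosen so
the whole suite completes in a couple of minutes while keeping every
statistical check well-powered: 5 replicate pairs of 500 kb at the k = 90
operating point; 10 replicates × 4 distances at L = 100 kb for parameter
recovery; 200 pairs of 2 kb (9 well-separated positions each) for the
Monte-Carlo checks of the closed-form laws, scored within 3 SE per bin on
all bins with expected count ≥ 10; brute-force oracles up to L = 500.

## Known limitations

* Gap-free theory: indels break the homologous/background dichotomy for
  long extensions; large k amplifies this on real sequences.
* The estimator quantises p̂ through an integer peak position; the induced
  grid on d̂ is coarser at large d (≈ 0.01–0.04 per histogram bin).
* Worst-case partner enumeration is quadratic for pathologically repetitive
  inputs (e.g. mononucleotide runs); random and real genomic sequences are
  far from this regime.
* No reverse-complement or six-frame handling; sequences are compared as
  given.
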