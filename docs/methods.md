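# Methods

## The target function

A region is the pair `A = (A_g, A_e)` of its DNA sequence and a per-base
binary epigenomic state vector (1 inside a peak of the chosen mark, 0
outside).  An alignment `α` of query `A` against target `B` is scored as

    T(α) = S(α) + w · E(α)

and the engine returns `α* = argmax_α T(α)`.

`S` is a standard pairwise sequence score: a 5×5 substitution matrix over
`{A,C,G,T,N}` plus affine gaps.  `E` sums a 2×2 state-pair matrix over
*aligned base pairs only*; gap positions contribute nothing to `E`.  This
is a deliberate modelling choice: an unaligned base has no defined
counterpart whose state could agree or disagree.

The alignment is semi-global ("glocal"): every query base is consumed
(matched or gapped), while target flanks outside the alignment are free.
The DP is the three-state Gotoh recurrence (match M, gap-in-target X,
gap-in-query Y) with row 0 of M initialised to zero (free start anywhere
in the target) and the optimum read off the last query row.  All
inter-state transitions are allowed, so a gap in one region may directly
follow a gap in the other; each maximal run of same-type gap steps is
charged `gap_open` once plus `gap_extend` per base.  Filling the three
`(m+1)×(n+1)` matrices is O(mn) time and memory; an instrumentation
counter confirms exactly `3·m·n` cell updates.  A numba-compiled kernel
computes the fill when numba is importable; a vectorised numpy row sweep
otherwise — the two produce identical optima (the traceback is shared and
tolerant of last-ulp differences between the formulations).

Traceback is deterministic: among equal-scoring end cells the smallest
target end offset wins; within a cell, tie order is MATCH >
GAP_IN_TARGET > GAP_IN_QUERY.  The reported `T` is recomputed from the
traced path (`T = S + w·E` holds exactly, not merely to tolerance); the
last-row score profile then matches `T` to 1e−9.  The degenerate optimum
that aligns the entire query to gaps (possible under extreme penalties)
consumes no target base and is reported with an empty hit
(`target_hit = None`).

## Scoring parameters

| parameter     | default | meaning                                         |
|---------------|---------|-------------------------------------------------|
| `w`           | 0.1     | epigenome weight (dimensionless); 0 = sequence only |
| `seq_match`   | +2      | score per identical aligned base pair            |
| `seq_mismatch`| −2      | score per differing pair                         |
| `gap_open`    | −4      | once per gap run                                 |
| `gap_extend`  | −1      | per gapped base                                  |
| `epi_match1`  | +2      | aligned (1,1) state pair                         |
| `epi_match0`  | +0.2    | aligned (0,0) state pair                         |
| `epi_mismatch`| −2      | aligned (1,0)/(0,1) pair                         |

`epi_match0 ≪ epi_match1` so that the ubiquitous 0–0 agreement outside
peaks cannot dominate the epigenome term.  The default `w = 0.1` sits
inside the safe range established by the decoy study (below); the study
is why weights above 0.15 are not recommended.  `N` bases score 0 against
everything — ambiguity creates no signal in either direction.

Instead of flat match/mismatch scores, the substitution matrix may be
derived from an F81-style substitution process (the substitution side of
the TKF91 evolutionary model): `P_t(b|a) = e^{−rt}δ_ab + (1−e^{−rt})π_b`,
scored as the log-odds `log(P_t(b|a)/π_b)`.  The matrix is exactly
symmetric for any stationary distribution, its diagonal decreases
monotonically with divergence time, and all entries vanish as `rt → ∞`.
The TKF91 birth–death gap process is *not* carried over into the gap
scores: `gap_open`/`gap_extend` remain direct parameters, because a
principled mapping from (λ, μ, t) to affine penalties involves modelling
choices orthogonal to this package's purpose.  No parameter estimation
from data is attempted.

## Evaluation metrics

**Calibration.** All reported scores are also given per kilobase:
`score × 1000 / query_length`.  The query length (not the aligned-column
count) is the denominator for every score of the same query, which keeps
`T` and `S` of different hits directly comparable.

**Two hits per query.**  The *epi hit* comes from the run at the
configured `w`, the *sequence-only hit* from a `w = 0` run.  `E_epi =
T_epi − S_epi` is the (weighted) epigenome contribution at the epi hit.
For the sequence-only hit, `T_seq` is obtained by re-scoring that hit's
path with the epigenome term switched on at weight `w` — not by
re-aligning — so `T_seq < S_seq` is exactly the statement "the epigenome
term is negative on the sequence-best alignment".  A badge is raised when
the two hit intervals do not overlap.  In all-against-all mode a query is
*altered* when the two hits are different regions and `T_epi > S_epi`
while `T_seq < S_seq`.

**Theoretical E range.**  For a query with `k` ones and `z` zeros, a
gap-free full-query alignment has `E` between `(k+z)·epi_mismatch` (every
state pair penalised) and `k·epi_match1 + z·epi_match0` (every pair
rewarded).  The range is reported on the unweighted `E` scale.

**Signal-to-noise ratio.**  The SNR compares a hit's sequence score with
what the query can achieve at other locations of the same target.
`n_background` (default 20) windows are sampled uniformly among positions
whose window does not overlap the hit; window length is
`max(hit_len + query_len, (target_len − hit_len)/n_background +
query_len)`, so the sample stochastically tiles the non-hit part of the
target and any true repeat of the query fits completely inside a window
regardless of phase.  Each window is aligned sequence-only and the
background statistic is the **maximum** window score — the best score
attainable elsewhere.  SNR = `S_hit / background`, sign-extended:
if no background window scores positively while the hit does, the SNR is
+∞ with an explicit flag; if the hit itself is non-positive the ratio
falls in [0, 1] (pure noise).  An SNR ≤ 1 therefore always means the
hit's sequence similarity is indistinguishable from — or worse than —
what nearby sequence offers anyway.  A mean-based background was
evaluated and rejected during design: under the default scoring, random
DNA has negative alignment-score drift, so window means are typically
non-positive and a mean-ratio degenerates for unrelated sequence pairs,
while a tandem-repeat target (where every location is equivalent and the
SNR should be 1) is systematically overestimated.  The max-of-tiling
estimator gives SNR = 1.0 exactly on tandem repeats, large/∞ on a planted
copy in random sequence, and values concentrated near 1 for unrelated
pairs.  When the ideal window does not fit beside the hit, the window
shrinks to the larger flank so the background can never degenerate to the
hit itself.

**Reference score ranges.**  For context, per-kilobase sequence-score
ranges are computed from (a) dinucleotide-shuffled copies of the query
(Eulerian-walk shuffle preserving dinucleotide counts) aligned to the
target — the "random" band — and (b) synthetic homologous copies of the
query generated at a stated substitution divergence (default 25%) — the
"homologous" band.

## Synthetic data

The generator produces what the weight-selection study needs and nothing
more real:

* **Homolog pairs.**  Query drawn i.i.d. uniform over ACGT; the
  orthologous copy applies per-base substitutions (always to a different
  base, so identity = 1 − sub_rate in expectation) and geometric-length
  indels with equal insertion/deletion probability (zero expected length
  drift).  Realized identity counts query bases copied unchanged.
* **Decoy triplets.**  Target = random flank + orthologous copy + random
  flank.  States: query all 1, orthologous span all 0, and a decoy span
  of query length — placed uniformly in the flanks, never overlapping the
  orthologue — all 1.  The decoy's sequence is a copy of the query
  randomised to a chosen expected identity; the default 0.25 makes it
  statistically indistinguishable from random sequence, i.e. a pure
  "random peak".  Decoy length equals the query signal length so the two
  candidate explanations are comparable.
* **Weight sweep.**  Per-region substitution rates drawn uniformly from
  [0, 0.4] spread identities over 0.6–1.0.  For each `w` in the grid the
  query is aligned to the full target and classified *misaligned* when
  the hit overlaps the decoy span more than the orthologous span
  (majority-overlap rule — "the decoy was identified as the best hit"
  needs an overlap criterion, and majority overlap is symmetric and
  directly testable).  `S_ortho`/`S_decoy` are the `w = 0` scores of the
  query against each span alone.

What the generator does **not** emulate: real genomic base composition
and repeat structure, mark-specific peak geometry, liftOver failures, or
biological covariation between conservation and peak retention.  Passing
tests on this synthetic cohort establish the causal mechanics of the
method (the decoy's epigenome bonus grows linearly in `w` while the
orthologue's penalty grows, so takeover order follows sequence
conservation) — not performance on real chromatin data.

Study sizes used by the test suite and the acceptance script: 200 decoy
triplets of 500 bp queries with 600 bp flanks over a 31-point weight grid
(0 and 0.01–0.30); 200 random instances (query ≤ 6 bp, target ≤ 10 bp)
for the exhaustive-oracle comparison; 100 random pairs of 25 bp queries
vs 8 kb targets for the SNR noise regime.  The random-pair SNR sizes were
fixed at design time: short queries keep chance alignment scores positive
(a maximum over many placements), which is the regime where a
ratio-of-scores SNR is informative at all.

## Numerical and interface choices

* Scores accumulate in double precision; exactness assertions use 1e−9.
* Coordinates are 0-based half-open (BED) everywhere internally.
* Minus-strand regions hold the reverse-complemented sequence, and their
  state vectors are reversed to match — sequence and states always share
  an orientation.
* Overlapping peaks are merged before annotation (binary states make
  multiplicity meaningless); peak files may be BED3 or wider (narrowPeak
  columns beyond the first six are ignored).
* One-vs-one pairing is strictly line-by-line; a count mismatch is a hard
  error (CLI exit code 3).
* Best-hit ties in all-against-all mode go to the first target in input
  order; traceback ties follow the fixed step-type order above.  Both
  rules exist purely for determinism.
* Every stochastic component (SNR backgrounds, generators, sweeps) takes
  an explicit seed, and run manifests record all parameters, so any run
  is reproducible bit-for-bit.

## Limitations

* No genome-wide search: the engine aligns a query against a designated
  target region, not a chromosome.
* One epigenomic mark at a time; no peak significance weighting — a peak
  is a peak.
* No homology remapping (users supply target coordinates), no reverse-
  complement search (regions are aligned as strand-resolved at
  extraction), no expression panels or genome-browser integration.
* The TKF91-derived mode covers substitutions only; gap scores are
  user-set parameters, not derived from the indel process.
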