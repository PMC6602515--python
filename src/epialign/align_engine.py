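"""Semi-global dynamic program over sequence + epigenome scores.

The engine aligns a query region *globally* (every query base is consumed)
against a target region whose flanks are free: unaligned target prefix and
suffix cost nothing, so the alignment picks out the contiguous target
sub-interval that maximises

    T(alpha) = S(alpha) + w * E(alpha).

``S`` accumulates substitution scores plus affine gap penalties
(``gap_open`` once per gap run, ``gap_extend`` per gapped base); ``E``
accumulates state-pair scores over *aligned* base pairs only — gaps carry
no epigenome term.  The recurrence is the standard three-state Gotoh
scheme (match / gap-in-target / gap-in-query) with all inter-state
transitions allowed, filled row by row in O(m*n) time.

Traceback is deterministic: among equal-scoring end cells the smallest
target end offset wins, and ties between step types are broken in the
order MATCH > GAP_IN_TARGET > GAP_IN_QUERY.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .core_scoring import (
    EpiRegion,
    GenomicInterval,
    ScoreTables,
    encode_sequence,
)

# Step labels: MATCH consumes one base of each region, GAP_IN_TARGET
# consumes a query base (aligned to a gap), GAP_IN_QUERY consumes a
# target base (aligned to a gap).
MATCH = "M"
GAP_IN_TARGET = "GT"
GAP_IN_QUERY = "GQ"

#: A step is (op, query_index, target_index); the index not consumed is None.
Step = Tuple[str, Optional[int], Optional[int]]

_NEG = -np.inf


class AlignmentInputError(ValueError):
    """Raised for empty or inconsistent alignment inputs."""


@dataclass
class Alignment:
    """An alignment path with its score decomposition.

    ``T = S + w * E`` holds exactly (to float round-off); ``E`` is the
    unweighted epigenome sum over aligned pairs.  ``target_hit`` is the
    genomic sub-interval of the target spanned by the path, or None for
    the degenerate all-gap alignment that consumes no target base.
    """

    path: List[Step]
    T: float
    S: float
    E: float
    w: float
    target_hit: Optional[GenomicInterval]
    target_start_offset: int
    target_end_offset: int


@dataclass
class ScoreProfile:
    """Best alignment score as a function of target end offset."""

    positions: np.ndarray
    scores: np.ndarray


class CellCounter:
    """Counts DP cell updates, for complexity instrumentation."""

    def __init__(self) -> None:
        self.cells = 0


def _pair_scores(query: EpiRegion, target: EpiRegion, tables: ScoreTables) -> np.ndarray:
    """m x n matrix of per-aligned-pair scores sub + w*epi."""
    qi = encode_sequence(query.seq)
    ti = encode_sequence(target.seq)
    qs = query.states.astype(np.intp)
    ts = target.states.astype(np.intp)
    seq_part = tables.sub[np.ix_(qi, ti)]
    epi_part = tables.epi[np.ix_(qs, ts)]
    return seq_part + tables.w * epi_part


try:  # optional JIT acceleration of the row fill
    from numba import njit as _njit

    @_njit(cache=True)
    def _fill_kernel(qi, ti, qs, ts, sub, epi, w, go, ge):  # pragma: no cover
        m, n = qi.shape[0], ti.shape[0]
        NEG = -np.inf
        M = np.full((m + 1, n + 1), NEG)
        X = np.full((m + 1, n + 1), NEG)
        Y = np.full((m + 1, n + 1), NEG)
        for j in range(n + 1):
            M[0, j] = 0.0
        for i in range(1, m + 1):
            a = M[i - 1, 0] + go + ge
            b = X[i - 1, 0] + ge
            c = Y[i - 1, 0] + go + ge
            best = a if a > b else b
            if c > best:
                best = c
            X[i, 0] = best
            for j in range(1, n + 1):
                # match state
                a, b, c = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
                best = a if a > b else b
                if c > best:
                    best = c
                pair_score = (
                    sub[qi[i - 1], ti[j - 1]] + w * epi[qs[i - 1], ts[j - 1]]
                )
                M[i, j] = pair_score + best
                # gap in target (consumes query base)
                a = M[i - 1, j] + go + ge
                b = X[i - 1, j] + ge
                c = Y[i - 1, j] + go + ge
                best = a if a > b else b
                if c > best:
                    best = c
                X[i, j] = best
                # gap in query (consumes target base)
                a = M[i, j - 1] + go + ge
                b = X[i, j - 1] + go + ge
                c = Y[i, j - 1] + ge
                best = a if a > b else b
                if c > best:
                    best = c
                Y[i, j] = best
        return M, X, Y

except ImportError:  # pragma: no cover
    _fill_kernel = None


def _fill_matrices(
    query: EpiRegion,
    target: EpiRegion,
    tables: ScoreTables,
    counter: Optional[CellCounter] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three DP state matrices row by row.

    M[i][j]: best score of a path ending with MATCH of query i-1 / target j-1.
    X[i][j]: ending with GAP_IN_TARGET consuming query i-1.
    Y[i][j]: ending with GAP_IN_QUERY consuming target j-1.
    Row 0 of M is 0: alignments may start at any target offset for free.
    """
    if counter is not None:
        counter.cells += 3 * len(query) * len(target)
    if _fill_kernel is not None:
        return _fill_kernel(
            encode_sequence(query.seq),
            encode_sequence(target.seq),
            query.states.astype(np.int8),
            target.states.astype(np.int8),
            tables.sub,
            tables.epi,
            float(tables.w),
            float(tables.gap_open),
            float(tables.gap_extend),
        )
    pair = _pair_scores(query, target, tables)
    return _fill_matrices_numpy(pair, tables.gap_open, tables.gap_extend)


def _fill_matrices_numpy(
    pair: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised row-sweep fill, used when no JIT compiler is available."""
    m, n = pair.shape
    go, ge = gap_open, gap_extend
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)
    Y = np.full((m + 1, n + 1), _NEG)
    M[0, :] = 0.0

    j_idx = np.arange(1, n + 1, dtype=float)
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = pair[i - 1] + prev_best[:-1]
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) + go + ge,
            X[i - 1] + ge,
        )
        # Y chains within the row: Y[i][j] = max(B[j-1]+go+ge, Y[i][j-1]+ge)
        # with B = max(M, X); unrolled with a running maximum so the row
        # update stays vectorised.
        B = np.maximum(M[i], X[i])
        c = B[:-1] + go - ge * np.arange(n, dtype=float)
        Y[i, 1:] = ge * (j_idx) + np.maximum.accumulate(c)
        Y[i, 0] = _NEG
    return M, X, Y


def _argmax3(a: float, b: float, c: float) -> int:
    # ties resolved in state order M > GAP_IN_TARGET > GAP_IN_QUERY
    if a >= b:
        return 0 if a >= c else 2
    return 1 if b >= c else 2


def _traceback(
    M: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> Tuple[List[Step], int, int, float]:
    """Recover the optimal path; returns (steps, start_offset, end_offset, T)."""
    m, n = M.shape[0] - 1, M.shape[1] - 1
    go, ge = gap_open, gap_extend
    last = np.vstack([M[m], X[m], Y[m]])
    profile = last.max(axis=0)
    best = profile.max()
    j = int(np.argmax(profile == best))  # smallest end offset among ties
    # step-type preference M > X > GQ at the end cell
    state = int(np.argmax(last[:, j] == last[:, j].max()))
    end_offset = j
    steps: List[Step] = []
    i = m
    while not (state == 0 and i == 0):
        if state == 0:  # MATCH consuming query i-1, target j-1
            steps.append((MATCH, i - 1, j - 1))
            state = _argmax3(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i -= 1
            j -= 1
        elif state == 1:  # GAP_IN_TARGET consuming query i-1
            steps.append((GAP_IN_TARGET, i - 1, None))
            state = _argmax3(
                M[i - 1, j] + go + ge, X[i - 1, j] + ge, Y[i - 1, j] + go + ge
            )
            i -= 1
        else:  # GAP_IN_QUERY consuming target j-1
            steps.append((GAP_IN_QUERY, None, j - 1))
            state = _argmax3(
                M[i, j - 1] + go + ge, X[i, j - 1] + go + ge, Y[i, j - 1] + ge
            )
            j -= 1
    steps.reverse()
    return steps, j, end_offset, float(best)


def score_path(
    path: List[Step],
    query: EpiRegion,
    target: EpiRegion,
    tables: ScoreTables,
) -> Tuple[float, float]:
    """Independently re-score an alignment path; returns (S, E).

    Walks the step list accumulating substitution and affine-gap terms
    into S and state-pair terms into E.  A gap run is a maximal stretch
    of consecutive gap steps of the same type; each run is charged
    ``gap_open`` once plus ``gap_extend`` per base.
    """
    qi = encode_sequence(query.seq)
    ti = encode_sequence(target.seq)
    S = 0.0
    E = 0.0
    prev_op: Optional[str] = None
    for op, i, j in path:
        if op == MATCH:
            if not (0 <= i < len(qi) and 0 <= j < len(ti)):  # type: ignore[operator]
                raise ValueError(f"path step ({op},{i},{j}) out of range")
            S += tables.sub[qi[i], ti[j]]
            E += tables.epi[query.states[i], target.states[j]]
        elif op in (GAP_IN_TARGET, GAP_IN_QUERY):
            idx, bound = (i, len(qi)) if op == GAP_IN_TARGET else (j, len(ti))
            if not (0 <= idx < bound):  # type: ignore[operator]
                raise ValueError(f"path step ({op},{i},{j}) out of range")
            if op != prev_op:
                S += tables.gap_open
            S += tables.gap_extend
        else:
            raise ValueError(f"unknown step type {op!r}")
        prev_op = op
    return S, E


def decompose(
    alignment: Alignment,
    query: EpiRegion,
    target: EpiRegion,
    tables: ScoreTables,
) -> Tuple[float, float]:
    """Re-derive the (S, E) decomposition of an alignment from its path."""
    return score_path(alignment.path, query, target, tables)


def epialign(
    query: EpiRegion,
    target: EpiRegion,
    tables: ScoreTables,
    counter: Optional[CellCounter] = None,
) -> Tuple[Alignment, ScoreProfile]:
    """Align ``query`` semi-globally against ``target``.

    Returns the maximal-T alignment together with the last-row score
    profile (best score over alignments ending at each target offset).
    """
    if len(query) == 0 or len(target) == 0:
        raise AlignmentInputError("query and target must be non-empty")
    M, X, Y = _fill_matrices(query, target, tables, counter)
    steps, start, end, _ = _traceback(M, X, Y, tables.gap_open, tables.gap_extend)
    S, E = score_path(steps, query, target, tables)
    T = S + tables.w * E  # exact by construction; equals the DP optimum
    t_iv = target.interval
    if end > start:
        hit = GenomicInterval(
            chrom=t_iv.chrom,
            start=t_iv.start + start,
            end=t_iv.start + end,
            strand=t_iv.strand,
            name=f"{query.interval.name}_hit",
        )
    else:
        hit = None
    m, n = len(query), len(target)
    profile_scores = np.max(np.vstack([M[m], X[m], Y[m]]), axis=0)
    profile = ScoreProfile(positions=np.arange(n + 1), scores=profile_scores)
    aln = Alignment(
        path=steps,
        T=T,
        S=S,
        E=E,
        w=tables.w,
        target_hit=hit,
        target_start_offset=start,
        target_end_offset=end,
    )
    return aln, profile


# --------------------------------------------------------------------------
# Exhaustive oracle (tests only)

_BF_MAX_QUERY = 8
_BF_MAX_TARGET = 12


def brute_force_align(
    query: EpiRegion,
    target: EpiRegion,
    tables: ScoreTables,
) -> Alignment:
    """Exhaustively enumerate semi-global paths; return the max-T alignment.

    A verification oracle for small inputs (query <= 8, target <= 12
    bases): every monotone path consuming the whole query is generated
    recursively and scored by :func:`score_path`.  Leading and trailing
    gap-in-query steps are omitted — with strictly negative gap-extend
    scores they strictly lower T, so the maximum is unaffected.
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        raise AlignmentInputError("query and target must be non-empty")
    if m > _BF_MAX_QUERY or n > _BF_MAX_TARGET:
        raise ValueError(
            f"brute_force_align limited to query <= {_BF_MAX_QUERY}, "
            f"target <= {_BF_MAX_TARGET} (got {m}, {n})"
        )

    qi = encode_sequence(query.seq)
    ti = encode_sequence(target.seq)
    sub, epi, w = tables.sub, tables.epi, tables.w
    go, ge = tables.gap_open, tables.gap_extend
    qs, ts = query.states, target.states

    best: List = [None, -np.inf, 0, 0]  # path, T, start, end

    # T is accumulated incrementally along the recursion; score_path is
    # still used below to produce the reported S/E decomposition.
    def recurse(i: int, j: int, start: int, path: List[Step], T: float) -> None:
        if i == m:
            if T > best[1] + 1e-15:
                best[0] = list(path)
                best[1] = T
                best[2] = start
                best[3] = j
            return
        prev = path[-1][0] if path else None
        if j < n:
            path.append((MATCH, i, j))
            dT = sub[qi[i], ti[j]] + w * epi[qs[i], ts[j]]
            recurse(i + 1, j + 1, start, path, T + dT)
            path.pop()
        path.append((GAP_IN_TARGET, i, None))
        dT = ge + (go if prev != GAP_IN_TARGET else 0.0)
        recurse(i + 1, j, start, path, T + dT)
        path.pop()
        if j < n and path:
            path.append((GAP_IN_QUERY, None, j))
            dT = ge + (go if prev != GAP_IN_QUERY else 0.0)
            recurse(i, j + 1, start, path, T + dT)
            path.pop()

    for s in range(n + 1):
        recurse(0, s, s, [], 0.0)

    path, _, start, end = best
    S, E = score_path(path, query, target, tables)
    T = S + tables.w * E
    t_iv = target.interval
    hit = (
        GenomicInterval(
            chrom=t_iv.chrom,
            start=t_iv.start + start,
            end=t_iv.start + end,
            strand=t_iv.strand,
            name=f"{query.interval.name}_hit",
        )
        if end > start
        else None
    )
    return Alignment(
        path=path,
        T=float(T),
        S=float(S),
        E=float(E),
        w=tables.w,
        target_hit=hit,
        target_start_offset=start,
        target_end_offset=end,
    )
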