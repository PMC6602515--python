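"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pytest

from epialign import (
    EpiRegion,
    GenomicInterval,
    ScoringParams,
    build_score_tables,
)
from epialign.align_engine import GAP_IN_QUERY, GAP_IN_TARGET, MATCH, Step

BASES = np.array(list("ACGT"))


def random_region(
    rng: np.random.Generator,
    length: int,
    chrom: str = "chr_test",
    states: Optional[np.ndarray] = None,
    start: int = 0,
) -> EpiRegion:
    seq = "".join(rng.choice(BASES, size=length))
    if states is None:
        states = rng.integers(0, 2, size=length)
    return EpiRegion(
        GenomicInterval(chrom, start, start + length, "+", "r"), seq, np.asarray(states)
    )


def random_params(rng: np.random.Generator) -> ScoringParams:
    return ScoringParams(
        w=float(rng.uniform(0, 0.5)),
        seq_match=float(rng.uniform(0.5, 3)),
        seq_mismatch=float(-rng.uniform(0.5, 3)),
        gap_open=float(-rng.uniform(0, 4)),
        gap_extend=float(-rng.uniform(0.1, 2)),
        epi_match1=float(rng.uniform(0.5, 3)),
        epi_match0=float(rng.uniform(0.05, 1)),
        epi_mismatch=float(-rng.uniform(0.5, 3)),
    )


def mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute bases (always to a different one) at rate 1 - identity."""
    out = []
    for b in seq:
        if rng.random() < 1.0 - identity:
            out.append(rng.choice([c for c in "ACGT" if c != b]))
        else:
            out.append(b)
    return "".join(out)


def sequence_only_dp(query: EpiRegion, target: EpiRegion, tables) -> float:
    """Independent semi-global sequence-only DP (scores only).

    Plain-python three-state recurrence over substitution and affine gap
    scores, ignoring epigenome states entirely; used as the oracle for
    the w = 0 reduction.
    """
    from epialign import encode_sequence

    qi = encode_sequence(query.seq)
    ti = encode_sequence(target.seq)
    sub = tables.sub
    go, ge = tables.gap_open, tables.gap_extend
    m, n = len(qi), len(ti)
    NEG = float("-inf")
    M = [0.0] * (n + 1)
    X = [NEG] * (n + 1)
    Y = [NEG] * (n + 1)
    for i in range(1, m + 1):
        pM, pX, pY = M, X, Y
        M = [NEG] * (n + 1)
        X = [NEG] * (n + 1)
        Y = [NEG] * (n + 1)
        X[0] = max(pM[0] + go + ge, pX[0] + ge, pY[0] + go + ge)
        for j in range(1, n + 1):
            M[j] = sub[qi[i - 1], ti[j - 1]] + max(pM[j - 1], pX[j - 1], pY[j - 1])
            X[j] = max(pM[j] + go + ge, pX[j] + ge, pY[j] + go + ge)
            Y[j] = max(M[j - 1] + go + ge, X[j - 1] + go + ge, Y[j - 1] + ge)
    return max(max(M), max(X), max(Y))


def naive_path_scores(
    path: List[Step], query: EpiRegion, target: EpiRegion, tables
) -> Tuple[float, float]:
    """Second, independent path re-scorer (oracle for decompose)."""
    from epialign import encode_sequence

    qi = encode_sequence(query.seq)
    ti = encode_sequence(target.seq)
    S = 0.0
    E = 0.0
    runs: List[str] = []
    for op, i, j in path:
        if op == MATCH:
            S += tables.sub[qi[i], ti[j]]
            E += tables.epi[query.states[i], target.states[j]]
            runs.append("m")
        elif op == GAP_IN_TARGET:
            runs.append("x")
        elif op == GAP_IN_QUERY:
            runs.append("y")
    # gap runs from the op string
    ops = "".join(runs)
    import re

    for kind in ("x", "y"):
        for run in re.findall(f"{kind}+", ops):
            S += tables.gap_open + len(run) * tables.gap_extend
    return S, E


def make_hit_shift_fixture(
    seed: int,
    high_identity: float = 0.95,
    moderate_identity: float = 0.85,
    length: int = 200,
    flank: int = 150,
    spacer: int = 150,
):
    """Target with a conserved signal-free locus A and a diverged signal
    locus B; the query carries signal everywhere.

    Returns (query, target, span_a, span_b) with spans as (start, end)
    offsets within the target.
    """
    rng = np.random.default_rng(seed)
    qseq = "".join(rng.choice(BASES, size=length))
    locus_a = mutate_to_identity(qseq, high_identity, rng)
    locus_b = mutate_to_identity(qseq, moderate_identity, rng)
    f1 = "".join(rng.choice(BASES, size=flank))
    sp = "".join(rng.choice(BASES, size=spacer))
    f2 = "".join(rng.choice(BASES, size=flank))
    tseq = f1 + locus_a + sp + locus_b + f2
    states = np.zeros(len(tseq), dtype=np.int8)
    b0 = flank + length + spacer
    states[b0 : b0 + length] = 1
    query = EpiRegion(
        GenomicInterval("q", 0, length, "+", "query"), qseq, np.ones(length, dtype=np.int8)
    )
    target = EpiRegion(GenomicInterval("t", 0, len(tseq), "+", "target"), tseq, states)
    return query, target, (flank, flank + length), (b0, b0 + length)


def span_overlap(hit, span: Tuple[int, int]) -> int:
    if hit is None:
        return 0
    return max(0, min(hit.end, span[1]) - max(hit.start, span[0]))


@pytest.fixture
def default_params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture
def default_tables(default_params):
    return build_score_tables(default_params)
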