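"""Synthetic homolog pairs, decoy triplets and the weight-selection sweep.

The generator emulates the causal structure of the weight-selection
study: a query region carrying a real epigenomic signal (states all 1)
whose orthologous counterpart in the target has lost the signal (states
all 0), plus a planted "decoy" — a random peak (states all 1) over
unrelated sequence at a random nearby location.  Sweeping the epigenome
weight w then measures when the decoy overtakes the true orthologue as
the best hit ("misalignment"), as a function of how conserved the
orthologous sequence is.

Every generator output is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align_engine import Alignment, epialign
from .core_scoring import (
    EpiRegion,
    GenomicInterval,
    ParameterError,
    ScoringParams,
    build_score_tables,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class HomologSimParams:
    """Parameters of the divergent-homolog generator.

    length            query length in bp
    sub_rate          per-base substitution probability (to a different base)
    indel_rate        per-base probability of initiating an indel
    indel_len_geom_p  geometric length parameter (mean length 1/p)
    flank             target extension in bp on each side of the orthologue
    seed              RNG seed
    """

    length: int
    sub_rate: float = 0.1
    indel_rate: float = 0.005
    indel_len_geom_p: float = 0.5
    flank: int = 600
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0 or self.flank <= 0:
            raise ParameterError("length and flank must be > 0")
        for name in ("sub_rate", "indel_rate", "indel_len_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1] (got {v})")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _substitute(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def generate_homolog_pair(params: HomologSimParams) -> Tuple[str, str, float]:
    """Generate (query, target_core, identity).

    The query is i.i.d. uniform over ACGT; the target core applies
    per-base substitutions (always to a different base) and
    geometric-length insertions/deletions (equal probability, so length
    drift is zero in expectation).  Identity is the fraction of query
    positions copied unchanged into the core — deleted positions count
    as mismatches.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    query = _random_seq(rng, params.length)
    core, matched = _mutate_core(query, params, rng)
    return query, core, matched / params.length


@dataclass(frozen=True)
class DecoyTriplet:
    """A query with signal, its signal-free orthologue and a planted decoy."""

    query: EpiRegion
    target: EpiRegion
    ortho_span: GenomicInterval
    decoy_span: GenomicInterval
    identity: float


def make_decoy_triplet(
    params: HomologSimParams,
    decoy_identity: float = 0.25,
    decoy_offset_range: Optional[Tuple[int, int]] = None,
) -> DecoyTriplet:
    """Build one simulation unit of the weight-selection study.

    The target is random flank + mutated orthologous copy + random
    flank.  The query carries states all 1; the orthologous span carries
    states all 0; a decoy span of query length, placed uniformly in the
    flanks without overlapping the orthologue, carries states all 1.
    The decoy's sequence is a copy of the query randomised to the given
    expected identity (0.25 = indistinguishable from random sequence).

    ``decoy_offset_range`` optionally constrains the gap in bp between
    the decoy and the orthologous span; a range that would force overlap
    (negative gap) or that no placement satisfies is an error.
    """
    params.validate()
    if not 0.0 <= decoy_identity <= 1.0:
        raise ParameterError("decoy_identity must be in [0, 1]")
    rng = np.random.default_rng(params.seed)
    query_seq = _random_seq(rng, params.length)
    core, matched = _mutate_core(query_seq, params, rng)

    flank = params.flank
    left = _random_seq(rng, flank)
    right = _random_seq(rng, flank)
    target_seq = left + core + right
    n = len(target_seq)
    ortho_start, ortho_end = flank, flank + len(core)

    decoy_len = params.length
    if decoy_len > flank:
        raise ParameterError(
            f"flank ({flank}) too small for a non-overlapping decoy of "
            f"length {decoy_len}"
        )
    candidates = _decoy_starts(n, ortho_start, ortho_end, decoy_len, decoy_offset_range)
    if not candidates:
        raise ParameterError(
            "no valid decoy placement for the given offset range"
        )
    dstart = int(candidates[int(rng.integers(len(candidates)))])
    dend = dstart + decoy_len

    # decoy sequence: copy of the query randomised to the target identity
    p_mut = min(1.0, 4.0 * (1.0 - decoy_identity) / 3.0)
    decoy_seq = np.array(list(query_seq))
    mask = rng.random(decoy_len) < p_mut
    decoy_seq[mask] = rng.choice(_BASES, size=int(mask.sum()))
    target_arr = np.array(list(target_seq))
    target_arr[dstart:dend] = decoy_seq
    target_seq = "".join(target_arr)

    states = np.zeros(n, dtype=np.int8)
    states[dstart:dend] = 1

    query = EpiRegion(
        GenomicInterval("sim_q", 0, params.length, "+", "query"),
        query_seq,
        np.ones(params.length, dtype=np.int8),
    )
    target = EpiRegion(
        GenomicInterval("sim_t", 0, n, "+", "target"),
        target_seq,
        states,
    )
    return DecoyTriplet(
        query=query,
        target=target,
        ortho_span=GenomicInterval("sim_t", ortho_start, ortho_end, "+", "ortho"),
        decoy_span=GenomicInterval("sim_t", dstart, dend, "+", "decoy"),
        identity=matched / params.length,
    )


def _mutate_core(
    query_seq: str, params: HomologSimParams, rng: np.random.Generator
) -> Tuple[str, int]:
    """Apply substitutions and indels; returns (core, bases copied unchanged)."""
    out: List[str] = []
    matched = 0
    i = 0
    while i < len(query_seq):
        if params.indel_rate > 0 and rng.random() < params.indel_rate:
            length = int(rng.geometric(params.indel_len_geom_p))
            if rng.random() < 0.5:  # deletion: skip query bases
                i += length
                continue
            out.append(_random_seq(rng, length))  # insertion
        base = query_seq[i]
        if params.sub_rate > 0 and rng.random() < params.sub_rate:
            out.append(_substitute(base, rng))
        else:
            out.append(base)
            matched += 1
        i += 1
    return "".join(out), matched


def _decoy_starts(
    n: int,
    ortho_start: int,
    ortho_end: int,
    decoy_len: int,
    offset_range: Optional[Tuple[int, int]],
) -> List[int]:
    if offset_range is None:
        left = range(0, max(ortho_start - decoy_len + 1, 0))
        right = range(ortho_end, n - decoy_len + 1)
        return list(left) + list(right)
    gmin, gmax = offset_range
    if gmin < 0:
        raise ParameterError(
            f"decoy_offset_range {offset_range} would force overlap with the orthologue"
        )
    left = range(
        max(0, ortho_start - decoy_len - gmax),
        max(0, ortho_start - decoy_len - gmin + 1),
    )
    right = range(
        min(ortho_end + gmin, n),
        min(ortho_end + gmax, n - decoy_len) + 1,
    )
    return [s for s in list(left) + list(right) if 0 <= s <= n - decoy_len]


@dataclass
class WeightSweepResult:
    """Outcome of a misalignment sweep over the epigenome weight grid."""

    w_grid: np.ndarray
    misaligned_fraction: np.ndarray
    per_region: pd.DataFrame  # identity, S_ortho, S_decoy, first_misaligned_w
    misaligned: np.ndarray  # regions x weights boolean matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"w": self.w_grid, "misaligned_fraction": self.misaligned_fraction}
        )


def _span_region(target: EpiRegion, span: GenomicInterval) -> EpiRegion:
    lo = span.start - target.interval.start
    hi = span.end - target.interval.start
    return EpiRegion(span, target.seq[lo:hi], target.states[lo:hi])


def _classify_misaligned(aln: Alignment, triplet: DecoyTriplet) -> bool:
    """Majority-overlap rule: the hit counts as misaligned if it overlaps
    the decoy span more than the orthologous span."""
    hit = aln.target_hit
    if hit is None:
        return False
    return hit.overlap_length(triplet.decoy_span) > hit.overlap_length(
        triplet.ortho_span
    )


def weight_sweep(
    n_regions: int,
    params: HomologSimParams,
    w_grid: Sequence[float],
    seed: int = 0,
    sub_rate_range: Optional[Tuple[float, float]] = (0.0, 0.4),
    decoy_identity: float = 0.25,
    scoring: Optional[ScoringParams] = None,
) -> WeightSweepResult:
    """Run the decoy-misalignment study over a weight grid.

    For each of ``n_regions`` generated triplets and each w in the
    (ascending) grid, the query is aligned to the full target and
    classified as misaligned when the hit majority-overlaps the decoy.
    ``S_ortho`` and ``S_decoy`` are the sequence-only (w = 0) scores of
    the query against each span.  Per-region substitution rates are
    drawn uniformly from ``sub_rate_range`` (None: use ``params.sub_rate``
    for all), spreading conservation levels across the cohort.
    """
    w_grid = np.asarray(list(w_grid), dtype=float)
    if n_regions < 1:
        raise ParameterError("n_regions must be >= 1")
    if len(w_grid) == 0 or np.any(np.diff(w_grid) < 0):
        raise ParameterError("w_grid must be non-empty and sorted ascending")
    base_scoring = scoring if scoring is not None else ScoringParams()
    tables0 = build_score_tables(base_scoring).with_weight(0.0)

    rng = np.random.default_rng(seed)
    records = []
    mis = np.zeros((n_regions, len(w_grid)), dtype=bool)
    for r in range(n_regions):
        sub_rate = (
            float(rng.uniform(*sub_rate_range))
            if sub_rate_range is not None
            else params.sub_rate
        )
        region_params = replace(
            params, sub_rate=sub_rate, seed=int(rng.integers(2**31 - 1))
        )
        triplet = make_decoy_triplet(region_params, decoy_identity=decoy_identity)

        s_ortho = epialign(
            triplet.query, _span_region(triplet.target, triplet.ortho_span), tables0
        )[0].S
        s_decoy = epialign(
            triplet.query, _span_region(triplet.target, triplet.decoy_span), tables0
        )[0].S

        first_w = np.nan
        for wi, w in enumerate(w_grid):
            tables = build_score_tables(base_scoring.with_weight(float(w)))
            aln, _ = epialign(triplet.query, triplet.target, tables)
            mis[r, wi] = _classify_misaligned(aln, triplet)
            if mis[r, wi] and np.isnan(first_w):
                first_w = float(w)
        records.append(
            {
                "region": r,
                "identity": triplet.identity,
                "sub_rate": sub_rate,
                "S_ortho": s_ortho,
                "S_decoy": s_decoy,
                "first_misaligned_w": first_w,
            }
        )
    return WeightSweepResult(
        w_grid=w_grid,
        misaligned_fraction=mis.mean(axis=0),
        per_region=pd.DataFrame(records),
        misaligned=mis,
    )
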