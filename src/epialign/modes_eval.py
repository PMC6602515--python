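"""Alignment modes and result-evaluation metrics.

Orchestrates the two modes a user runs — one-vs-one (paired query/target
regions) and many-vs-many (all-against-all) — and computes everything the
result tables carry: per-kilobase calibrated scores, signal-to-noise
ratios, the theoretical epigenome-score range, the hit-overlap badge and
the altered-hit classification.

Score vocabulary.  Each query is aligned twice: once with the configured
epigenome weight (w > 0), once with w = 0 (sequence only).  The best
matches are the *epi hit* and the *sequence-only hit*; their scores are

    T_epi, S_epi   total and sequence component at the epi hit
    E_epi          = T_epi - S_epi, the (weighted) epigenome contribution
    S_seq          sequence score at the sequence-only hit
    T_seq          = S_seq + w * E(path), the sequence-only hit's path
                     re-scored with the epigenome term switched on
    E_seq          = T_seq - S_seq

The altered flag (many-vs-many) marks queries whose two hits are
different regions while the epigenome term helps at the epi hit
(T_epi > S_epi) and hurts at the sequence-only hit (T_seq < S_seq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align_engine import Alignment, ScoreProfile, epialign
from .core_scoring import EpiRegion, GenomicInterval, ScoringParams, build_score_tables


def calibrate(score: float, length_bp: int) -> float:
    """Rescale an alignment score to a per-1000-bp (per kilobase) basis."""
    if length_bp <= 0:
        raise ValueError(f"length_bp must be > 0 (got {length_bp})")
    return score * 1000.0 / length_bp


def e_range(query_states: np.ndarray, params: ScoringParams) -> Tuple[float, float]:
    """Theoretical (min, max) epigenome score for a gap-free full-query alignment.

    With k ones and z zeros in the query state track, the maximum is
    attained when every state pair is rewarded (k*epi_match1 +
    z*epi_match0) and the minimum when every pair is penalised
    ((k+z)*epi_mismatch).  Values are on the unweighted E scale.
    """
    states = np.asarray(query_states)
    if states.size and not np.isin(states, (0, 1)).all():
        raise ValueError("query states must be binary (0/1)")
    k = int(states.sum())
    z = int(states.size - k)
    max_e = k * params.epi_match1 + z * params.epi_match0
    min_e = (k + z) * params.epi_mismatch
    return (min_e, max_e)


@dataclass
class SnrResult:
    """A signal-to-noise ratio with its background context.

    ``value`` is the hit's sequence score divided by the best background
    score; ``infinite`` flags the case where the hit scores positively
    but no background window does.
    """

    value: float
    hit_score: float
    background: float
    n_background: int
    seed: int
    infinite: bool = False

    def __float__(self) -> float:
        return float(self.value)


def _extended_ratio(s_hit: float, bg: float) -> Tuple[float, bool]:
    if bg > 0:
        return s_hit / bg, False
    if s_hit > 0:
        return math.inf, True
    if bg == 0:
        return (1.0 if s_hit == 0 else 0.0), False
    # both non-positive: s_hit >= bg, so the ratio lies in [0, 1] — the
    # hit is no better than local background.
    return s_hit / bg, False


def compute_snr(
    query: EpiRegion,
    target: EpiRegion,
    hit: Alignment,
    tables,
    n_background: int = 20,
    seed: int = 0,
) -> SnrResult:
    """Compare a hit's sequence score to the best attainable elsewhere.

    Background windows are sampled uniformly among target positions whose
    window does not overlap the hit span; their length is
    ``max(hit_len + query_len, (target_len - hit_len)/n_background +
    query_len)`` so the sample stochastically tiles the non-hit part of
    the target.  Each window is aligned sequence-only (w = 0) and the
    background statistic is the *maximum* window score — the best
    alignment the query achieves away from the hit.  An SNR <= 1 means
    the hit's sequence similarity is indistinguishable from what nearby
    sequence offers anyway.

    The ratio is sign-extended: if no background window scores
    positively while the hit does, the SNR is +inf with ``infinite``
    set; if the hit itself is non-positive the ratio falls in [0, 1].
    """
    n = len(target)
    m = len(query)
    if n < m:
        raise ValueError(f"target (len {n}) shorter than query (len {m})")
    hit_len = max(hit.target_end_offset - hit.target_start_offset, 1)
    wl = min(n, max(hit_len + m, -((hit_len - n) // n_background) + m))
    # if no window of the ideal length fits beside the hit, shrink to the
    # larger flank so the background never degenerates to the hit itself
    max_side = max(hit.target_start_offset, n - hit.target_end_offset)
    if 0 < max_side < wl:
        wl = max_side
    starts = [
        s
        for s in range(0, n - wl + 1)
        if s + wl <= hit.target_start_offset or s >= hit.target_end_offset
    ]
    if not starts:  # hit spans the whole target: no meaningful background
        starts = list(range(0, n - wl + 1))
    rng = np.random.default_rng(seed)
    tables0 = tables.with_weight(0.0)
    t_iv = target.interval
    bgs = []
    for s in rng.choice(starts, size=n_background, replace=True):
        s = int(s)
        window = EpiRegion(
            GenomicInterval(t_iv.chrom, t_iv.start + s, t_iv.start + s + wl, t_iv.strand),
            target.seq[s : s + wl],
            target.states[s : s + wl],
        )
        aln, _ = epialign(query, window, tables0)
        bgs.append(aln.S)
    background = float(np.max(bgs))
    value, infinite = _extended_ratio(hit.S, background)
    return SnrResult(
        value=value,
        hit_score=hit.S,
        background=background,
        n_background=n_background,
        seed=seed,
        infinite=infinite,
    )


@dataclass
class AlignmentOutcome:
    """Per-query result bundling the epi hit and the sequence-only hit."""

    query: GenomicInterval
    query_length: int
    w: float
    epi_aln: Alignment
    seq_aln: Alignment
    epi_profile: Optional[ScoreProfile] = field(default=None, repr=False)
    seq_profile: Optional[ScoreProfile] = field(default=None, repr=False)
    T_epi: float = 0.0
    S_epi: float = 0.0
    E_epi: float = 0.0
    S_seq: float = 0.0
    T_seq: float = 0.0
    E_seq: float = 0.0
    snr_epi: Optional[SnrResult] = None
    snr_seq: Optional[SnrResult] = None
    e_range: Tuple[float, float] = (0.0, 0.0)
    hits_overlap: bool = True
    altered: bool = False
    epi_target_index: Optional[int] = None
    seq_target_index: Optional[int] = None

    @property
    def T_epi_per_kb(self) -> float:
        return calibrate(self.T_epi, self.query_length)

    @property
    def S_epi_per_kb(self) -> float:
        return calibrate(self.S_epi, self.query_length)

    @property
    def S_seq_per_kb(self) -> float:
        return calibrate(self.S_seq, self.query_length)

    @property
    def T_seq_per_kb(self) -> float:
        return calibrate(self.T_seq, self.query_length)

    def to_record(self) -> Dict:
        def hit_cols(aln: Alignment) -> Tuple[str, int, int]:
            if aln.target_hit is None:
                return ".", -1, -1
            h = aln.target_hit
            return h.chrom, h.start, h.end

        ec, es, ee = hit_cols(self.epi_aln)
        sc, ss, se = hit_cols(self.seq_aln)
        return {
            "query_chrom": self.query.chrom,
            "query_start": self.query.start,
            "query_end": self.query.end,
            "query_name": self.query.name,
            "query_strand": self.query.strand,
            "epi_hit_chrom": ec,
            "epi_hit_start": es,
            "epi_hit_end": ee,
            "T_epi": self.T_epi,
            "S_epi": self.S_epi,
            "E_epi": self.E_epi,
            "T_epi_per_kb": self.T_epi_per_kb,
            "S_epi_per_kb": self.S_epi_per_kb,
            "snr_epi": float(self.snr_epi) if self.snr_epi is not None else float("nan"),
            "seq_hit_chrom": sc,
            "seq_hit_start": ss,
            "seq_hit_end": se,
            "S_seq": self.S_seq,
            "T_seq": self.T_seq,
            "E_seq": self.E_seq,
            "S_seq_per_kb": self.S_seq_per_kb,
            "T_seq_per_kb": self.T_seq_per_kb,
            "snr_seq": float(self.snr_seq) if self.snr_seq is not None else float("nan"),
            "e_range_min": self.e_range[0],
            "e_range_max": self.e_range[1],
            "hits_overlap": bool(self.hits_overlap),
            "altered": bool(self.altered),
        }


def _hits_overlap(a: Alignment, b: Alignment) -> bool:
    if a.target_hit is None or b.target_hit is None:
        return a.target_hit is None and b.target_hit is None
    return a.target_hit.overlaps(b.target_hit)


def _build_outcome(
    query: EpiRegion,
    epi_target: EpiRegion,
    seq_target: EpiRegion,
    epi_aln: Alignment,
    epi_profile: Optional[ScoreProfile],
    seq_aln: Alignment,
    seq_profile: Optional[ScoreProfile],
    params: ScoringParams,
    tables,
    with_snr: bool,
    seed: int,
    n_background: int,
) -> AlignmentOutcome:
    w = params.w
    T_epi, S_epi = epi_aln.T, epi_aln.S
    S_seq = seq_aln.S
    T_seq = S_seq + w * seq_aln.E  # re-score the w=0 path with the epi term
    out = AlignmentOutcome(
        query=query.interval,
        query_length=len(query),
        w=w,
        epi_aln=epi_aln,
        seq_aln=seq_aln,
        epi_profile=epi_profile,
        seq_profile=seq_profile,
        T_epi=T_epi,
        S_epi=S_epi,
        E_epi=T_epi - S_epi,
        S_seq=S_seq,
        T_seq=T_seq,
        E_seq=T_seq - S_seq,
        e_range=e_range(query.states, params),
        hits_overlap=_hits_overlap(epi_aln, seq_aln),
    )
    if with_snr:
        out.snr_epi = compute_snr(
            query, epi_target, epi_aln, tables, n_background=n_background, seed=seed
        )
        out.snr_seq = compute_snr(
            query, seq_target, seq_aln, tables, n_background=n_background, seed=seed + 1
        )
    return out


def one_vs_one(
    pairs: Sequence[Tuple[EpiRegion, EpiRegion]],
    params: ScoringParams,
    with_snr: bool = True,
    n_background: int = 20,
    seed: int = 0,
) -> List[AlignmentOutcome]:
    """Align each query to its paired target with w and with w = 0.

    Pairs are matched line-by-line; each outcome carries both hits, both
    score profiles, SNRs and the theoretical E range.  When the
    configured w is 0 the two runs coincide.
    """
    tables = build_score_tables(params)
    tables0 = tables.with_weight(0.0)
    outcomes: List[AlignmentOutcome] = []
    for idx, (query, target) in enumerate(pairs):
        epi_aln, epi_prof = epialign(query, target, tables)
        if params.w == 0:
            seq_aln, seq_prof = epi_aln, epi_prof
        else:
            seq_aln, seq_prof = epialign(query, target, tables0)
        outcomes.append(
            _build_outcome(
                query, target, target,
                epi_aln, epi_prof, seq_aln, seq_prof,
                params, tables, with_snr, seed + 2 * idx, n_background,
            )
        )
    return outcomes


@dataclass
class ScoreMatrixPair:
    """Calibrated all-against-all score matrices (queries x targets)."""

    epi_scores: np.ndarray
    seq_scores: np.ndarray
    row_labels: List[str]
    col_labels: List[str]

    def epi_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epi_scores, index=self.row_labels, columns=self.col_labels)

    def seq_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.seq_scores, index=self.row_labels, columns=self.col_labels)


def many_vs_many(
    queries: Sequence[EpiRegion],
    targets: Sequence[EpiRegion],
    params: ScoringParams,
    with_snr: bool = True,
    n_background: int = 20,
    seed: int = 0,
) -> Tuple[ScoreMatrixPair, List[AlignmentOutcome]]:
    """Align every query against every target (counts may differ).

    Returns the pair of calibrated score matrices (T at the configured w;
    S at w = 0) and one outcome per query whose epi hit is the best
    target by T and whose sequence-only hit is the best target by S.
    Ties are broken by input order.
    """
    if not queries or not targets:
        raise ValueError("queries and targets must both be non-empty")
    tables = build_score_tables(params)
    tables0 = tables.with_weight(0.0)
    nq, nt = len(queries), len(targets)
    epi_T = np.zeros((nq, nt))
    seq_S = np.zeros((nq, nt))
    epi_alns: List[List[Alignment]] = []
    seq_alns: List[List[Alignment]] = []
    epi_profs: List[List[ScoreProfile]] = []
    seq_profs: List[List[ScoreProfile]] = []
    for qi, query in enumerate(queries):
        row_e, row_s, row_ep, row_sp = [], [], [], []
        for target in targets:
            ae, pe = epialign(query, target, tables)
            as_, ps = epialign(query, target, tables0)
            row_e.append(ae)
            row_s.append(as_)
            row_ep.append(pe)
            row_sp.append(ps)
            epi_T[qi, len(row_e) - 1] = calibrate(ae.T, len(query))
            seq_S[qi, len(row_s) - 1] = calibrate(as_.S, len(query))
        epi_alns.append(row_e)
        seq_alns.append(row_s)
        epi_profs.append(row_ep)
        seq_profs.append(row_sp)

    matrices = ScoreMatrixPair(
        epi_scores=epi_T,
        seq_scores=seq_S,
        row_labels=[q.interval.name for q in queries],
        col_labels=[t.interval.name for t in targets],
    )
    outcomes: List[AlignmentOutcome] = []
    for qi, query in enumerate(queries):
        best_e = int(np.argmax([a.T for a in epi_alns[qi]]))
        best_s = int(np.argmax([a.S for a in seq_alns[qi]]))
        out = _build_outcome(
            query,
            targets[best_e],
            targets[best_s],
            epi_alns[qi][best_e],
            epi_profs[qi][best_e],
            seq_alns[qi][best_s],
            seq_profs[qi][best_s],
            params,
            tables,
            with_snr,
            seed + 2 * qi,
            n_background,
        )
        out.epi_target_index = best_e
        out.seq_target_index = best_s
        out.altered = (
            best_e != best_s and out.T_epi > out.S_epi and out.T_seq < out.S_seq
        )
        outcomes.append(out)
    return matrices, outcomes


# --------------------------------------------------------------------------
# Reference sequence-score ranges

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide counts.

    Random Eulerian-walk shuffle on the dinucleotide multigraph: each
    vertex's outgoing edge list is permuted, a spanning arborescence to
    the terminal base is enforced by moving one edge to the end of each
    list, and the walk from the original first base rebuilds a sequence
    with identical dinucleotide composition.
    """
    if len(seq) < 3:
        return seq
    edges: Dict[str, List[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # pick random "last exit" edges forming a tree into the terminal vertex
    for _ in range(100):
        lasts = {}
        for v, outs in edges.items():
            if v != last:
                lasts[v] = outs[int(rng.integers(len(outs)))]
        # check connectivity of the chosen last-edge graph toward `last`
        ok = True
        for v in lasts:
            seen = set()
            u = v
            while u != last and u in lasts and u not in seen:
                seen.add(u)
                u = lasts[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    else:  # extremely degenerate composition; fall back to identity
        return seq
    shuffled: Dict[str, List[str]] = {}
    for v, outs in edges.items():
        outs = list(outs)
        if v in lasts:
            outs.remove(lasts[v])
        rng.shuffle(outs)
        if v in lasts:
            outs.append(lasts[v])
        shuffled[v] = outs
    walk = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    v = seq[0]
    while ptr.get(v, 0) < len(shuffled.get(v, [])):
        nxt = shuffled[v][ptr[v]]
        ptr[v] += 1
        walk.append(nxt)
        v = nxt
    return "".join(walk)


def reference_score_ranges(
    query: EpiRegion,
    target: EpiRegion,
    params: ScoringParams,
    n: int = 10,
    divergence: float = 0.25,
    seed: int = 0,
) -> Dict[str, Tuple[float, float]]:
    """Calibrated sequence-score reference ranges for a query/target pair.

    ``random``: range of w=0 scores of dinucleotide-shuffled copies of
    the query aligned to the target.  ``homologous``: range of scores of
    the query aligned to synthetic homologous copies generated at the
    stated substitution divergence (flanked by random sequence).
    """
    from .synthesizer import HomologSimParams, generate_homolog_pair

    rng = np.random.default_rng(seed)
    tables0 = build_score_tables(params).with_weight(0.0)
    m = len(query)
    zeros_t = np.zeros(len(target), dtype=np.int8)
    shuffled_scores = []
    for _ in range(n):
        qseq = dinucleotide_shuffle(query.seq, rng)
        q = EpiRegion(query.interval, qseq, np.zeros(m, dtype=np.int8))
        t = EpiRegion(target.interval, target.seq, zeros_t)
        aln, _ = epialign(q, t, tables0)
        shuffled_scores.append(calibrate(aln.S, m))
    homolog_scores = []
    for k in range(n):
        sim = HomologSimParams(
            length=m,
            sub_rate=divergence,
            indel_rate=0.005,
            indel_len_geom_p=0.5,
            flank=max(50, m // 4),
            seed=int(rng.integers(2**31 - 1)),
        )
        qseq, core, _ = generate_homolog_pair(sim)
        rng2 = np.random.default_rng(sim.seed + 1)
        flanks = ["".join(rng2.choice(list("ACGT"), sim.flank)) for _ in range(2)]
        tseq = flanks[0] + core + flanks[1]
        q = EpiRegion(
            GenomicInterval("ref_q", 0, m), qseq, np.zeros(m, dtype=np.int8)
        )
        t = EpiRegion(
            GenomicInterval("ref_t", 0, len(tseq)),
            tseq,
            np.zeros(len(tseq), dtype=np.int8),
        )
        aln, _ = epialign(q, t, tables0)
        homolog_scores.append(calibrate(aln.S, m))
    return {
        "random": (float(np.min(shuffled_scores)), float(np.max(shuffled_scores))),
        "homologous": (float(np.min(homolog_scores)), float(np.max(homolog_scores))),
    }
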