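"""Domain types and score-table construction.

The alignment engine maximises the joint target function

    T(alpha) = S(alpha) + w * E(alpha)

where ``S`` is a classical sequence-alignment score (substitutions plus
affine gaps) and ``E`` is an epigenome-similarity score accumulated over
aligned base pairs whose per-base chromatin states (1 = inside a peak,
0 = outside) agree or disagree.  This module defines the value types used
throughout the package and converts user-level parameters into the dense
lookup tables consumed by the dynamic program.

Sequence substitution scores may either be given directly (flat
match/mismatch) or derived from an F81-style continuous-time substitution
process, the substitution component of the TKF91 evolutionary model:

    P_t(b | a) = exp(-r t) * delta_ab + (1 - exp(-r t)) * pi_b
    sub[a][b]  = log( P_t(b | a) / pi_b )

which rewards identities less and less as the divergence time ``t`` grows
and is symmetric for any stationary distribution ``pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

# Alphabet shared by every score table.  N is a neutral ambiguity code:
# it scores 0 against everything, including itself.
ALPHABET = "ACGTN"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_N = BASE_INDEX["N"]

VALID_STRANDS = ("+", "-", ".")


class ParameterError(ValueError):
    """A scoring or simulation parameter violates its constraints."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with BED6-style metadata."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class EpiRegion:
    """A genomic interval carrying its DNA sequence and binary state track.

    ``seq`` and ``states`` are both oriented 5'->3' on the region's own
    strand: a minus-strand region holds the reverse complement of the
    reference sequence and a correspondingly reversed state vector.
    """

    interval: GenomicInterval
    seq: str
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        n = len(self.interval)
        if len(self.seq) != n or len(states) != n:
            raise ValueError(
                f"region {self.interval.chrom}:{self.interval.start}-"
                f"{self.interval.end}: seq length {len(self.seq)} and state "
                f"length {len(states)} must both equal {n}"
            )
        bad = set(self.seq.upper()) - set(ALPHABET)
        if bad:
            raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
        if states.size and not np.isin(states, (0, 1)).all():
            raise ValueError("states must be binary (0/1)")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class TkfParams:
    """Substitution side of the TKF91 model used to derive sequence scores.

    subst_rate   per-site substitution rate r (1/time)
    birth_rate   insertion (birth) rate lambda; must be < death rate
    death_rate   deletion (death) rate mu
    time         divergence time t (> 0)
    base_freqs   stationary base frequencies pi over A,C,G,T (sums to 1)
    """

    subst_rate: float
    birth_rate: float
    death_rate: float
    time: float
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)

    def validate(self) -> None:
        if self.subst_rate <= 0:
            raise ParameterError("tkf.subst_rate must be > 0")
        if not self.birth_rate < self.death_rate:
            raise ParameterError(
                "tkf.birth_rate must be smaller than tkf.death_rate "
                f"(got lambda={self.birth_rate}, mu={self.death_rate})"
            )
        if self.time <= 0:
            raise ParameterError("tkf.time must be > 0")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or (freqs <= 0).any():
            raise ParameterError("tkf.base_freqs must be 4 positive values")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ParameterError("tkf.base_freqs must sum to 1")


@dataclass(frozen=True)
class ScoringParams:
    """All tunable alignment parameters.

    w             epigenome weight (>= 0); 0 disables the epigenome term
    seq_match     score per identical aligned base pair (> 0)
    seq_mismatch  score per differing pair (< 0)
    gap_open      score for opening a gap (<= 0; charged once per gap run)
    gap_extend    score per gapped base (< 0)
    epi_match1    score per aligned (1,1) state pair (> 0)
    epi_match0    score per aligned (0,0) state pair (> 0, typically small)
    epi_mismatch  score per aligned (1,0)/(0,1) state pair (< 0)
    tkf           optional TKF/F81 record; when present the substitution
                  matrix is derived from it and seq_match/seq_mismatch are
                  ignored
    """

    w: float = 0.1
    seq_match: float = 2.0
    seq_mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    epi_match1: float = 2.0
    epi_match0: float = 0.2
    epi_mismatch: float = -2.0
    tkf: Optional[TkfParams] = None

    def validate(self) -> None:
        if self.w < 0:
            raise ParameterError(f"w must be >= 0 (got {self.w})")
        if not self.seq_match > 0:
            raise ParameterError(f"seq_match must be > 0 (got {self.seq_match})")
        if not self.seq_mismatch < 0:
            raise ParameterError(f"seq_mismatch must be < 0 (got {self.seq_mismatch})")
        if self.gap_open > 0:
            raise ParameterError(f"gap_open must be <= 0 (got {self.gap_open})")
        if not self.gap_extend < 0:
            raise ParameterError(f"gap_extend must be < 0 (got {self.gap_extend})")
        if not self.epi_match1 > 0:
            raise ParameterError(f"epi_match1 must be > 0 (got {self.epi_match1})")
        if not self.epi_match0 > 0:
            raise ParameterError(f"epi_match0 must be > 0 (got {self.epi_match0})")
        if not self.epi_mismatch < 0:
            raise ParameterError(f"epi_mismatch must be < 0 (got {self.epi_mismatch})")
        if self.tkf is not None:
            self.tkf.validate()

    def with_weight(self, w: float) -> "ScoringParams":
        return replace(self, w=w)


@dataclass(frozen=True)
class ScoreTables:
    """Dense per-pair lookup tables derived from :class:`ScoringParams`.

    ``sub`` is a 5x5 matrix over A,C,G,T,N (row N and column N are zero);
    ``epi`` is the 2x2 state-pair matrix.
    """

    sub: np.ndarray
    epi: np.ndarray
    gap_open: float
    gap_extend: float
    w: float
    params: ScoringParams = field(repr=False, default=None)  # type: ignore[assignment]

    def with_weight(self, w: float) -> "ScoreTables":
        params = self.params.with_weight(w) if self.params is not None else None
        return replace(self, w=w, params=params)


def _f81_substitution_matrix(tkf: TkfParams) -> np.ndarray:
    """Log-odds substitution scores under the F81 process."""
    rt = tkf.subst_rate * tkf.time
    pi = np.asarray(tkf.base_freqs, dtype=float)
    decay = math.exp(-rt)
    # P_t(b|a) = decay * I + (1 - decay) * pi_b  (rows a, cols b), so the
    # log-odds matrix is log(1 - decay) off the diagonal (exactly
    # symmetric) and log(decay/pi_a + 1 - decay) on it.
    out = np.full((4, 4), math.log1p(-decay))
    for a in range(4):
        out[a, a] = math.log(decay / pi[a] + (1.0 - decay))
    return out


def build_score_tables(params: ScoringParams) -> ScoreTables:
    """Validate ``params`` and materialise the DP lookup tables.

    When ``params.tkf`` is set the 4x4 core of the substitution matrix is
    the F81 log-odds matrix; otherwise flat match/mismatch scores sit on
    and off the diagonal.  N rows/columns are always zero.
    """
    params.validate()
    sub = np.zeros((5, 5), dtype=float)
    if params.tkf is not None:
        sub[:4, :4] = _f81_substitution_matrix(params.tkf)
    else:
        sub[:4, :4] = params.seq_mismatch
        np.fill_diagonal(sub[:4, :4], params.seq_match)
    sub[_N, :] = 0.0
    sub[:, _N] = 0.0

    epi = np.array(
        [
            [params.epi_match0, params.epi_mismatch],
            [params.epi_mismatch, params.epi_match1],
        ],
        dtype=float,
    )
    return ScoreTables(
        sub=sub,
        epi=epi,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        w=params.w,
        params=params,
    )


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string onto row indices of the substitution matrix."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = sorted({chr(c) for c in arr[out < 0]})
        raise ValueError(f"sequence contains invalid characters {bad}")
    return out
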