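"""Stage 1: all-vs-all local alignments and the distance matrix.

Every pair of input sequences is aligned with the Smith-Waterman/Gotoh
affine-gap aligner running on the blocked engine in LOCAL mode — n(n-1)/2
independent jobs dispatched through the scheduler.  Each alignment is turned
into a distance: one minus the fraction of identical residue pairs over the
residue-residue columns of the local alignment (an empty alignment counts as
distance 1).  An optional Kimura correction for multiple hits is off by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import fastlsa
from .fastlsa import (FastLsaParams, GridCache, Mode, SequencePairScorer,
                      moves_to_strings)
from .io_formats import SequenceRecord, SequenceSet
from .scheduler import PairJob, Scheduler
from .scoring import SCALE, ScoringScheme


@dataclass
class PairwiseResult:
    """One local alignment with its score, bounds, and identity."""

    id_a: str
    id_b: str
    score: float
    aligned_a: str
    aligned_b: str
    start_a: int
    start_b: int
    end_a: int
    end_b: int
    identity_fraction: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.ids.index(id_a), self.ids.index(id_b)])


def _identity(moves, a: str, b: str, origin) -> float:
    i, j = origin
    pairs = matches = 0
    for mv in moves:
        if mv == fastlsa.MOVE_DIAG:
            pairs += 1
            if a[i] == b[j]:
                matches += 1
            i += 1
            j += 1
        elif mv == fastlsa.MOVE_UP:
            i += 1
        else:
            j += 1
    return matches / pairs if pairs else 0.0


def local_affine_align(a: SequenceRecord, b: SequenceRecord,
                       s: ScoringScheme,
                       params: FastLsaParams | None = None) -> PairwiseResult:
    """Best local affine-gap alignment of two sequences.

    The score is the maximum Smith-Waterman score under the Gotoh
    recurrences; sequences with no positive-scoring cell yield score 0 and an
    empty alignment.
    """
    if a.alphabet != b.alphabet:
        raise ValueError(
            f"alphabet mismatch: {a.id!r} is {a.alphabet.value}, "
            f"{b.id!r} is {b.alphabet.value}")
    params = params or FastLsaParams()
    local = FastLsaParams(k=params.k, mode=Mode.LOCAL,
                          cell_codec=params.cell_codec,
                          calibration=params.calibration)
    scorer = _make_scorer(a, b, s)
    cache, best = fastlsa.forward_fill(scorer, local)
    return _result_from_cache(cache, a, b, s)


def _make_scorer(a: SequenceRecord, b: SequenceRecord,
                 s: ScoringScheme) -> SequencePairScorer:
    return SequencePairScorer(s.encode(a.residues), s.encode(b.residues),
                              s.int_matrix, s.int_gap_open, s.int_gap_extend)


def _result_from_cache(cache: GridCache, a: SequenceRecord,
                       b: SequenceRecord, s: ScoringScheme) -> PairwiseResult:
    scorer = _make_scorer(a, b, s)
    moves, origin, end = fastlsa.traceback(cache, scorer)
    aligned_a, aligned_b = moves_to_strings(a.residues, b.residues,
                                            moves, origin)
    return PairwiseResult(
        id_a=a.id, id_b=b.id, score=cache.best_score / SCALE,
        aligned_a=aligned_a, aligned_b=aligned_b,
        start_a=origin[0], start_b=origin[1], end_a=end[0], end_b=end[1],
        identity_fraction=_identity(moves, a.residues, b.residues, origin))


def percent_identity_distance(r: PairwiseResult) -> float:
    """1 - (identical residue pairs / residue-residue columns); empty -> 1."""
    if not r.aligned_a:
        return 1.0
    return 1.0 - r.identity_fraction


def kimura_distance(d: float) -> float:
    """Kimura multiple-hit correction of a fractional distance."""
    if d < 0.75:
        return -math.log(1.0 - d - 0.2 * d * d)
    # Beyond 75% divergence the correction diverges; cap as saturated.
    return 10.0


def build_distance_matrix(seqs: SequenceSet, s: ScoringScheme | None = None,
                          sched: Scheduler | None = None,
                          params: FastLsaParams | None = None,
                          kimura: bool = False
                          ) -> tuple[DistanceMatrix, list[PairwiseResult]]:
    """All-vs-all distances: n(n-1)/2 alignment jobs through the scheduler.

    The forward half of every job serializes its grid cache to bytes and the
    backward half deserializes it, so the two are genuinely decoupled.  The
    matrix is identical for any scheduler configuration.
    """
    if seqs.n < 2:
        raise ValueError("need at least two sequences")
    s = s or ScoringScheme.default_for(seqs.alphabet)
    sched = sched or Scheduler()
    params = params or FastLsaParams()

    pairs = [(i, j) for i in range(seqs.n) for j in range(i + 1, seqs.n)]

    def make_job(i: int, j: int) -> PairJob:
        a, b = seqs[i], seqs[j]
        if a.alphabet != b.alphabet:
            raise ValueError(f"alphabet mismatch between {a.id!r} and {b.id!r}")
        local = FastLsaParams(k=params.k, mode=Mode.LOCAL,
                              cell_codec=params.cell_codec,
                              calibration=params.calibration)

        def forward() -> bytes:
            cache, _best = fastlsa.forward_fill(_make_scorer(a, b, s), local)
            return cache.to_bytes()

        def backward(blob: bytes) -> PairwiseResult:
            return _result_from_cache(GridCache.from_bytes(blob), a, b, s)

        return PairJob(job_id=f"{a.id}|{b.id}", forward=forward,
                       backward=backward)

    try:
        results = sched.run_pairwise_stage([make_job(i, j) for i, j in pairs])
    except fastlsa.EngineError as exc:
        raise RuntimeError(f"pairwise alignment failed: {exc}") from exc

    d = np.zeros((seqs.n, seqs.n))
    for (i, j), res in zip(pairs, results):
        dist = percent_identity_distance(res)
        if kimura:
            dist = kimura_distance(dist)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=seqs.ids, d=d), results
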