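"""End-to-end orchestration of the three alignment stages.

Stage 1 fills the distance matrix from all pairwise local alignments, stage 2
builds and roots the neighbor-joining guide tree and derives sequence
weights, stage 3 merges profiles progressively along the tree.  A run is
fully determined by its inputs and configuration — there is no randomness —
so repeated runs are byte-identical regardless of worker counts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .fastlsa import FastLsaParams
from .io_formats import Msa, SequenceSet
from .pairwise import DistanceMatrix, PairwiseResult, build_distance_matrix
from .profiles import MergeRecord, progressive_align
from .scheduler import Scheduler
from .scoring import ScoringScheme
from .tree import (GuideTree, SequenceWeights, compute_weights,
                   midpoint_root, nj_build)

log = logging.getLogger("gridmsa")


@dataclass
class AlignmentResult:
    msa: Msa
    tree: GuideTree          # midpoint-rooted guide tree
    nj_tree: GuideTree       # unrooted NJ tree as built
    distances: DistanceMatrix
    weights: SequenceWeights
    pairwise: list[PairwiseResult]
    merges: list[MergeRecord]
    stage_seconds: dict[str, float] = field(default_factory=dict)


def align_sequences(seqs: SequenceSet, s: ScoringScheme | None = None,
                    params: FastLsaParams | None = None,
                    sched: Scheduler | None = None,
                    fragment_policy: bool = False,
                    kimura: bool = False) -> AlignmentResult:
    """Run the full three-stage pipeline on a sequence set."""
    if seqs.n < 2:
        raise ValueError("need at least two sequences to align")
    s = s or ScoringScheme.default_for(seqs.alphabet)
    params = params or FastLsaParams()
    sched = sched or Scheduler()
    timings: dict[str, float] = {}

    t0 = time.monotonic()
    dm, pairwise = build_distance_matrix(seqs, s, sched=sched, params=params,
                                         kimura=kimura)
    timings["pairwise"] = time.monotonic() - t0
    log.info("stage 1: %d pairwise jobs in %.2fs",
             seqs.n * (seqs.n - 1) // 2, timings["pairwise"])

    t0 = time.monotonic()
    nj = nj_build(dm)
    rooted = midpoint_root(nj)
    weights = compute_weights(rooted)
    timings["tree"] = time.monotonic() - t0
    log.info("stage 2: guide tree in %.2fs", timings["tree"])

    t0 = time.monotonic()
    msa, merges = progressive_align(seqs, rooted, weights, s, params=params,
                                    sched=sched,
                                    fragment_policy=fragment_policy)
    timings["progressive"] = time.monotonic() - t0
    log.info("stage 3: %d merges in %.2fs", len(merges),
             timings["progressive"])

    return AlignmentResult(msa=msa, tree=rooted, nj_tree=nj, distances=dm,
                           weights=weights, pairwise=pairwise, merges=merges,
                           stage_seconds=timings)
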