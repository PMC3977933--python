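"""Stage 3: profiles, prfscore, and progressive profile-profile alignment.

A *profile* summarizes a partial alignment as a 35 x m matrix: 33 residue
category rows (the full IUPAC ambiguity alphabet, padded to 33 for both DNA
and protein, unused rows zero) followed by one position-specific gap-open row
and one gap-extend row.  Residue rows hold, per column, the weight-averaged
substitution-matrix row of the residues observed there, so the profile-profile
cell score — prfscore — is a plain vector multiplication: the residue rows of
one profile's column dotted with the weighted residue frequencies of the
other's.  Because the substitution matrix is symmetric this product equals
f1' M f2 and is symmetric in its arguments; gap rows are excluded from it.

Each merge of the progressive stage aligns two profiles globally on the
blocked engine (scorer = prfscore, gap penalties from the profile gap rows)
and stitches the two group alignments together along the optimal path.  DP
cell values are prfscore points rounded onto the integer x100 scale, which
keeps grid-cache cells exact and both codecs meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import fastlsa
from .fastlsa import FastLsaParams, Mode
from .io_formats import GAP, Msa, SequenceSet
from .scoring import SCALE, ScoringScheme, residue_order
from .tree import GuideTree, SequenceWeights, traversal_schedule

#: Fixed profile height: residue categories plus the two gap-penalty rows.
PROFILE_ROWS = 35
RESIDUE_ROWS = 33
GAP_OPEN_ROW = 33
GAP_EXT_ROW = 34

#: Existing gaps in a column scale its penalties by 1 - 0.7 * gap_fraction.
GAP_DILUTION = 0.7


@dataclass
class Profile:
    """Weighted residue/gap-penalty summary of one group alignment."""

    data: np.ndarray        # (35, m): residue score rows + gap penalty rows
    freq: np.ndarray        # (33, m): weighted residue frequencies
    member_ids: list[str]
    alphabet: object

    @property
    def m(self) -> int:
        return self.data.shape[1]

    @property
    def score_rows(self) -> np.ndarray:
        return self.data[:RESIDUE_ROWS]

    @property
    def gap_open(self) -> np.ndarray:
        return self.data[GAP_OPEN_ROW]

    @property
    def gap_extend(self) -> np.ndarray:
        return self.data[GAP_EXT_ROW]


def build_profile(group: Msa, weights: SequenceWeights,
                  s: ScoringScheme) -> Profile:
    """Build the 35 x m profile of a group alignment.

    Residue rows are the weight-averaged substitution rows of the observed
    residues (average over the total member weight, so gap-only columns are
    all zero); gap rows hold the base affine penalties scaled down where the
    column already contains gaps.
    """
    order = residue_order(s.alphabet)
    L = len(order)
    m = group.length
    try:
        w = np.array([weights[rid] for rid, _ in group.rows])
    except KeyError as exc:
        raise ValueError(f"no weight for group member {exc.args[0]!r}") from None
    total = w.sum()

    freq = np.zeros((RESIDUE_ROWS, m))
    gap_w = np.zeros(m)
    for (rid, row), wt in zip(group.rows, w):
        codes = s.encode(row.replace(GAP, "").ljust(1, order[0]))
        ci = 0
        for c, ch in enumerate(row):
            if ch == GAP:
                gap_w[c] += wt
            else:
                freq[codes[ci], c] += wt
                ci += 1
    freq /= total
    gap_frac = gap_w / total

    data = np.zeros((PROFILE_ROWS, m))
    data[:L] = s.matrix @ freq[:L]
    dilution = 1.0 - GAP_DILUTION * gap_frac
    data[GAP_OPEN_ROW] = s.gap_open * dilution
    data[GAP_EXT_ROW] = s.gap_extend * dilution
    return Profile(data=data, freq=freq,
                   member_ids=[rid for rid, _ in group.rows],
                   alphabet=s.alphabet)


def prfscore(p1: Profile, p2: Profile, i: int, j: int) -> float:
    """Vector product of p1's residue score column i with p2's weighted
    residue frequencies at column j; symmetric, and zero against an all-gap
    column."""
    return float(p1.score_rows[:, i] @ p2.freq[:, j])


@njit(cache=True, nogil=True)
def _prf_block(score_cols, freq_cols, scale):  # pragma: no cover - jitted
    # Fixed summation order keeps results bit-identical across block
    # partitions and fragment copies (BLAS reassociates by operand shape).
    bh = score_cols.shape[1]
    bw = freq_cols.shape[1]
    out = np.empty((bh, bw), np.int64)
    for i in range(bh):
        for j in range(bw):
            acc = 0.0
            for r in range(score_cols.shape[0]):
                acc += score_cols[r, i] * freq_cols[r, j]
            v = acc * scale
            if v >= 0.0:
                out[i, j] = np.int64(np.floor(v + 0.5))
            else:
                out[i, j] = np.int64(np.ceil(v - 0.5))
    return out


class ProfilePairScorer:
    """prfscore cells plus position-specific gap penalties for the engine.

    With the fragment-transfer policy on, each block job first copies the
    profile fragments it needs (emulating per-worker local-memory copies);
    with it off blocks read the shared arrays.  Both paths compute identical
    cells.
    """

    def __init__(self, p1: Profile, p2: Profile,
                 fragment_policy: bool = False):
        self.p1 = p1
        self.p2 = p2
        self.fragment_policy = fragment_policy
        self.len_a = p1.m
        self.len_b = p2.m
        self._score1 = np.ascontiguousarray(p1.score_rows)
        self._freq2 = np.ascontiguousarray(p2.freq)
        from .scoring import to_scaled_int
        self.gap_open_a = to_scaled_int(p1.gap_open)
        self.gap_ext_a = to_scaled_int(p1.gap_extend)
        self.gap_open_b = to_scaled_int(p2.gap_open)
        self.gap_ext_b = to_scaled_int(p2.gap_extend)

    def sub_block(self, rs: int, re: int, cs: int, ce: int) -> np.ndarray:
        if self.fragment_policy:
            score = self._score1[:, rs:re].copy()
            freq = self._freq2[:, cs:ce].copy()
        else:
            score = np.ascontiguousarray(self._score1[:, rs:re])
            freq = np.ascontiguousarray(self._freq2[:, cs:ce])
        return _prf_block(score, freq, float(SCALE))


@dataclass
class ProfilePairTask:
    """A self-contained profile-profile alignment job."""

    p1: Profile
    p2: Profile
    group_a: Msa
    group_b: Msa
    params: FastLsaParams = field(default_factory=FastLsaParams)
    fragment_policy: bool = False


def merge_groups(group_a: Msa, group_b: Msa, moves) -> Msa:
    """Stitch two group alignments together along an engine move path."""
    take_a = [mv != fastlsa.MOVE_LEFT for mv in moves]
    take_b = [mv != fastlsa.MOVE_UP for mv in moves]
    rows: list[tuple[str, str]] = []
    for rid, seq in group_a.rows:
        it = iter(seq)
        rows.append((rid, "".join(next(it) if t else GAP for t in take_a)))
    for rid, seq in group_b.rows:
        it = iter(seq)
        rows.append((rid, "".join(next(it) if t else GAP for t in take_b)))
    return Msa(rows)


def profile_align_scored(task: ProfilePairTask, sched=None
                         ) -> tuple[Msa, float, list[str]]:
    """Globally align two profiles on the blocked engine.

    Returns the merged group alignment, the corner DP score in prfscore
    points, and the move path.  The result is independent of the worker count
    and the fragment policy.
    """
    params = FastLsaParams(k=task.params.k, mode=Mode.GLOBAL,
                           cell_codec=task.params.cell_codec,
                           calibration=task.params.calibration)
    scorer = ProfilePairScorer(task.p1, task.p2,
                               fragment_policy=task.fragment_policy)
    try:
        cache, best = fastlsa.forward_fill(scorer, params, sched=sched)
        moves, _origin, _end = fastlsa.traceback(cache, scorer)
    except fastlsa.EngineError as exc:
        raise RuntimeError(
            f"profile alignment of groups {task.p1.member_ids} x "
            f"{task.p2.member_ids} failed: {exc}") from exc
    return merge_groups(task.group_a, task.group_b, moves), \
        best[0] / SCALE, moves


def profile_align(task: ProfilePairTask, sched=None) -> Msa:
    return profile_align_scored(task, sched=sched)[0]


@dataclass
class MergeRecord:
    """Audit record of one executed merge step."""

    members: frozenset
    score: float
    moves: list[str]
    msa: Msa


def progressive_align(seqs: SequenceSet, tree: GuideTree,
                      weights: SequenceWeights,
                      s: ScoringScheme | None = None,
                      params: FastLsaParams | None = None,
                      sched=None, fragment_policy: bool = False,
                      ) -> tuple[Msa, list[MergeRecord]]:
    """Run the guide-tree merge schedule to the final multiple alignment.

    Every intermediate group alignment is an explicit Msa; each merge builds
    two profiles and aligns them on the engine.  Final rows are returned in
    input order, and gap-stripping any row reproduces its input sequence.
    """
    s = s or ScoringScheme.default_for(seqs.alphabet)
    params = params or FastLsaParams()
    if set(tree.leaf_names()) != set(seqs.ids):
        raise ValueError("guide-tree leaves do not match the sequence ids")

    groups: dict[frozenset, Msa] = {
        frozenset({rec.id}): Msa([(rec.id, rec.residues)]) for rec in seqs}
    records: list[MergeRecord] = []
    for step in traversal_schedule(tree):
        if step.left not in groups or step.right not in groups:
            raise AssertionError(
                "merge schedule references a group that is not available")
        ga = groups.pop(step.left)
        gb = groups.pop(step.right)
        task = ProfilePairTask(
            p1=build_profile(ga, weights, s),
            p2=build_profile(gb, weights, s),
            group_a=ga, group_b=gb, params=params,
            fragment_policy=fragment_policy)
        merged, score, moves = profile_align_scored(task, sched=sched)
        groups[step.members] = merged
        records.append(MergeRecord(members=step.members, score=score,
                                   moves=moves, msa=merged))
    if len(groups) != 1:
        raise AssertionError("merge schedule did not converge to one group")
    final = next(iter(groups.values())).reordered(seqs.ids)
    return final, records
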