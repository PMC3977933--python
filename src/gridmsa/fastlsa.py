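"""Blocked affine-gap dynamic programming with a grid cache.

The DP matrix is partitioned into a k x k grid of blocks.  The forward pass
fills blocks in wave-front order — block (bi, bj) becomes runnable once
(bi-1, bj) and (bi, bj-1) are done — and keeps only the DP values on block
boundaries (the *grid cache*): k+1 boundary rows and k+1 boundary columns of
(H, E, F) cells.  Traceback is a separate job that re-derives each block
interior on demand from its cached boundary while walking the optimal path, so
the forward and backward halves of an alignment can run as decoupled jobs that
communicate only through the serialized cache.

Cell values are signed 32-bit integers on the scoring scale; overflow is an
error, never a silent wrap.  Two byte-level cell codecs are provided: a
12-byte absolute encoding and a 6-byte relative one that stores E and F as
signed 8-bit offsets from H (valid only while those offsets stay below 128 in
magnitude; the int8 value -128 is reserved for the minus-infinity sentinel of
uninitialized gap states).
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass, field
from math import ceil, sqrt
from typing import Callable, Sequence

import numpy as np
from numba import njit

#: Minus-infinity sentinel for unreachable gap states.  Absorbing under the
#: clamped DP arithmetic and far below any reachable score, yet safely inside
#: the int32 range required of grid-cache cells.
NEG_INF = -(2 ** 30)

_INT32_MIN, _INT32_MAX = -(2 ** 31), 2 ** 31 - 1


class Mode(enum.Enum):
    GLOBAL = "global"
    LOCAL = "local"


class Codec(enum.Enum):
    ABSOLUTE12 = "absolute12"
    RELATIVE6 = "relative6"


class CodecOverflowError(ValueError):
    """A cell does not fit the requested codec; upgrade to ABSOLUTE12."""


class EngineError(RuntimeError):
    """Internal DP invariant violated (cache/input mismatch, bad traceback)."""


@dataclass
class FastLsaParams:
    """Engine parameters.

    ``k`` is the per-axis block *count*; ``k=1`` degenerates to plain
    full-matrix DP.  ``None`` selects k from the calibration table via
    :func:`select_k`.
    """

    k: int | None = None
    mode: Mode = Mode.GLOBAL
    cell_codec: Codec = Codec.ABSOLUTE12
    calibration: Sequence[tuple[int, int]] | None = None

    def resolve_k(self, len_a: int, len_b: int) -> int:
        if self.k is None:
            return select_k(len_a, len_b, self.calibration)
        k = int(self.k)
        if not 1 <= k <= min(len_a, len_b):
            raise ValueError(
                f"k={k} out of range [1, {min(len_a, len_b)}] for lengths "
                f"{len_a}x{len_b}")
        return k


# ---------------------------------------------------------------------------
# Block geometry


def axis_bounds(length: int, k: int) -> np.ndarray:
    """k+1 cut points along one axis; segment sizes differ by at most one,
    larger segments first."""
    if length < 1:
        raise ValueError("axis length must be >= 1")
    if not 1 <= k <= length:
        raise ValueError(f"k={k} out of range [1, {length}]")
    return np.array([-(-t * length // k) for t in range(k + 1)], dtype=np.int64)


def partition_blocks(len_a: int, len_b: int, k: int):
    """Row-major list of half-open block extents ((rs, re), (cs, ce))."""
    rb, cb = axis_bounds(len_a, k), axis_bounds(len_b, k)
    return [((int(rb[bi]), int(rb[bi + 1])), (int(cb[bj]), int(cb[bj + 1])))
            for bi in range(k) for bj in range(k)]


def wavefront_diagonals(k: int) -> list[list[tuple[int, int]]]:
    """Blocks grouped by anti-diagonal, each diagonal sorted row-major."""
    return [[(bi, d - bi) for bi in range(max(0, d - k + 1), min(d, k - 1) + 1)]
            for d in range(2 * k - 1)]


def select_k(len_a: int, len_b: int,
             table: Sequence[tuple[int, int]] | None = None) -> int:
    """Pick a block count for a pair of lengths.

    With a calibration table of (length, k) points sorted by length, k is
    piecewise-linearly interpolated on max(len_a, len_b) and rounded to the
    nearest integer.  Without a table the portable default
    ceil(sqrt(max_len / 64)) clamped to [1, 16] is used.  Either way the
    result is clamped to [1, min(len_a, len_b)].
    """
    max_len, min_len = max(len_a, len_b), min(len_a, len_b)
    if table:
        pts = sorted((int(l), int(kv)) for l, kv in table)
        xs = np.array([p[0] for p in pts], dtype=np.float64)
        ys = np.array([p[1] for p in pts], dtype=np.float64)
        k = int(np.floor(np.interp(max_len, xs, ys) + 0.5))
    else:
        k = ceil(sqrt(max_len / 64))
        k = min(max(k, 1), 16)
    return min(max(k, 1), min_len)


# ---------------------------------------------------------------------------
# Cell codecs

_ABS = struct.Struct("<iii")
_REL = struct.Struct("<ibb")
_REL_SENTINEL = -128


@dataclass(frozen=True)
class GridCacheCell:
    """One (H, E, F) triple of DP values at a block boundary."""

    h: int
    e: int
    f: int


def _check_int32(*values: int) -> None:
    for v in values:
        if not _INT32_MIN <= v <= _INT32_MAX:
            raise EngineError(f"DP value {v} overflows signed 32-bit cells")


def encode_cell(cell: GridCacheCell, codec: Codec) -> bytes:
    _check_int32(cell.h, cell.e, cell.f)
    if codec is Codec.ABSOLUTE12:
        return _ABS.pack(cell.h, cell.e, cell.f)
    diffs = []
    for v in (cell.e, cell.f):
        if v == NEG_INF:
            diffs.append(_REL_SENTINEL)
            continue
        d = v - cell.h
        if abs(d) >= 128:
            raise CodecOverflowError(
                f"|h-e|/|h-f| = {abs(d)} >= 128: cell {cell} does not fit the "
                "6-byte relative codec; use the 12-byte absolute codec")
        diffs.append(d)
    return _REL.pack(cell.h, diffs[0], diffs[1])


def decode_cell(data: bytes, codec: Codec) -> GridCacheCell:
    if codec is Codec.ABSOLUTE12:
        h, e, f = _ABS.unpack(data)
        return GridCacheCell(h, e, f)
    h, de, df = _REL.unpack(data)
    e = NEG_INF if de == _REL_SENTINEL else h + de
    f = NEG_INF if df == _REL_SENTINEL else h + df
    return GridCacheCell(h, e, f)


def cell_size(codec: Codec) -> int:
    return _ABS.size if codec is Codec.ABSOLUTE12 else _REL.size


def _encode_stream(h: np.ndarray, e: np.ndarray, f: np.ndarray,
                   codec: Codec) -> bytes:
    """Vectorized cell-major encoding of parallel H/E/F arrays."""
    for arr in (h, e, f):
        if arr.size and (arr.min() < _INT32_MIN or arr.max() > _INT32_MAX):
            raise EngineError("DP values overflow signed 32-bit cells")
    if codec is Codec.ABSOLUTE12:
        out = np.empty((h.size, 3), dtype="<i4")
        out[:, 0], out[:, 1], out[:, 2] = h, e, f
        return out.tobytes()
    dt = np.dtype([("h", "<i4"), ("de", "i1"), ("df", "i1")])
    out = np.empty(h.size, dtype=dt)
    out["h"] = h
    for name, arr in (("de", e), ("df", f)):
        sentinel = arr == NEG_INF
        d = arr - h
        if np.any(~sentinel & (np.abs(d) >= 128)):
            raise CodecOverflowError(
                "cache holds cells with |h-e| or |h-f| >= 128: the 6-byte "
                "relative codec cannot store them; use the 12-byte absolute "
                "codec")
        d[sentinel] = _REL_SENTINEL
        out[name] = d.astype(np.int8)
    return out.tobytes()


def _decode_stream(data: bytes, count: int, codec: Codec):
    if codec is Codec.ABSOLUTE12:
        arr = np.frombuffer(data, dtype="<i4", count=3 * count).reshape(-1, 3)
        return (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64),
                arr[:, 2].astype(np.int64))
    dt = np.dtype([("h", "<i4"), ("de", "i1"), ("df", "i1")])
    arr = np.frombuffer(data, dtype=dt, count=count)
    h = arr["h"].astype(np.int64)
    out = []
    for name in ("de", "df"):
        d = arr[name].astype(np.int64)
        v = h + d
        v[d == _REL_SENTINEL] = NEG_INF
        out.append(v)
    return h, out[0], out[1]


# ---------------------------------------------------------------------------
# Grid cache

_MAGIC = b"GMC1"
_HEADER = struct.Struct("<4sBBIqqqqq")


@dataclass
class GridCache:
    """Block-boundary (H, E, F) values of one forward pass.

    ``rows[t]`` holds DP row ``row_bounds[t]`` (length len_b + 1); ``cols[t]``
    holds DP column ``col_bounds[t]`` (length len_a + 1).  Total cell count is
    exactly (k+1) * (len_a + len_b + 2).
    """

    mode: Mode
    codec: Codec
    k: int
    len_a: int
    len_b: int
    row_bounds: np.ndarray
    col_bounds: np.ndarray
    h_rows: np.ndarray
    e_rows: np.ndarray
    f_rows: np.ndarray
    h_cols: np.ndarray
    e_cols: np.ndarray
    f_cols: np.ndarray
    best_score: int = 0
    best_i: int = 0
    best_j: int = 0

    @property
    def total_cells(self) -> int:
        return self.h_rows.size + self.h_cols.size

    @property
    def best(self) -> tuple[int, int, int]:
        return self.best_score, self.best_i, self.best_j

    def to_bytes(self) -> bytes:
        header = _HEADER.pack(
            _MAGIC, list(Codec).index(self.codec), list(Mode).index(self.mode),
            self.k, self.len_a, self.len_b,
            self.best_score, self.best_i, self.best_j)
        rows = _encode_stream(self.h_rows.ravel(), self.e_rows.ravel(),
                              self.f_rows.ravel(), self.codec)
        cols = _encode_stream(self.h_cols.ravel(), self.e_cols.ravel(),
                              self.f_cols.ravel(), self.codec)
        return header + rows + cols

    @classmethod
    def from_bytes(cls, data: bytes) -> "GridCache":
        magic, codec_i, mode_i, k, len_a, len_b, bs, bi, bj = \
            _HEADER.unpack_from(data)
        if magic != _MAGIC:
            raise EngineError("not a grid-cache byte stream")
        codec, mode = list(Codec)[codec_i], list(Mode)[mode_i]
        n_row = (k + 1) * (len_b + 1)
        n_col = (k + 1) * (len_a + 1)
        off = _HEADER.size
        sz = cell_size(codec)
        hr, er, fr = _decode_stream(data[off:off + n_row * sz], n_row, codec)
        off += n_row * sz
        hc, ec, fc = _decode_stream(data[off:off + n_col * sz], n_col, codec)
        return cls(
            mode=mode, codec=codec, k=k, len_a=len_a, len_b=len_b,
            row_bounds=axis_bounds(len_a, k), col_bounds=axis_bounds(len_b, k),
            h_rows=hr.reshape(k + 1, len_b + 1),
            e_rows=er.reshape(k + 1, len_b + 1),
            f_rows=fr.reshape(k + 1, len_b + 1),
            h_cols=hc.reshape(k + 1, len_a + 1),
            e_cols=ec.reshape(k + 1, len_a + 1),
            f_cols=fc.reshape(k + 1, len_a + 1),
            best_score=bs, best_i=bi, best_j=bj)


# ---------------------------------------------------------------------------
# Pair scorers

class SequencePairScorer:
    """Cell scores for a pair of encoded residue sequences.

    Substitution lookups come from an integer-scaled matrix; gap penalties are
    position-independent.
    """

    def __init__(self, codes_a: np.ndarray, codes_b: np.ndarray,
                 int_matrix: np.ndarray, gap_open: int, gap_extend: int):
        self.codes_a = np.ascontiguousarray(codes_a, dtype=np.int64)
        self.codes_b = np.ascontiguousarray(codes_b, dtype=np.int64)
        self.matrix = np.ascontiguousarray(int_matrix, dtype=np.int64)
        self.len_a = len(codes_a)
        self.len_b = len(codes_b)
        self.gap_open_a = np.full(self.len_a, gap_open, dtype=np.int64)
        self.gap_ext_a = np.full(self.len_a, gap_extend, dtype=np.int64)
        self.gap_open_b = np.full(self.len_b, gap_open, dtype=np.int64)
        self.gap_ext_b = np.full(self.len_b, gap_extend, dtype=np.int64)

    def sub_block(self, rs: int, re: int, cs: int, ce: int) -> np.ndarray:
        return np.ascontiguousarray(
            self.matrix[self.codes_a[rs:re, None], self.codes_b[None, cs:ce]])


# ---------------------------------------------------------------------------
# Numba kernel

@njit(cache=True, nogil=True)
def _fill_block(h_top, e_top, f_top, h_left, e_left, f_left,
                sub, goa, gea, gob, geb, local):  # pragma: no cover - jitted
    bh = sub.shape[0]
    bw = sub.shape[1]
    H = np.empty((bh + 1, bw + 1), np.int64)
    E = np.empty((bh + 1, bw + 1), np.int64)
    F = np.empty((bh + 1, bw + 1), np.int64)
    for j in range(bw + 1):
        H[0, j] = h_top[j]
        E[0, j] = e_top[j]
        F[0, j] = f_top[j]
    for i in range(bh + 1):
        H[i, 0] = h_left[i]
        E[i, 0] = e_left[i]
        F[i, 0] = f_left[i]
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, bh + 1):
        for j in range(1, bw + 1):
            e = H[i, j - 1] - gob[j - 1]
            e2 = E[i, j - 1] - geb[j - 1]
            if e2 > e:
                e = e2
            if e < NEG_INF:
                e = NEG_INF
            f = H[i - 1, j] - goa[i - 1]
            f2 = F[i - 1, j] - gea[i - 1]
            if f2 > f:
                f = f2
            if f < NEG_INF:
                f = NEG_INF
            h = H[i - 1, j - 1] + sub[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if local:
                if h < 0:
                    h = 0
                if h > best:
                    best = h
                    best_i = i
                    best_j = j
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F, best, best_i, best_j


# ---------------------------------------------------------------------------
# Forward pass


def _init_boundaries(cache: GridCache, scorer) -> None:
    """DP row 0 and column 0 under the requested mode."""
    la, lb = cache.len_a, cache.len_b
    if cache.mode is Mode.LOCAL:
        cache.h_rows[0, :] = 0
        cache.h_cols[0, :] = 0
        cache.e_rows[0, :] = NEG_INF
        cache.f_rows[0, :] = NEG_INF
        cache.e_cols[0, :] = NEG_INF
        cache.f_cols[0, :] = NEG_INF
        return
    # Global: row 0 is one horizontal gap run, column 0 one vertical run.
    e = np.empty(lb + 1, dtype=np.int64)
    e[0] = NEG_INF
    if lb:
        e[1] = -scorer.gap_open_b[0]
        if lb > 1:
            e[2:] = e[1] - np.cumsum(scorer.gap_ext_b[1:])
    cache.e_rows[0, :] = e
    cache.h_rows[0, :] = e
    cache.h_rows[0, 0] = 0
    cache.f_rows[0, :] = NEG_INF

    f = np.empty(la + 1, dtype=np.int64)
    f[0] = NEG_INF
    if la:
        f[1] = -scorer.gap_open_a[0]
        if la > 1:
            f[2:] = f[1] - np.cumsum(scorer.gap_ext_a[1:])
    cache.f_cols[0, :] = f
    cache.h_cols[0, :] = f
    cache.h_cols[0, 0] = 0
    cache.e_cols[0, :] = NEG_INF
    # Shared origin cell.
    cache.e_rows[0, 0] = NEG_INF
    cache.f_cols[0, 0] = NEG_INF
    cache.e_cols[0, 0] = NEG_INF
    cache.f_rows[0, 0] = NEG_INF


def _run_block(cache: GridCache, scorer, bi: int, bj: int,
               keep_interior: bool = False):
    """Fill one block from cached boundaries; write its outgoing edges."""
    rb, cb = cache.row_bounds, cache.col_bounds
    rs, re = int(rb[bi]), int(rb[bi + 1])
    cs, ce = int(cb[bj]), int(cb[bj + 1])
    local = cache.mode is Mode.LOCAL
    H, E, F, best, li, lj = _fill_block(
        np.ascontiguousarray(cache.h_rows[bi, cs:ce + 1]),
        np.ascontiguousarray(cache.e_rows[bi, cs:ce + 1]),
        np.ascontiguousarray(cache.f_rows[bi, cs:ce + 1]),
        np.ascontiguousarray(cache.h_cols[bj, rs:re + 1]),
        np.ascontiguousarray(cache.e_cols[bj, rs:re + 1]),
        np.ascontiguousarray(cache.f_cols[bj, rs:re + 1]),
        scorer.sub_block(rs, re, cs, ce),
        np.ascontiguousarray(scorer.gap_open_a[rs:re]),
        np.ascontiguousarray(scorer.gap_ext_a[rs:re]),
        np.ascontiguousarray(scorer.gap_open_b[cs:ce]),
        np.ascontiguousarray(scorer.gap_ext_b[cs:ce]),
        local)
    bh, bw = re - rs, ce - cs
    cache.h_rows[bi + 1, cs:ce + 1] = H[bh, :]
    cache.e_rows[bi + 1, cs:ce + 1] = E[bh, :]
    cache.f_rows[bi + 1, cs:ce + 1] = F[bh, :]
    cache.h_cols[bj + 1, rs:re + 1] = H[:, bw]
    cache.e_cols[bj + 1, rs:re + 1] = E[:, bw]
    cache.f_cols[bj + 1, rs:re + 1] = F[:, bw]
    block_best = (int(best), rs + int(li), cs + int(lj))
    if keep_interior:
        return H, E, F, block_best
    return block_best


def forward_fill(scorer, params: FastLsaParams, sched=None
                 ) -> tuple[GridCache, tuple[int, int, int]]:
    """Fill the DP grid block-by-block, keeping only boundary cells.

    Returns the grid cache and ``(score, i, j)`` — the corner value in GLOBAL
    mode, or the maximum cell (ties broken toward the smallest (i, j)) in
    LOCAL mode.  The result is identical for any worker count and any legal
    block completion order.
    """
    la, lb = scorer.len_a, scorer.len_b
    if la < 1 or lb < 1:
        raise ValueError("both inputs must be non-empty")
    k = params.resolve_k(la, lb)
    cache = GridCache(
        mode=params.mode, codec=params.cell_codec, k=k, len_a=la, len_b=lb,
        row_bounds=axis_bounds(la, k), col_bounds=axis_bounds(lb, k),
        h_rows=np.zeros((k + 1, lb + 1), dtype=np.int64),
        e_rows=np.zeros((k + 1, lb + 1), dtype=np.int64),
        f_rows=np.zeros((k + 1, lb + 1), dtype=np.int64),
        h_cols=np.zeros((k + 1, la + 1), dtype=np.int64),
        e_cols=np.zeros((k + 1, la + 1), dtype=np.int64),
        f_cols=np.zeros((k + 1, la + 1), dtype=np.int64))
    _init_boundaries(cache, scorer)

    block_bests: dict[tuple[int, int], tuple[int, int, int]] = {}

    def make_job(bi: int, bj: int) -> Callable[[], None]:
        def job() -> None:
            try:
                block_bests[(bi, bj)] = _run_block(cache, scorer, bi, bj)
            except Exception as exc:
                raise EngineError(
                    f"cell scoring failed in block ({bi}, {bj})") from exc
        return job

    for diagonal in wavefront_diagonals(k):
        jobs = [make_job(bi, bj) for bi, bj in diagonal]
        if sched is not None:
            sched.map_blocks(jobs)
        else:
            for job in jobs:
                job()

    if params.mode is Mode.GLOBAL:
        best = (int(cache.h_rows[k, lb]), la, lb)
    else:
        best = (0, 0, 0)
        for bi in range(k):
            for bj in range(k):
                s, i, j = block_bests[(bi, bj)]
                if s > best[0] or (s == best[0] and s > 0
                                   and (i, j) < (best[1], best[2])):
                    best = (s, i, j)
    _check_int32(best[0])
    cache.best_score, cache.best_i, cache.best_j = best
    return cache, best


# ---------------------------------------------------------------------------
# Traceback

_STATE_H, _STATE_E, _STATE_F = 0, 1, 2

#: Move symbols: D = diagonal (residue-residue), U = up (consume a, gap in b),
#: L = left (consume b, gap in a).
MOVE_DIAG, MOVE_UP, MOVE_LEFT = "D", "U", "L"


def traceback(cache: GridCache, scorer, start: tuple[int, int] | None = None
              ) -> tuple[list[str], tuple[int, int], tuple[int, int]]:
    """Walk the optimal path through cached boundaries.

    Block interiors are recomputed on demand from their cached edges.  Returns
    ``(moves, origin, end)`` with moves in forward order; ``origin`` and
    ``end`` are 0-based DP coordinates (origin exclusive of the first aligned
    residue pair, end inclusive).

    Tie-breaks: diagonal > vertical (gap in b) > horizontal (gap in a); inside
    a gap state, closing the gap is preferred over extending it.
    """
    la, lb = cache.len_a, cache.len_b
    if scorer.len_a != la or scorer.len_b != lb:
        raise EngineError(
            f"cache built for {la}x{lb} does not match scorer "
            f"{scorer.len_a}x{scorer.len_b}")
    local = cache.mode is Mode.LOCAL
    if start is None:
        start = (cache.best_i, cache.best_j) if local else (la, lb)
    i, j = start
    if not (0 <= i <= la and 0 <= j <= lb):
        raise EngineError(f"traceback start {start} outside the DP grid")
    if local and cache.best_score <= 0:
        return [], (i, j), (i, j)

    rb, cb = cache.row_bounds, cache.col_bounds
    goa, gea = scorer.gap_open_a, scorer.gap_ext_a
    gob, geb = scorer.gap_open_b, scorer.gap_ext_b
    moves: list[str] = []
    state = _STATE_H
    block = None
    H = E = F = None
    rs = re = cs = ce = -1

    while True:
        if i == 0 and j == 0:
            break
        if local and state == _STATE_H and (i == 0 or j == 0):
            break  # H is zero all along the local boundary
        if i == 0:
            moves.extend([MOVE_LEFT] * j)
            j = 0
            break
        if j == 0:
            moves.extend([MOVE_UP] * i)
            i = 0
            break
        bi = int(np.searchsorted(rb, i, side="left")) - 1
        bj = int(np.searchsorted(cb, j, side="left")) - 1
        if block != (bi, bj):
            block = (bi, bj)
            rs, re = int(rb[bi]), int(rb[bi + 1])
            cs, ce = int(cb[bj]), int(cb[bj + 1])
            H, E, F, _ = _run_block(cache, scorer, bi, bj, keep_interior=True)
            sub = scorer.sub_block(rs, re, cs, ce)
        li, lj = i - rs, j - cs
        while li > 0 and lj > 0:
            if state == _STATE_H:
                h = H[li, lj]
                if local and h == 0:
                    moves.reverse()
                    return moves, (i, j), start
                if h == H[li - 1, lj - 1] + sub[li - 1, lj - 1]:
                    moves.append(MOVE_DIAG)
                    i -= 1
                    j -= 1
                    li -= 1
                    lj -= 1
                elif h == F[li, lj]:
                    state = _STATE_F
                elif h == E[li, lj]:
                    state = _STATE_E
                else:
                    raise EngineError(
                        f"no predecessor for H at ({i}, {j}); cache and "
                        "inputs disagree")
            elif state == _STATE_F:
                moves.append(MOVE_UP)
                if F[li, lj] == H[li - 1, lj] - goa[i - 1]:
                    state = _STATE_H
                elif F[li, lj] == F[li - 1, lj] - gea[i - 1]:
                    pass
                else:
                    raise EngineError(
                        f"no predecessor for F at ({i}, {j}); cache and "
                        "inputs disagree")
                i -= 1
                li -= 1
            else:
                moves.append(MOVE_LEFT)
                if E[li, lj] == H[li, lj - 1] - gob[j - 1]:
                    state = _STATE_H
                elif E[li, lj] == E[li, lj - 1] - geb[j - 1]:
                    pass
                else:
                    raise EngineError(
                        f"no predecessor for E at ({i}, {j}); cache and "
                        "inputs disagree")
                j -= 1
                lj -= 1

    moves.reverse()
    return moves, (i, j), start


def align(scorer, params: FastLsaParams, sched=None):
    """Forward fill plus traceback in one call.

    Returns ``(score, moves, origin, end)`` with the score in DP units.
    """
    cache, best = forward_fill(scorer, params, sched=sched)
    moves, origin, end = traceback(cache, scorer)
    return best[0], moves, origin, end


def moves_to_strings(a: str, b: str, moves: Sequence[str],
                     origin: tuple[int, int]) -> tuple[str, str]:
    """Render a move path over two residue strings as gapped rows."""
    i, j = origin
    out_a: list[str] = []
    out_b: list[str] = []
    for mv in moves:
        if mv == MOVE_DIAG:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif mv == MOVE_UP:
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
    return "".join(out_a), "".join(out_b)
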