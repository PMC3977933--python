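"""Two-level work scheduling over a fixed worker pool.

The pool is partitioned into rectangular *geometries*: forward (F) geometries
fill DP grids, backward (B) geometries run tracebacks.  A geometry is a named
capacity sub-pool with one designated controller worker, not pinned hardware;
the contract is capacity plus mutual exclusivity.  A high-level overseer
distributes independent pairwise jobs across geometries (level 1), while a
single blocked alignment is spread over workers along wave-front anti-diagonals
(level 2).  All user-visible results are independent of the worker count, the
layout, and dispatch interleaving; forward and backward jobs communicate only
through the serialized grid cache.
"""

from __future__ import annotations

import enum
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence


class GeometryClass(enum.Enum):
    FORWARD = "F"
    BACKWARD = "B"


@dataclass(frozen=True)
class Geometry:
    """A rectangular worker sub-pool; worker 0 acts as the controller."""

    rows: int
    cols: int
    cls: GeometryClass
    gid: str

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("geometry shape must be positive")
        if self.worker_count < 2:
            raise ValueError(
                "a runnable geometry needs at least two workers "
                "(controller + one worker)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def worker_count(self) -> int:
        return self.rows * self.cols

    @property
    def controller(self) -> int:
        return 0


@dataclass
class GeometryLayout:
    """A partition of the distributable pool into geometries."""

    pool_size: int
    geometries: list[Geometry]
    reserved: int = 4

    def __post_init__(self) -> None:
        used = sum(g.worker_count for g in self.geometries)
        if used > self.pool_size:
            raise ValueError(
                f"geometries use {used} workers, pool holds {self.pool_size}")

    def forward(self) -> list[Geometry]:
        return [g for g in self.geometries if g.cls is GeometryClass.FORWARD]

    def backward(self) -> list[Geometry]:
        return [g for g in self.geometries if g.cls is GeometryClass.BACKWARD]

    @property
    def worker_total(self) -> int:
        return sum(g.worker_count for g in self.geometries)


def select_geometry_layout(n_jobs: int, pool_size: int = 60) -> GeometryLayout:
    """Static layout for a batch of pairwise jobs.

    On the reference 60-worker pool: four forward 7x2 geometries plus two
    backward 2x1 geometries, except for batches of 5-8 jobs where eight
    forward 7x1 geometries avoid a second batch with idle geometries (backward
    jobs then reuse freed forward geometries).  Smaller pools scale the same
    pattern down proportionally.
    """
    if n_jobs < 1:
        raise ValueError("need at least one pending job")
    if pool_size < 2:
        raise ValueError("pool too small for any runnable geometry")

    if 5 <= n_jobs <= 8 and pool_size >= 16:
        size = pool_size // 8
        geoms = [Geometry(size, 1, GeometryClass.FORWARD, f"F-{t:02d}")
                 for t in range(8)]
        return GeometryLayout(pool_size=pool_size, geometries=geoms)

    n_back = 2 if pool_size >= 32 else (1 if pool_size >= 6 else 0)
    remaining = pool_size - 2 * n_back
    n_fwd = min(4, max(1, remaining // 4))
    size = remaining // n_fwd
    if size % 2 == 0 and size >= 4:
        shape = (size // 2, 2)
    else:
        shape = (size, 1)
    geoms = [Geometry(shape[0], shape[1], GeometryClass.FORWARD, f"F-{t:02d}")
             for t in range(n_fwd)]
    geoms += [Geometry(2, 1, GeometryClass.BACKWARD, f"B-{t:02d}")
              for t in range(n_back)]
    return GeometryLayout(pool_size=pool_size, geometries=geoms)


@dataclass
class PairJob:
    """One decoupled pairwise alignment: forward produces grid-cache bytes,
    backward consumes them."""

    job_id: str
    forward: Callable[[], bytes]
    backward: Callable[[bytes], Any]


@dataclass
class JobLedger:
    """Bookkeeping of pending/running/done jobs and dispatch history."""

    pending: set = field(default_factory=set)
    running: set = field(default_factory=set)
    done: set = field(default_factory=set)
    history: list = field(default_factory=list)
    _lock: threading.Lock = field(default_factory=threading.Lock, repr=False)

    def record(self, job_id: str, geometry: str, event: str) -> None:
        with self._lock:
            self.history.append((job_id, geometry, event, time.monotonic()))
            if event == "forward-start":
                self.pending.discard(job_id)
                self.running.add(job_id)
            elif event == "backward-done":
                self.running.discard(job_id)
                self.done.add(job_id)


class Scheduler:
    """Portable overseer: a worker pool with geometry bookkeeping.

    ``workers`` is the number of OS threads actually used; geometries model
    the capacity partition.  With ``workers=1`` everything runs serially in a
    deterministic row-major order.
    """

    def __init__(self, workers: int = 1, pool_size: int = 60,
                 reserved: int = 4, layout: GeometryLayout | None = None):
        if workers < 1:
            raise ValueError("need at least one worker")
        self.workers = workers
        self.pool_size = pool_size
        self.reserved = reserved
        self.layout_override = layout
        self.last_ledger: JobLedger | None = None

    # -- level 1: independent pairwise jobs --------------------------------

    def run_pairwise_stage(self, jobs: Sequence[PairJob],
                           layout: GeometryLayout | None = None) -> list[Any]:
        """Run every job exactly once; results ordered as submitted.

        Each forward geometry processes its round-robin share in order; the
        produced cache bytes are handed to a backward geometry (reusing the
        forward one when the layout has none).  A failing job is retried once.
        """
        if not jobs:
            return []
        layout = layout or self.layout_override or select_geometry_layout(
            len(jobs), self.pool_size)
        fwd = layout.forward()
        if not fwd:
            raise ValueError("layout has no forward geometries")
        bwd = layout.backward() or fwd

        ledger = JobLedger(pending={j.job_id for j in jobs})
        self.last_ledger = ledger
        results: list[Any] = [None] * len(jobs)

        def run_one(idx: int, job: PairJob) -> None:
            fg = fwd[idx % len(fwd)]
            bg = bwd[idx % len(bwd)]
            for attempt in (0, 1):
                try:
                    ledger.record(job.job_id, fg.gid, "forward-start")
                    blob = job.forward()
                    ledger.record(job.job_id, fg.gid, "forward-done")
                    ledger.record(job.job_id, bg.gid, "backward-start")
                    results[idx] = job.backward(blob)
                    ledger.record(job.job_id, bg.gid, "backward-done")
                    return
                except Exception:
                    if attempt == 1:
                        raise
                    ledger.record(job.job_id, fg.gid, "retry")

        lanes: list[list[tuple[int, PairJob]]] = [[] for _ in fwd]
        for idx, job in enumerate(jobs):
            lanes[idx % len(fwd)].append((idx, job))

        def run_lane(lane: list[tuple[int, PairJob]]) -> None:
            for idx, job in lane:
                run_one(idx, job)

        n_threads = min(self.workers, len(fwd))
        if n_threads <= 1:
            for lane in lanes:
                run_lane(lane)
        else:
            with ThreadPoolExecutor(max_workers=n_threads) as pool:
                list(pool.map(run_lane, lanes))
        return results

    # -- level 2: wave-front execution of one blocked task ------------------

    def map_blocks(self, jobs: Sequence[Callable[[], None]]) -> None:
        """Execute one anti-diagonal of block jobs; barrier on completion."""
        if self.workers <= 1 or len(jobs) <= 1:
            for job in jobs:
                job()
            return
        with ThreadPoolExecutor(
                max_workers=min(self.workers, len(jobs))) as pool:
            futures = [pool.submit(job) for job in jobs]
            for fut in futures:
                fut.result()

    def run_wavefront(self, scorer, params):
        """Run one blocked forward fill under this scheduler's worker pool."""
        from . import fastlsa

        return fastlsa.forward_fill(scorer, params, sched=self)


def runnable_blocks(k: int, d: int) -> int:
    """How many blocks of a k x k grid are runnable on anti-diagonal d."""
    if not 0 <= d <= 2 * k - 2:
        raise ValueError(f"diagonal {d} outside [0, {2 * k - 2}]")
    return min(d + 1, k, 2 * k - 1 - d)
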