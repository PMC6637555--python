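"""Four-phase end-to-end search with pipelined chunk transfer.

Phases: (1) load inputs and partition spectra into chunks via the
scheduler; (2) the unrefined search — precursor-window candidate
retrieval for every spectrum; (3) per-chunk fragment scoring on a worker
pool, with chunks moved through a pair of bounded circular queues
(capacity 2 realizes double buffering: one chunk is in flight while
another is being scored); (4) deterministic merging and report writing.

The final report is identical whatever the worker count or chunking:
scoring one spectrum is independent of every other, and the merge orders
globally by (source_index, rank).
"""

from __future__ import annotations

import logging
import os
import threading
import time
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Iterator, Sequence

import numpy as np

from .config import SearchConfig
from .digestion import PeptideIndex, build_peptide_index
from .formats_io import Spectrum, read_fasta, read_mgf, write_psm_report
from .scheduler import (
    Chunk,
    WorkerModel,
    effective_weight,
    partition,
    sample_probe,
)
from .scoring import SCORERS, PSM, CandidateWindow, candidate_window

log = logging.getLogger(__name__)


class PhaseError(RuntimeError):
    """An error in one pipeline phase, tagged with the phase name."""


class QueueClosed(RuntimeError):
    pass


class WorkerDeath(RuntimeError):
    """Raised inside a worker to simulate its death mid-chunk."""


_SENTINEL = object()


class BoundedQueue:
    """Fixed-capacity circular queue with head/tail counters.

    The buffer holds ``capacity`` slots; monotonically increasing head
    (next read) and tail (next write) counters determine fullness
    (tail − head == capacity) and emptiness (tail == head), exactly as in
    a memory-mapped ring. ``put`` blocks while full, ``get`` while empty.
    Enqueue/dequeue totals are kept for conservation checks.
    """

    def __init__(self, capacity: int):
        if capacity < 2:
            raise ValueError("capacity must be >= 2 (double buffering)")
        self.capacity = capacity
        self._buf: list[Any] = [None] * capacity
        self.head = 0
        self.tail = 0
        self.n_enqueued = 0
        self.n_dequeued = 0
        self._lock = threading.Lock()
        self._not_full = threading.Condition(self._lock)
        self._not_empty = threading.Condition(self._lock)

    def put(self, item: Any) -> None:
        with self._not_full:
            while self.tail - self.head == self.capacity:
                self._not_full.wait()
            self._buf[self.tail % self.capacity] = item
            self.tail += 1
            self.n_enqueued += 1
            self._not_empty.notify()

    def get(self) -> Any:
        with self._not_empty:
            while self.tail == self.head:
                self._not_empty.wait()
            item = self._buf[self.head % self.capacity]
            self._buf[self.head % self.capacity] = None
            self.head += 1
            self.n_dequeued += 1
            self._not_full.notify()
            return item

    @property
    def in_flight(self) -> int:
        with self._lock:
            return self.tail - self.head


@dataclass
class BoundedQueuePair:
    """Request queue (chunks to workers) + response queue (results back)."""

    request: BoundedQueue
    response: BoundedQueue

    @classmethod
    def with_capacity(cls, capacity: int = 2) -> "BoundedQueuePair":
        return cls(BoundedQueue(capacity), BoundedQueue(capacity))


def pipelined_transfer(
    chunks: Iterable[Any],
    process_fn: Callable[[Any], Any],
    n_workers: int,
    queues: BoundedQueuePair | None = None,
    fail_plan: dict[int, int] | None = None,
) -> Iterator[tuple[Any, Any]]:
    """Stream chunks through a worker pool over bounded queues.

    A producer thread feeds the request queue while workers score and push
    to the response queue, so the next chunk is in transit while the
    current one is processed; at most ``capacity`` chunks are in flight
    per queue. Yields (chunk, result) pairs in completion order.

    ``fail_plan`` maps worker id → number of chunks after which that
    worker dies (raising mid-chunk). A dying worker requeues its in-flight
    chunk before exiting, so every chunk is still processed exactly once.
    """
    chunk_list = list(chunks)
    if queues is None:
        queues = BoundedQueuePair.with_capacity(2)
    if not chunk_list:
        return
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")

    dead: set[int] = set()
    dead_lock = threading.Lock()

    def worker(wid: int) -> None:
        n_done = 0
        while True:
            msg = queues.request.get()
            if msg is _SENTINEL:
                return
            try:
                if fail_plan and wid in fail_plan and n_done >= fail_plan[wid]:
                    raise WorkerDeath(f"worker {wid} died")
                result = process_fn(msg)
            except Exception:
                # supervised requeue: the chunk goes back for a live worker
                with dead_lock:
                    dead.add(wid)
                queues.request.put(msg)
                return
            n_done += 1
            queues.response.put((msg, result))

    threads = [
        threading.Thread(target=worker, args=(wid,), daemon=True, name=f"sdp-worker-{wid}")
        for wid in range(n_workers)
    ]
    for t in threads:
        t.start()

    def producer() -> None:
        for ch in chunk_list:
            queues.request.put(ch)

    feeder = threading.Thread(target=producer, daemon=True, name="sdp-feeder")
    feeder.start()

    try:
        for _ in range(len(chunk_list)):
            yield queues.response.get()
    finally:
        feeder.join()
        with dead_lock:
            n_live = n_workers - len(dead)
        for _ in range(n_live):
            queues.request.put(_SENTINEL)
        for t in threads:
            t.join(timeout=30)


def merge_results(per_chunk_results: Sequence[Sequence[PSM]]) -> list[PSM]:
    """Merge per-chunk PSM lists into the global order.

    Ordering is (spectrum source_index, rank) — independent of chunk
    arrival order. Duplicate (spectrum_id, rank) pairs indicate
    overlapping chunks and are an error.
    """
    merged: list[PSM] = [p for chunk in per_chunk_results for p in chunk]
    seen: set[tuple[str, int]] = set()
    for p in merged:
        key = (p.spectrum_id, p.rank)
        if key in seen:
            raise ValueError(f"duplicate (spectrum_id, rank) across chunks: {key}")
        seen.add(key)
    merged.sort(key=lambda p: (p.source_index, p.rank))
    return merged


def _subdivide(chunks: list[Chunk], target: int) -> list[Chunk]:
    """Split scheduler chunks into pipeline chunks of about ``target``."""
    out: list[Chunk] = []
    cid = 0
    for ch in chunks:
        pos = ch.start
        while pos < ch.stop:
            stop = min(pos + target, ch.stop)
            out.append(Chunk(cid, pos, stop, ch.assigned_worker))
            cid += 1
            pos = stop
    return out


@dataclass
class SearchResult:
    """Outcome of run_search: merged PSMs plus per-phase statistics."""

    psms: list[PSM]
    n_spectra: int
    n_index_entries: int
    n_chunks: int
    phase_seconds: dict[str, float] = field(default_factory=dict)


def run_search(
    config: SearchConfig,
    fasta_path: str | os.PathLike,
    spectra_path: str | os.PathLike,
    out_path: str | os.PathLike,
) -> SearchResult:
    """Execute the four-phase search and write the TSV report.

    Any phase failure aborts with a phase-tagged message and removes a
    partially written report.
    """
    config.validate()
    phase_seconds: dict[str, float] = {}

    def timed(phase: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                phase_seconds[phase] = time.perf_counter() - self_.t0
                if exc is not None and not isinstance(exc, PhaseError):
                    raise PhaseError(f"phase {phase}: {exc}") from exc
                return False

        return _T()

    try:
        # phase 1: load and partition
        with timed("1-load-partition"):
            proteins = read_fasta(fasta_path)
            spectra = read_mgf(spectra_path, default_charge=config.default_precursor_charge)
            index = build_peptide_index(proteins, config)
            rng = np.random.default_rng(config.seed)
            workers = [WorkerModel(i) for i in range(config.n_workers)]
            weights = {
                w.worker_id: effective_weight(sample_probe(w, 8, rng)) for w in workers
            }
            worker_chunks = partition(len(spectra), weights)
            chunks = _subdivide(worker_chunks, config.chunk_target_size)

        # phase 2: unrefined search — precursor-window candidate retrieval
        with timed("2-candidate-retrieval"):
            windows: list[CandidateWindow] = [
                candidate_window(
                    index, s.precursor_neutral_mass, config.precursor_tolerance_da
                )
                for s in spectra
            ]

        # phase 3: per-chunk SDP scoring on the worker pool
        with timed("3-scoring"):
            scorer = SCORERS[config.algorithm]

            def score_chunk(chunk: Chunk) -> list[list[PSM]]:
                return [
                    scorer(spectra[i], index, config, window=windows[i])
                    for i in chunk.spectrum_indices
                ]

            queues = BoundedQueuePair.with_capacity(config.queue_capacity)
            per_chunk: list[list[PSM]] = []
            for _, spectrum_psms in pipelined_transfer(
                chunks, score_chunk, config.n_workers, queues
            ):
                per_chunk.extend(spectrum_psms)

        # phase 4: sort, merge and write the results document
        with timed("4-merge-report"):
            merged = merge_results(per_chunk)
            write_psm_report(merged, out_path)
    except PhaseError:
        if os.path.exists(out_path):
            os.remove(out_path)
        raise

    for phase, secs in phase_seconds.items():
        log.info("phase %s: %.3f s", phase, secs)
    return SearchResult(
        psms=merged,
        n_spectra=len(spectra),
        n_index_entries=len(index),
        n_chunks=len(chunks),
        phase_seconds=phase_seconds,
    )
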