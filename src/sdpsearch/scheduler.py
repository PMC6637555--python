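"""Dynamic feedback task scheduling for heterogeneous workers.

Spectra are divided into chunks and assigned to workers in proportion to a
per-worker performance factor built from a sample probe (throughput) and
load statistics (CPU utilization, run-queue length, memory utilization).
During execution a feedback loop runs on every chunk-completion report:
observed throughput is folded into the weight by geometric smoothing
(w ← α·w_old + (1−α)·w_observed) and unstarted chunks are moved away from
the worker with the largest projected finish time whenever the projected
imbalance exceeds the threshold. Started chunks never move, so no spectrum
is duplicated or lost.

All tests and simulations use :class:`WorkerModel` with simulated load
sources; live /proc probing (Linux) sits behind the same interface for the
CLI ``probe`` command.
"""

from __future__ import annotations

import os
import time
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np


class DeadWorkerError(RuntimeError):
    """Raised when a probe targets a worker that is not alive."""


def mem_usage(mt: float, mf: float, buffers: float, cached: float) -> float:
    """Memory utilization (MT − MF − Buffers − Cached) / MT, in [0, 1].

    Inputs mirror /proc/meminfo: total memory, free memory, block-device
    buffers and the file cache (cache pages are reclaimable, so they count
    as available).
    """
    if mt <= 0:
        raise ValueError("MT must be > 0")
    if min(mf, buffers, cached) < 0:
        raise ValueError("MF, Buffers and Cached must be >= 0")
    if mf + buffers + cached > mt:
        raise ValueError("free + buffers + cached exceeds total memory")
    return (mt - mf - buffers - cached) / mt


@dataclass(frozen=True)
class PerformanceFactor:
    """A worker's composite load descriptor from one sample probe."""

    cpu_utilization: float
    avg_queue_length: float
    mem_usage: float
    throughput_estimate: float  # work units per second

    def __post_init__(self) -> None:
        if not 0.0 <= self.cpu_utilization <= 1.0:
            raise ValueError("cpu_utilization must lie in [0, 1]")
        if not 0.0 <= self.mem_usage <= 1.0:
            raise ValueError("mem_usage must lie in [0, 1]")
        if self.avg_queue_length < 0:
            raise ValueError("avg_queue_length must be >= 0")
        if self.throughput_estimate <= 0:
            raise ValueError("throughput_estimate must be > 0 for a live worker")


@dataclass
class WorkerModel:
    """A computing node abstraction with a simulated load-stat source.

    ``speed_factor`` is the worker's relative throughput (dimensionless);
    the remaining fields are the load statistics a live probe would read
    from /proc.
    """

    worker_id: int
    speed_factor: float = 1.0
    cpu_utilization: float = 0.3
    avg_queue_length: float = 0.5
    mem_fraction_used: float = 0.4
    alive: bool = True

    def __post_init__(self) -> None:
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be > 0")


#: Relative sigma of the lognormal timing jitter a simulated probe sees.
PROBE_JITTER_SIGMA = 0.05


def sample_probe(
    worker: WorkerModel, probe_size: int, rng: np.random.Generator
) -> PerformanceFactor:
    """Run the sample test on one worker and collect its performance factor.

    The simulated probe processes ``probe_size`` unit-cost work items in
    ``probe_size / speed_factor`` seconds up to lognormal timing jitter,
    so the throughput estimate tracks the true speed.
    """
    if probe_size < 1:
        raise ValueError("probe batch must be non-empty")
    if not worker.alive:
        raise DeadWorkerError(f"worker {worker.worker_id} is dead")
    elapsed = probe_size / worker.speed_factor
    elapsed *= float(np.exp(rng.normal(0.0, PROBE_JITTER_SIGMA)))
    return PerformanceFactor(
        cpu_utilization=worker.cpu_utilization,
        avg_queue_length=worker.avg_queue_length,
        mem_usage=worker.mem_fraction_used,
        throughput_estimate=probe_size / elapsed,
    )


def effective_weight(factor: PerformanceFactor) -> float:
    """Partitioning weight: probed throughput with an overload penalty.

    When CPU utilization exceeds 0.9 the worker is treated as overloaded
    and its weight is scaled by (1 − mem_usage) and divided by
    (1 + avg_queue_length) — a monotone, bounded combination of the three
    load statistics.
    """
    w = factor.throughput_estimate
    if factor.cpu_utilization > 0.9:
        w *= (1.0 - factor.mem_usage)
        w /= (1.0 + factor.avg_queue_length)
    return w


@dataclass(frozen=True)
class Chunk:
    """A contiguous range of spectrum indices assigned to one worker."""

    chunk_id: int
    start: int
    stop: int  # half-open
    assigned_worker: int

    @property
    def spectrum_indices(self) -> range:
        return range(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


def partition(spectra_count: int, weights: dict[int, float]) -> list[Chunk]:
    """Split ``spectra_count`` spectra into one contiguous chunk per worker,
    sized proportionally to the weights.

    Rounding uses the largest-remainder rule with ties broken by worker id,
    so the partition is deterministic, disjoint, complete and
    scale-invariant in the weights.
    """
    if spectra_count < 0:
        raise ValueError("spectra_count must be >= 0")
    if not weights:
        raise ValueError("no live workers to partition over")
    ids = sorted(weights)
    total_w = sum(weights[i] for i in ids)
    if total_w <= 0:
        raise ValueError("weights must sum to > 0")
    shares = [spectra_count * weights[i] / total_w for i in ids]
    sizes = [int(s) for s in shares]
    remainder = spectra_count - sum(sizes)
    order = sorted(range(len(ids)), key=lambda j: (-(shares[j] - sizes[j]), ids[j]))
    for j in order[:remainder]:
        sizes[j] += 1
    chunks: list[Chunk] = []
    pos = 0
    for cid, (wid, size) in enumerate(zip(ids, sizes)):
        chunks.append(Chunk(cid, pos, pos + size, wid))
        pos += size
    return chunks


def load_imbalance(completion_loads: list[float]) -> float:
    """(max load − mean load) / mean load; 0 for all-equal or all-zero."""
    if not completion_loads:
        raise ValueError("at least one worker required")
    if min(completion_loads) < 0:
        raise ValueError("loads must be >= 0")
    mean = sum(completion_loads) / len(completion_loads)
    if mean == 0:
        return 0.0
    return (max(completion_loads) - mean) / mean


@dataclass
class SchedulerState:
    """Mutable assignment state the feedback loop operates on.

    ``pending`` holds unstarted chunk ids per worker; ``free_time`` is the
    simulation clock at which each worker becomes idle; ``weights`` are the
    smoothed performance weights (work units per second).
    """

    weights: dict[int, float]
    pending: dict[int, deque]
    free_time: dict[int, float]
    imbalance_threshold: float = 0.08
    n_moves: int = 0

    def projected_finish(self) -> dict[int, float]:
        return {
            wid: self.free_time[wid] + len(self.pending[wid]) / self.weights[wid]
            for wid in self.weights
        }


def feedback_rebalance(state: SchedulerState) -> int:
    """One feedback step: shed unstarted chunks from the most-backlogged
    worker to the least-backlogged one while the projected imbalance
    exceeds the threshold. Returns the number of chunks moved.

    Only unstarted chunks move, from the back of the donor's queue to the
    back of the receiver's, so started work is never duplicated.
    """
    moved = 0
    while True:
        proj = state.projected_finish()
        mean = sum(proj.values()) / len(proj)
        if mean <= 0 or (max(proj.values()) - mean) / mean <= state.imbalance_threshold:
            break
        donor = max(proj, key=lambda w: (proj[w], w))
        receiver = min(proj, key=lambda w: (proj[w], w))
        if donor == receiver or not state.pending[donor]:
            break
        # moving one chunk must strictly reduce the donor/receiver gap
        gain = 1.0 / state.weights[donor] + 1.0 / state.weights[receiver]
        if proj[donor] - proj[receiver] <= gain:
            break
        state.pending[receiver].append(state.pending[donor].pop())
        moved += 1
    state.n_moves += moved
    return moved


@dataclass
class ScheduleResult:
    """Outcome of one simulated run."""

    busy: dict[int, float]  # per-worker total processing time
    processed: dict[int, list[int]]  # chunk ids in completion order
    initial_sizes: dict[int, int]
    imbalance: float
    n_moves: int


def simulate_schedule(
    chunk_costs: np.ndarray,
    workers: list[WorkerModel],
    *,
    alpha: float = 0.5,
    imbalance_threshold: float = 0.08,
    feedback: bool = True,
    seed: int = 0,
    probe_size: int = 8,
    speed_change: dict[int, tuple[int, float]] | None = None,
) -> ScheduleResult:
    """Event-driven simulation of the full scheduling loop.

    Probe → proportional partition → execution with per-completion
    feedback. ``speed_change`` maps a worker id to (after_n_completed,
    multiplier) to model a mid-run slowdown. Dead workers are excluded
    up front.
    """
    rng = np.random.default_rng(seed)
    live = [w for w in workers if w.alive]
    if not live:
        raise ValueError("no live workers")
    factors = {w.worker_id: sample_probe(w, probe_size, rng) for w in live}
    weights = {wid: effective_weight(f) for wid, f in factors.items()}
    chunks = partition(len(chunk_costs), weights)

    speed = {w.worker_id: w.speed_factor for w in live}
    pending = {w.worker_id: deque() for w in live}
    for ch in chunks:
        pending[ch.assigned_worker].extend(range(ch.start, ch.stop))
    initial_sizes = {wid: len(q) for wid, q in pending.items()}
    state = SchedulerState(
        weights=dict(weights),
        pending=pending,
        free_time={w.worker_id: 0.0 for w in live},
        imbalance_threshold=imbalance_threshold,
    )
    busy = {w.worker_id: 0.0 for w in live}
    processed: dict[int, list[int]] = {w.worker_id: [] for w in live}
    completed = {w.worker_id: 0 for w in live}

    while any(state.pending[wid] for wid in state.pending):
        wid = min(
            (w for w in state.pending if state.pending[w]),
            key=lambda w: (state.free_time[w], w),
        )
        job = state.pending[wid].popleft()
        dt = float(chunk_costs[job]) / speed[wid]
        start_at = state.free_time[wid]
        state.free_time[wid] = start_at + dt
        busy[wid] += dt
        processed[wid].append(job)
        completed[wid] += 1
        if speed_change and wid in speed_change:
            after_n, mult = speed_change[wid]
            if completed[wid] == after_n:
                speed[wid] *= mult
        if feedback:
            observed = completed[wid] / busy[wid]  # chunks per second
            state.weights[wid] = alpha * state.weights[wid] + (1 - alpha) * observed
            feedback_rebalance(state)

    return ScheduleResult(
        busy=busy,
        processed=processed,
        initial_sizes=initial_sizes,
        imbalance=load_imbalance(list(busy.values())),
        n_moves=state.n_moves,
    )


# --- live /proc probing (Linux), behind the same WorkerModel interface ----

def live_performance_factor(sample_interval: float = 0.1) -> PerformanceFactor:
    """Probe the local host through /proc (Linux only).

    CPU utilization from two /proc/stat samples, run-queue length per core
    from /proc/loadavg, memory utilization from /proc/meminfo.
    """
    def cpu_times() -> tuple[float, float]:
        with open("/proc/stat") as fh:
            parts = fh.readline().split()[1:]
        vals = [float(v) for v in parts]
        idle = vals[3] + (vals[4] if len(vals) > 4 else 0.0)
        return sum(vals), idle

    t0, i0 = cpu_times()
    time.sleep(sample_interval)
    t1, i1 = cpu_times()
    dtotal, didle = t1 - t0, i1 - i0
    cpu = max(0.0, min(1.0, 1.0 - didle / dtotal)) if dtotal > 0 else 0.0

    with open("/proc/loadavg") as fh:
        load1 = float(fh.read().split()[0])
    queue = load1 / max(os.cpu_count() or 1, 1)

    info: dict[str, float] = {}
    with open("/proc/meminfo") as fh:
        for line in fh:
            key, _, rest = line.partition(":")
            info[key] = float(rest.split()[0])
    mem = mem_usage(
        info["MemTotal"], info["MemFree"], info.get("Buffers", 0.0), info.get("Cached", 0.0)
    )
    # throughput on the live host is unknown before a real probe run
    return PerformanceFactor(cpu, queue, mem, throughput_estimate=1.0)
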