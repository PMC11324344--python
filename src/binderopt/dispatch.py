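"""Producer/Consumer task dispatch with scheduling-invariant results.

Sampling and scoring tasks of an epoch are queued and claimed by a bounded
worker pool in submission (first come, first served) order.  Determinism is a
hard contract: every task derives its randomness from its own substream seed,
never from worker identity or timing, so the result mapping is bit-identical
for any worker count.
"""

from __future__ import annotations

import logging
import traceback
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable, Hashable, Mapping, Optional, Sequence

import numpy as np

log = logging.getLogger("binderopt.dispatch")


@dataclass(frozen=True)
class TaskSpec:
    """One self-contained unit of work.

    ``payload`` must close over every input (no shared mutable state); when
    ``substream_seed`` is set the callable receives an independent
    ``numpy.random.Generator`` seeded from it as keyword ``rng``.
    """

    task_id: Hashable
    fn: Callable[..., Any]
    payload: Mapping[str, Any] = field(default_factory=dict)
    substream_seed: Optional[int] = None


@dataclass(frozen=True)
class TaskResult:
    task_id: Hashable
    ok: bool
    value: Any = None
    error: Optional[str] = None


def _execute(task: TaskSpec) -> TaskResult:
    kwargs = dict(task.payload)
    if task.substream_seed is not None:
        kwargs["rng"] = np.random.default_rng(task.substream_seed)
    try:
        value = task.fn(**kwargs)
        return TaskResult(task.task_id, ok=True, value=value)
    except Exception as exc:  # a failing task must not abort the batch
        return TaskResult(
            task.task_id, ok=False,
            error="".join(traceback.format_exception_only(type(exc), exc)).strip(),
        )


def run_tasks(tasks: Sequence[TaskSpec], n_workers: int = 1) -> dict[Hashable, TaskResult]:
    """Drain ``tasks`` over ``n_workers`` workers; FIFO claim order.

    Returns ``{task_id: TaskResult}``; failures are recorded, not raised.
    The mapping is identical for every ``n_workers`` >= 1.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    ids = [t.task_id for t in tasks]
    if len(set(ids)) != len(ids):
        raise ValueError("task ids must be unique within a batch")
    if not tasks:
        return {}
    if n_workers == 1:
        results = [_execute(t) for t in tasks]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            # submission order == queue order == claim order (FIFO)
            futures = [pool.submit(_execute, t) for t in tasks]
            results = [f.result() for f in futures]
    for r in results:  # logged after the drain so log order is scheduling-free
        log.debug("task %s -> %s", r.task_id, "ok" if r.ok else f"FAILED: {r.error}")
    return {r.task_id: r for r in results}
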