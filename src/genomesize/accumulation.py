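"""Mutation-accumulation experiments: many independent single-cell lines.

Each line is one genome propagated through repeated single-individual
bottlenecks, so selection is disabled and the spontaneous mutation
dynamics is exposed.  The module runs many such lines with independent
random substreams, and reduces them to the summary statistics a
mutation-accumulation study reports: the fraction of lines that shrank,
the median DNA loss, and per-type event counts and sizes.

Two engines produce identical laws:

* :func:`run_line` — the reference per-generation loop, with optional full
  event logging (replayable bit-exactly);
* an event-skipping engine used by :func:`run_experiment` and
  :func:`run_until_floor` — because the per-generation event count is
  Poisson with mean ``mu * s`` (often far below 1), generations without
  events are skipped in O(1) by drawing the geometric gap to the next
  mutation-bearing generation.  This is what makes 250,000-generation
  runs desk-scale.

Per-generation state is exposed (`run_line` trajectories and event logs),
so a user-supplied selection step can be interposed between generations;
no selection operator is provided here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generation_process import one_generation
from .mutation_model import (
    EVENT_TYPES,
    IndelSizeModel,
    MutationEvent,
    MutationRates,
    RearrangementSizeModel,
    _transition,
)

__all__ = [
    "ExperimentConfig",
    "LineTrajectory",
    "ExperimentSummary",
    "run_line",
    "run_experiment",
    "run_until_floor",
    "summarize_events",
    "replay_sizes",
    "verify_replay",
]

_CODES = np.arange(4)


@dataclass(frozen=True)
class ExperimentConfig:
    """Mutation rates plus the two size laws — everything but the seeds."""

    rates: MutationRates
    indel: IndelSizeModel
    rearrangements: RearrangementSizeModel

    @classmethod
    def mutation_accumulation(cls, kind: str = "uniform") -> "ExperimentConfig":
        """The default bacterial setup: enterobacterial rates, indels
        uniform on 1–40 bp, rearrangement sizes ``uniform`` or
        ``truncated_lognormal`` (the fitted enterobacterial law)."""
        if kind == "uniform":
            rearr = RearrangementSizeModel.uniform()
        elif kind in ("lognormal", "truncated_lognormal"):
            rearr = RearrangementSizeModel.truncated_lognormal()
        else:
            raise ValueError(f"unknown rearrangement kind {kind!r}")
        return cls(
            rates=MutationRates.bacterial_defaults(),
            indel=IndelSizeModel.uniform(40),
            rearrangements=rearr,
        )


@dataclass
class LineTrajectory:
    """Per-generation genome sizes of one line, plus its typed event log.

    ``sizes[0]`` is the initial size; ``sizes[t+1]`` is the end of
    generation ``t``.  ``events`` holds ``(generation, MutationEvent)``
    pairs in application order.
    """

    line_id: int
    sizes: np.ndarray
    events: list[tuple[int, MutationEvent]] = field(default_factory=list)
    stop_reason: str = "completed"  # or "hit_floor"


@dataclass
class ExperimentSummary:
    """Summary of a mutation-accumulation experiment over ``n_lines`` lines.

    Medians of event sizes are medians *over lines* of the per-line mean
    absolute event size; lines without events of a type are excluded from
    that type's size median (their mean is undefined) but contribute count
    0 to the count median.  Spread is reported both as the median absolute
    deviation (MAD) and the standard deviation, since the two differ a lot
    for the heavy-tailed rearrangement sizes.
    """

    n_lines: int
    initial_size: int
    generations: int
    fraction_shrunk: float
    median_size_change: float
    median_event_count: dict[str, float]
    median_event_size: dict[str, float]
    event_count_mad: dict[str, float]
    event_count_sd: dict[str, float]
    event_size_mad: dict[str, float]
    event_size_sd: dict[str, float]
    final_sizes: np.ndarray
    event_counts: np.ndarray  # (n_lines, 4) in EVENT_TYPES order
    mean_event_sizes: np.ndarray  # (n_lines, 4), NaN where count is 0

    def table(self) -> pd.DataFrame:
        """Per-type summary as a DataFrame (rows = mutation types)."""
        return pd.DataFrame(
            {
                "median_count": self.median_event_count,
                "count_mad": self.event_count_mad,
                "count_sd": self.event_count_sd,
                "median_size": self.median_event_size,
                "size_mad": self.event_size_mad,
                "size_sd": self.event_size_sd,
            }
        ).loc[list(EVENT_TYPES)]

    def to_dict(self) -> dict:
        """JSON-serialisable scalar summary (drops the per-line arrays)."""
        return {
            "n_lines": self.n_lines,
            "initial_size": self.initial_size,
            "generations": self.generations,
            "fraction_shrunk": self.fraction_shrunk,
            "median_size_change": self.median_size_change,
            "median_event_count": self.median_event_count,
            "median_event_size": self.median_event_size,
            "event_count_mad": self.event_count_mad,
            "event_count_sd": self.event_count_sd,
            "event_size_mad": self.event_size_mad,
            "event_size_sd": self.event_size_sd,
        }


def run_line(
    initial_size: int,
    generations: int,
    config: ExperimentConfig,
    rng: np.random.Generator,
    floor: int | None = None,
    record_events: bool = True,
    line_id: int = 0,
) -> LineTrajectory:
    """Propagate one line generation by generation (reference engine).

    If ``floor`` is given, the line stops at the first generation whose end
    size drops below it (``stop_reason == "hit_floor"``).
    """
    if initial_size < 1:
        raise ValueError("initial_size must be >= 1")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    sizes = [int(initial_size)]
    events: list[tuple[int, MutationEvent]] = []
    stop = "completed"
    s = int(initial_size)
    for t in range(generations):
        outcome = one_generation(
            s, config.rates, config.indel, config.rearrangements, rng
        )
        s = outcome.end_size
        sizes.append(s)
        if record_events:
            events.extend((t, ev) for ev in outcome.events)
        if floor is not None and s < floor:
            stop = "hit_floor"
            break
    return LineTrajectory(
        line_id=line_id,
        sizes=np.asarray(sizes, dtype=np.int64),
        events=events,
        stop_reason=stop,
    )


def _poisson_ge1(lam: float, rng: np.random.Generator) -> int:
    """Sample ``N | N >= 1`` with ``N ~ Poisson(lam)`` by CDF inversion."""
    u = rng.random() * -math.expm1(-lam)
    term = lam * math.exp(-lam)
    n, cum = 1, term
    while cum < u:
        n += 1
        term *= lam / n
        cum += term
        if n > 100_000:  # pragma: no cover - numerically unreachable
            break
    return n


def _simulate_line(
    initial_size: int,
    generations: int,
    config: ExperimentConfig,
    rng: np.random.Generator,
    floor: int | None = None,
) -> tuple[int, int, str, np.ndarray, np.ndarray]:
    """Event-skipping engine for one line.

    Returns ``(final_size, end_generation, stop_reason, counts, abs_size_sums)``
    where ``counts`` and ``abs_size_sums`` are per-type accumulators in
    ``EVENT_TYPES`` order.  Distributionally identical to iterating
    :func:`one_generation`: generations with zero events leave the size
    unchanged, so only the geometric gap to the next mutation-bearing
    generation needs sampling.
    """
    rates, indel, rearr = config.rates, config.indel, config.rearrangements
    mu = rates.mu_total
    counts = np.zeros(4, dtype=np.int64)
    sums = np.zeros(4, dtype=float)
    s = int(initial_size)
    t = 0
    if mu <= 0:
        return s, generations, "completed", counts, sums
    probs = rates.type_probabilities()
    cum = np.cumsum(probs)
    while t < generations:
        lam = mu * s
        p_event = -math.expm1(-lam)
        if p_event <= 0.0:  # pragma: no cover - s >= 1 and mu > 0
            break
        gap = int(rng.geometric(p_event))
        if t + gap > generations:
            t = generations
            break
        t += gap
        n = _poisson_ge1(lam, rng)
        if n == 1:
            order = (int(np.searchsorted(cum, rng.random(), side="right")),)
        else:
            order = np.repeat(_CODES, rng.multinomial(n, probs))
            rng.shuffle(order)
        for code in order:
            post, delta = _transition(s, int(code), indel, rearr, rng)
            counts[code] += 1
            sums[code] += abs(delta)
            s = post
        if s == 0:
            s = 1
        if floor is not None and s < floor:
            return s, t, "hit_floor", counts, sums
    return s, t, "completed", counts, sums


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def run_experiment(
    n_lines: int,
    initial_size: int,
    generations: int,
    config: ExperimentConfig,
    seed,
) -> ExperimentSummary:
    """Run ``n_lines`` statistically independent lines and summarise them.

    ``seed`` is an integer (or ``numpy.random.SeedSequence``); each line
    gets its own spawned substream, so summaries are reproducible from the
    root seed alone and independent of execution order.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    children = _as_seedseq(seed).spawn(n_lines)
    finals = np.empty(n_lines, dtype=np.int64)
    counts = np.empty((n_lines, 4), dtype=np.int64)
    sums = np.empty((n_lines, 4), dtype=float)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        finals[i], _, _, counts[i], sums[i] = _simulate_line(
            initial_size, generations, config, rng
        )
    with np.errstate(invalid="ignore"):
        mean_sizes = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return _summarize(
        n_lines, int(initial_size), generations, finals, counts, mean_sizes
    )


def _mad(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan")
    return float(np.median(np.abs(x - np.median(x))))


def _summarize(n_lines, initial_size, generations, finals, counts, mean_sizes):
    shrunk = float(np.mean(finals < initial_size))  # strict: ties not shrunk
    change = float(np.median(finals.astype(float) - initial_size))
    med_count, med_size = {}, {}
    cnt_mad, cnt_sd, siz_mad, siz_sd = {}, {}, {}, {}
    for j, name in enumerate(EVENT_TYPES):
        med_count[name] = float(np.median(counts[:, j]))
        cnt_mad[name] = _mad(counts[:, j].astype(float))
        cnt_sd[name] = float(np.std(counts[:, j]))
        col = mean_sizes[:, j]
        valid = col[~np.isnan(col)]
        med_size[name] = float(np.median(valid)) if valid.size else float("nan")
        siz_mad[name] = _mad(col)
        siz_sd[name] = float(np.std(valid)) if valid.size else float("nan")
    return ExperimentSummary(
        n_lines=n_lines,
        initial_size=initial_size,
        generations=generations,
        fraction_shrunk=shrunk,
        median_size_change=change,
        median_event_count=med_count,
        median_event_size=med_size,
        event_count_mad=cnt_mad,
        event_count_sd=cnt_sd,
        event_size_mad=siz_mad,
        event_size_sd=siz_sd,
        final_sizes=finals,
        event_counts=counts,
        mean_event_sizes=mean_sizes,
    )


def run_until_floor(
    n_lines: int,
    initial_size: int,
    floor: int,
    max_generations: int,
    config: ExperimentConfig,
    seed,
) -> np.ndarray:
    """First generation at which each line drops below ``floor`` bp.

    Lines that never cross within ``max_generations`` report
    ``max_generations``.  Uses the event-skipping engine, so very long
    horizons (hundreds of thousands of generations) stay cheap.
    """
    if floor >= initial_size:
        raise ValueError("floor must be strictly below initial_size")
    children = _as_seedseq(seed).spawn(n_lines)
    crossings = np.empty(n_lines, dtype=np.int64)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        _, t, reason, _, _ = _simulate_line(
            initial_size, max_generations, config, rng, floor=floor
        )
        crossings[i] = t if reason == "hit_floor" else max_generations
    return crossings


def summarize_events(
    trajectories: list[LineTrajectory], pooled: bool = False
) -> pd.DataFrame:
    """Per-type event summary from fully logged trajectories.

    Default convention: per line, take the mean absolute size of its
    events of each type; report the median of those per-line means across
    lines ("median size of events in a line").  ``pooled=True`` instead
    pools every event of a type across lines and takes one global median.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n = len(trajectories)
    counts = np.zeros((n, 4), dtype=np.int64)
    sums = np.zeros((n, 4), dtype=float)
    pool: list[list[float]] = [[], [], [], []]
    for i, traj in enumerate(trajectories):
        for _, ev in traj.events:
            j = EVENT_TYPES.index(ev.event_type)
            counts[i, j] += 1
            sums[i, j] += abs(ev.size_change)
            if pooled:
                pool[j].append(abs(ev.size_change))
    with np.errstate(invalid="ignore"):
        mean_sizes = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    summary = _summarize(n, 0, 0, np.zeros(n, dtype=np.int64), counts, mean_sizes)
    frame = summary.table()
    if pooled:
        frame["pooled_median_size"] = [
            float(np.median(pool[j])) if pool[j] else float("nan") for j in range(4)
        ]
    return frame


def replay_sizes(traj: LineTrajectory) -> np.ndarray:
    """Recompute the per-generation sizes from the event log alone.

    Checks the chaining of every event (each pre-size must equal the
    running size) and applies the end-of-generation rewiring; the result
    must match ``traj.sizes`` bit-exactly for a well-formed log.
    """
    sizes = [int(traj.sizes[0])]
    by_gen: dict[int, list[MutationEvent]] = {}
    for t, ev in traj.events:
        by_gen.setdefault(t, []).append(ev)
    for t in range(len(traj.sizes) - 1):
        s = sizes[-1]
        for ev in by_gen.get(t, ()):
            if ev.pre_size != s:
                raise ValueError(
                    f"event log broken at generation {t}: pre_size "
                    f"{ev.pre_size} != running size {s}"
                )
            if ev.post_size != max(0, ev.pre_size + ev.size_change):
                raise ValueError(f"inconsistent event at generation {t}: {ev}")
            s = ev.post_size
        sizes.append(max(1, s))
    return np.asarray(sizes, dtype=np.int64)


def verify_replay(traj: LineTrajectory) -> None:
    """Raise if the logged events do not reproduce the trajectory exactly."""
    replayed = replay_sizes(traj)
    if not np.array_equal(replayed, traj.sizes):
        diff = int(np.nonzero(replayed != traj.sizes)[0][0])
        raise ValueError(
            f"replay diverges at generation {diff}: "
            f"{replayed[diff]} != {traj.sizes[diff]}"
        )
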