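"""NSGA-II over wiring patterns.

The genetic search operates directly on the reservoir weight matrix.  Any
subset of three objectives can be optimized simultaneously (all handled in
minimization convention internally):

- ``maximize_te`` — aggregate transfer entropy from input signals to
  RC-readout activations (negated internally),
- ``minimize_cost`` — total coupling cost sum |W_ij| D_ij,
- ``minimize_density`` — fraction of nonzero connections.

Per generation each pattern goes through the full developmental pipeline:
spectral-radius normalization (at birth), Hebbian tuning under spontaneous
activity, Hebbian readout training on the saccade series, then objective
evaluation on a validation series.  Survivors are chosen by non-dominated
sorting with crowding-distance tie-breaks; offspring are produced by 2x2
block crossover (each aligned tile inherited whole from either parent with
probability 1/2) followed, with probability ``p_mutation``, by a block
mutation that deletes the block or refills it at the initial sparsity.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .info import InfoEstimatorConfig, pattern_te
from .plasticity import HebbParams, train_readout, tune_reservoir
from .reservoir import (
    ReservoirParams,
    WiringPattern,
    init_pattern,
    init_readout_weights,
    normalize_spectral_radius,
    spectral_radius,
)
from .stimuli import StimulusSeries
from .structure import GridLayout, build_layout, evaluate_structure

OBJECTIVES = ("maximize_te", "minimize_cost", "minimize_density")


@dataclass(frozen=True)
class EvolutionConfig:
    """Search configuration.

    generations : number of selection/variation cycles (Gen).
    n_survivors : patterns preserved per generation (P).
    n_offspring : patterns newly generated per generation (Q).
    objectives : ordered subset of :data:`OBJECTIVES`.
    block_size : side of the square structural regions used by crossover and
        mutation.
    p_mutation : fraction of offspring that receive a mutation.
    p_delete : probability a mutation deletes its block rather than refilling
        it at the initial sparsity.
    n_mutated_blocks : block regions altered per mutation event.
    parent_selection : "tournament" (binary, on rank then crowding) or
        "uniform" (parents drawn uniformly from the survivors).
    """

    generations: int = 10
    n_survivors: int = 25
    n_offspring: int = 25
    objectives: tuple[str, ...] = ("maximize_te", "minimize_cost")
    block_size: int = 2
    p_mutation: float = 0.8
    p_delete: float = 0.5
    n_mutated_blocks: int = 1
    parent_selection: str = "tournament"

    def __post_init__(self) -> None:
        if self.generations < 1 or self.n_survivors < 1 or self.n_offspring < 1:
            raise ValueError("generations, n_survivors, n_offspring must be >= 1")
        if not self.objectives:
            raise ValueError("at least one objective is required")
        unknown = set(self.objectives) - set(OBJECTIVES)
        if unknown:
            raise ValueError(f"unknown objectives: {sorted(unknown)}")
        if len(set(self.objectives)) != len(self.objectives):
            raise ValueError("objectives must be distinct")
        if not (0 <= self.p_mutation <= 1 and 0 <= self.p_delete <= 1):
            raise ValueError("p_mutation and p_delete must lie in [0, 1]")
        if self.parent_selection not in ("tournament", "uniform"):
            raise ValueError(f"unknown parent_selection: {self.parent_selection!r}")


@dataclass
class EvaluatedPattern:
    """A pattern with its objective vector and descriptive metrics."""

    pattern: WiringPattern
    objectives_vector: np.ndarray
    record: dict
    rank: int | None = None
    crowding: float | None = None


@dataclass
class FrontHistory:
    """Outcome of one evolution run.

    summary : per-generation max/min/mean of every metric over the full pool
        (generations + 1 rows, generation 0 = initial population).
    archive : one row per evaluated pattern (all generations).
    population : the final pool (survivors + last offspring), ranked.
    survivors : final NSGA-II selection of ``n_survivors`` from that pool.
    patterns : id -> WiringPattern for every pattern ever evaluated.
    """

    summary: pd.DataFrame
    archive: pd.DataFrame
    population: list[EvaluatedPattern]
    survivors: list[EvaluatedPattern]
    patterns: dict[str, WiringPattern] = field(repr=False)


# ---------------------------------------------------------------------------
# NSGA-II primitives


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(points: Sequence[np.ndarray]) -> list[list[int]]:
    """Fast non-dominated sorting (minimization convention).

    Returns fronts as index lists: front 0 contains points dominated by
    none; front k points dominated only by members of earlier fronts.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    n = len(pts)
    if n == 0:
        return []
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(pts[i], pts[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif _dominates(pts[j], pts[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts = [list(np.flatnonzero(n_dominating == 0))]
    while True:
        nxt: list[int] = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        if not nxt:
            return fronts
        fronts.append(nxt)


def crowding_distance(front: Sequence[np.ndarray]) -> np.ndarray:
    """Crowding distances within one front (minimization convention).

    Boundary points per objective get infinity; interior points accumulate
    the normalized gap between their neighbors.  Objectives with zero range
    contribute nothing (degenerate-range guard).
    """
    pts = np.asarray(front, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, m = pts.shape
    if n == 0:
        raise ValueError("front must be nonempty")
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(pts[:, j], kind="stable")
        span = pts[order[-1], j] - pts[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            gaps = (pts[order[2:], j] - pts[order[:-2], j]) / span
            dist[order[1:-1]] += gaps
    return dist


def rank_population(population: list[EvaluatedPattern]) -> None:
    """Assign non-domination ranks and crowding distances in place."""
    if not population:
        return
    fronts = non_dominated_sort([p.objectives_vector for p in population])
    for rank, front in enumerate(fronts):
        dists = crowding_distance([population[i].objectives_vector for i in front])
        for i, d in zip(front, dists):
            population[i].rank = rank
            population[i].crowding = float(d)


def select_survivors(
    population: list[EvaluatedPattern], n_survivors: int
) -> list[EvaluatedPattern]:
    """Elitist NSGA-II survivor selection: whole fronts in rank order, the
    splitting front resolved by descending crowding distance."""
    rank_population(population)
    fronts = non_dominated_sort([p.objectives_vector for p in population])
    chosen: list[EvaluatedPattern] = []
    for front in fronts:
        members = [population[i] for i in front]
        if len(chosen) + len(members) <= n_survivors:
            chosen.extend(members)
        else:
            members.sort(key=lambda p: -p.crowding)
            chosen.extend(members[: n_survivors - len(chosen)])
        if len(chosen) >= n_survivors:
            break
    return chosen


# ---------------------------------------------------------------------------
# Variation operators


def _tile_blend(
    Wa: np.ndarray, Wb: np.ndarray, block_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Blend two matrices tile-by-tile; returns (child, tile_mask) where
    tile_mask[i, j] is True when the tile came from the first parent.
    Tiling is aligned and non-overlapping starting at (0, 0)."""
    n = Wa.shape[0]
    n_tiles = -(-n // block_size)
    tile_mask = rng.random((n_tiles, n_tiles)) < 0.5
    child = Wb.copy()
    for bi in range(n_tiles):
        for bj in range(n_tiles):
            if tile_mask[bi, bj]:
                sl_i = slice(bi * block_size, min((bi + 1) * block_size, n))
                sl_j = slice(bj * block_size, min((bj + 1) * block_size, n))
                child[sl_i, sl_j] = Wa[sl_i, sl_j]
    return child, tile_mask


def crossover(
    parent_a: WiringPattern,
    parent_b: WiringPattern,
    block_size: int,
    rng: np.random.Generator,
) -> WiringPattern:
    """Block crossover: every aligned ``block_size x block_size`` tile of the
    child is copied whole from one parent, chosen with probability 1/2; the
    child is then re-normalized to spectral radius 1."""
    if parent_a.W.shape != parent_b.W.shape:
        raise ValueError("parents must have identical dimensions")
    child_raw, _ = _tile_blend(parent_a.W, parent_b.W, block_size, rng)
    child = normalize_spectral_radius(child_raw)
    return parent_a.with_weights(child, new_id=f"x-{uuid.uuid4().hex[:8]}")


def _random_block_values(
    shape: tuple[int, int], sparsity: float, rng: np.random.Generator
) -> np.ndarray:
    """Fresh block content: nonzero with probability ``sparsity``, values
    Uniform[-0.5, 0.5] (the initialization distribution)."""
    mask = rng.random(shape) < sparsity
    return rng.uniform(-0.5, 0.5, shape) * mask


def mutate(
    pattern: WiringPattern,
    cfg: EvolutionConfig,
    params: ReservoirParams,
    rng: np.random.Generator,
) -> WiringPattern:
    """Block mutation: ``n_mutated_blocks`` aligned tiles are each either
    zeroed (probability ``p_delete``) or refilled at the initial sparsity
    with Uniform[-0.5, 0.5] values; the result is re-normalized."""
    W = pattern.W.copy()
    n = W.shape[0]
    b = cfg.block_size
    n_tiles = -(-n // b)
    for _ in range(cfg.n_mutated_blocks):
        bi, bj = rng.integers(0, n_tiles, size=2)
        sl_i = slice(bi * b, min((bi + 1) * b, n))
        sl_j = slice(bj * b, min((bj + 1) * b, n))
        if rng.random() < cfg.p_delete:
            W[sl_i, sl_j] = 0.0
        else:
            shape = (sl_i.stop - sl_i.start, sl_j.stop - sl_j.start)
            W[sl_i, sl_j] = _random_block_values(shape, params.sparsity, rng)
    return pattern.with_weights(
        normalize_spectral_radius(W), new_id=f"m-{uuid.uuid4().hex[:8]}"
    )


# ---------------------------------------------------------------------------
# Evaluation pipeline


@dataclass
class EvalContext:
    """Everything needed to evaluate one pattern."""

    params: ReservoirParams
    hebb: HebbParams
    info_cfg: InfoEstimatorConfig
    layout: GridLayout
    training_series: StimulusSeries
    validation_series: StimulusSeries


def _child_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-(generation, index, stream) seed below 2**31."""
    state = np.random.SeedSequence([master_seed, *key]).generate_state(1)[0]
    return int(state % (2**31))


def evaluate_pattern(
    pattern: WiringPattern,
    ctx: EvalContext,
    seed: int,
    objectives: tuple[str, ...],
    gen: int,
) -> EvaluatedPattern:
    """Run the developmental pipeline on one (already normalized) pattern.

    Records the spectral radius on entry, tunes the reservoir under
    spontaneous activity, trains the readout on the training series,
    measures the TE objective on the validation series, and computes the
    structural record on the tuned weights.  The tuned weights become the
    pattern's phenotype (and genome for subsequent variation).
    """
    rho_in = spectral_radius(pattern.W)
    tuned = tune_reservoir(pattern, ctx.params, ctx.hebb, seed=_child_seed(seed, 0))
    W_out = init_readout_weights(ctx.params, _child_seed(seed, 1))
    W_out = train_readout(
        tuned, W_out, ctx.training_series, ctx.params, ctx.hebb,
        seed=_child_seed(seed, 2),
    )
    te = pattern_te(
        tuned, W_out, ctx.validation_series, ctx.params, ctx.info_cfg,
        seed=_child_seed(seed, 3),
    )
    struct = evaluate_structure(tuned.W, ctx.layout)
    record = {
        "id": tuned.id,
        "gen": gen,
        "te": te,
        "cost": struct.coupling_cost,
        "density": struct.density,
        "modularity": struct.modularity,
        "clustering": struct.clustering,
        "avg_path": struct.avg_path,
        "rho": rho_in,
    }
    vec = {
        "maximize_te": -te,
        "minimize_cost": struct.coupling_cost,
        "minimize_density": struct.density,
    }
    return EvaluatedPattern(
        pattern=tuned,
        objectives_vector=np.array([vec[o] for o in objectives]),
        record=record,
    )


def _pick_parent(
    survivors: list[EvaluatedPattern], cfg: EvolutionConfig, rng: np.random.Generator
) -> EvaluatedPattern:
    if cfg.parent_selection == "uniform":
        return survivors[rng.integers(len(survivors))]
    i, j = rng.integers(0, len(survivors), size=2)
    a, b = survivors[i], survivors[j]
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    return a if a.crowding >= b.crowding else b


def _summary_row(gen: int, pool: list[EvaluatedPattern]) -> dict:
    row: dict = {"gen": gen, "n": len(pool)}
    for metric in ("te", "cost", "density", "modularity", "clustering", "avg_path"):
        values = np.array([p.record[metric] for p in pool])
        row[f"{metric}_max"] = values.max()
        row[f"{metric}_min"] = values.min()
        row[f"{metric}_mean"] = values.mean()
    return row


def evolve(
    cfg: EvolutionConfig,
    params: ReservoirParams,
    hebb: HebbParams,
    info_cfg: InfoEstimatorConfig,
    training_series: StimulusSeries,
    validation_series: StimulusSeries | None = None,
    seed: int = 0,
    layout: GridLayout | None = None,
) -> FrontHistory:
    """Run the full NSGA-II experiment.

    The initial pool holds ``P + Q`` freshly initialized patterns; each of
    the ``generations`` cycles selects ``P`` survivors, breeds ``Q``
    offspring from them, evaluates the offspring, and re-pools.  All
    randomness is derived from ``seed`` via per-(generation, index) streams,
    so identical seeds reproduce the run exactly.  ``validation_series``
    defaults to the training series.
    """
    if layout is None:
        layout = build_layout()
    if validation_series is None:
        validation_series = training_series
    ctx = EvalContext(
        params=params,
        hebb=hebb,
        info_cfg=info_cfg,
        layout=layout,
        training_series=training_series,
        validation_series=validation_series,
    )

    pool: list[EvaluatedPattern] = []
    patterns: dict[str, WiringPattern] = {}
    archive_rows: list[dict] = []
    for idx in range(cfg.n_survivors + cfg.n_offspring):
        pat = init_pattern(
            params, _child_seed(seed, 0, idx, 0), layout=layout,
            pattern_id=f"g0-{idx}",
        )
        ev = evaluate_pattern(pat, ctx, _child_seed(seed, 0, idx, 1),
                              cfg.objectives, gen=0)
        pool.append(ev)
        patterns[ev.pattern.id] = ev.pattern
        archive_rows.append(ev.record)

    summary_rows = [_summary_row(0, pool)]
    for gen in range(1, cfg.generations + 1):
        survivors = select_survivors(pool, cfg.n_survivors)
        offspring: list[EvaluatedPattern] = []
        for idx in range(cfg.n_offspring):
            op_rng = np.random.default_rng(_child_seed(seed, gen, idx, 0))
            pa = _pick_parent(survivors, cfg, op_rng)
            pb = _pick_parent(survivors, cfg, op_rng)
            child = crossover(pa.pattern, pb.pattern, cfg.block_size, op_rng)
            if op_rng.random() < cfg.p_mutation:
                child = mutate(child, cfg, params, op_rng)
            child = child.with_weights(child.W, new_id=f"g{gen}-{idx}")
            ev = evaluate_pattern(child, ctx, _child_seed(seed, gen, idx, 1),
                                  cfg.objectives, gen=gen)
            offspring.append(ev)
            patterns[ev.pattern.id] = ev.pattern
            archive_rows.append(ev.record)
        pool = survivors + offspring
        summary_rows.append(_summary_row(gen, pool))

    final_survivors = select_survivors(pool, cfg.n_survivors)
    rank_population(pool)
    return FrontHistory(
        summary=pd.DataFrame(summary_rows),
        archive=pd.DataFrame(archive_rows),
        population=pool,
        survivors=final_survivors,
        patterns=patterns,
    )


def expected_pattern_count(generations: int, n_survivors: int, n_offspring: int) -> int:
    """Patterns evaluated by a ``generations``-generation experiment whose
    initial P + Q pool counts as the first generation: P + Q plus Q fresh
    offspring in each of the remaining generations - 1 cycles.  At the full
    published scale (Gen=100, P=Q=250) this is 25,250.  A run of
    :func:`evolve` with ``cfg.generations`` offspring cycles therefore
    evaluates ``expected_pattern_count(cfg.generations + 1, P, Q)``
    patterns."""
    return (generations - 1) * n_offspring + n_survivors + n_offspring
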