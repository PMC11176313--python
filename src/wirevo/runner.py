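"""Experiment orchestration: objective conditions, presets, summaries.

Maps the seven objective-function conditions onto evolution runs, selects
the top/bottom TE pattern sets, characterizes representative entities
(random / top / bottom) with the oriented-bar probe set, and bundles
everything into a reloadable manifest of tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import CharacterizationRecord, characterize, normalized_volumes
from .evolution import (
    EvolutionConfig,
    FrontHistory,
    evaluate_pattern,
    EvalContext,
    evolve,
    expected_pattern_count,
)
from .info import InfoEstimatorConfig
from .plasticity import HebbParams, train_readout, tune_reservoir
from .reservoir import (
    ReservoirParams,
    WiringPattern,
    init_pattern,
    init_readout_weights,
)
from .stimuli import (
    StimulusSeries,
    generate_surrogate_landscape,
    make_probe_series,
    make_saccade_series,
)
from .structure import build_layout

logger = logging.getLogger(__name__)

#: Condition id -> objective subset (all-conditions comparison experiment).
CONDITION_OBJECTIVES: dict[int, tuple[str, ...]] = {
    1: ("maximize_te", "minimize_cost"),
    2: ("maximize_te",),
    3: ("minimize_cost",),
    4: ("minimize_density",),
    5: ("maximize_te", "minimize_cost", "minimize_density"),
    6: ("maximize_te", "minimize_density"),
    7: ("minimize_cost", "minimize_density"),
}


@dataclass(frozen=True)
class ScalePreset:
    """Bundled problem sizes for one run."""

    name: str
    generations: int
    n_survivors: int
    n_offspring: int
    n_train_landscapes: int
    n_val_landscapes: int
    n_scenes: int
    n_clips: int
    probe_hold: int = 20

    @property
    def train_length(self) -> int:
        return self.n_train_landscapes * self.n_scenes * self.n_clips

    @property
    def val_length(self) -> int:
        return self.n_val_landscapes * self.n_scenes * self.n_clips


#: "paper" restates the full published scale; "desk" is the scaled-down
#: configuration used throughout tests and the acceptance runs; "smoke" is a
#: seconds-scale sanity size.
PRESETS: dict[str, ScalePreset] = {
    "paper": ScalePreset("paper", 100, 250, 250, 5, 2, 100, 40),
    "desk": ScalePreset("desk", 10, 25, 25, 1, 1, 50, 40),
    "smoke": ScalePreset("smoke", 2, 6, 6, 1, 1, 10, 20),
}


@dataclass
class RunManifest:
    """Everything one condition run produced."""

    condition_id: int
    objectives: tuple[str, ...]
    preset: str
    seed: int
    summary: pd.DataFrame
    archive: pd.DataFrame
    top_ids: list[str]
    bottom_ids: list[str]
    characterization: dict[str, CharacterizationRecord] = field(default_factory=dict)
    volumes: dict[str, float] = field(default_factory=dict)
    history: FrontHistory | None = field(default=None, repr=False)

    def save(self, out_dir) -> None:
        """Write summary/archive CSVs plus a JSON manifest into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.archive.to_csv(out / "archive.csv", index=False)
        payload = {
            "condition_id": self.condition_id,
            "objectives": list(self.objectives),
            "preset": self.preset,
            "seed": self.seed,
            "files": ["summary.csv", "archive.csv"],
            "top_ids": self.top_ids,
            "bottom_ids": self.bottom_ids,
            "volumes": self.volumes,
            "characterization": {
                name: {
                    "fd": rec.fd,
                    "separation_nmi": rec.separation_nmi,
                    "volume": rec.volume,
                    "cumulative_contribution": rec.cumulative_contribution.tolist(),
                }
                for name, rec in self.characterization.items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(payload, indent=2))


def build_series(
    preset: ScalePreset, seed: int
) -> tuple[StimulusSeries, StimulusSeries]:
    """Training and validation saccade series for a preset, from disjoint
    surrogate landscapes."""
    train_imgs = [
        generate_surrogate_landscape(seed * 1000 + i)
        for i in range(preset.n_train_landscapes)
    ]
    val_imgs = [
        generate_surrogate_landscape(seed * 1000 + 500 + i)
        for i in range(preset.n_val_landscapes)
    ]
    train = make_saccade_series(
        train_imgs, n_scenes=preset.n_scenes, n_clips=preset.n_clips, seed=seed + 1
    )
    n_val_scenes = max(preset.n_scenes * 2 // 5, 1)  # validation ~40% of training
    val = make_saccade_series(
        val_imgs, n_scenes=n_val_scenes, n_clips=preset.n_clips, seed=seed + 2
    )
    return train, val


def top_bottom_sets(
    archive: pd.DataFrame, fraction: float = 0.1, source: str = "all"
) -> tuple[list[str], list[str]]:
    """Ids of the top and bottom TE-ranked patterns.

    ``source="all"`` (default) ranks every evaluated pattern in the
    archive; ``source="final"`` restricts the ranking to the last
    generation's patterns.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    if source not in ("all", "final"):
        raise ValueError(f"unknown source: {source!r}")
    pool = archive if source == "all" else archive[archive["gen"] == archive["gen"].max()]
    n = max(int(round(len(pool) * fraction)), 1)
    ranked = pool.sort_values("te", ascending=False, kind="stable")
    return list(ranked.head(n)["id"]), list(ranked.tail(n)["id"])


def consensus_connectivity(patterns: list[WiringPattern]) -> np.ndarray:
    """Signed connection-rate consensus across patterns.

    Entry (i, j) = (#patterns with W_ij > 0 - #patterns with W_ij < 0) / n;
    +1 means every pattern has an excitatory connection there, -1 every
    pattern an inhibitory one.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    stack = np.stack([p.W for p in patterns])
    return (np.sum(stack > 0, axis=0) - np.sum(stack < 0, axis=0)) / len(patterns)


def _characterize_entity(
    pattern: WiringPattern,
    ctx: EvalContext,
    probe: StimulusSeries,
    seed: int,
):
    """Train a fresh readout on the training series, then probe."""
    W_out = init_readout_weights(ctx.params, seed)
    W_out = train_readout(
        pattern, W_out, ctx.training_series, ctx.params, ctx.hebb, seed=seed + 1
    )
    return characterize(
        pattern, W_out, probe, ctx.params, ctx.info_cfg, seed=seed + 2
    )


def run_condition(
    condition_id: int,
    scale: str = "desk",
    seed: int = 0,
    top_bottom_fraction: float = 0.1,
    top_bottom_source: str = "all",
    characterize_entities: bool = True,
    params: ReservoirParams | None = None,
    hebb: HebbParams | None = None,
    info_cfg: InfoEstimatorConfig | None = None,
) -> RunManifest:
    """Run one objective condition end to end at a named scale.

    Evolves the population, picks the top/bottom TE sets from all evaluated
    patterns, and (optionally) characterizes three representative entities —
    a fresh random pattern plus the single highest- and lowest-TE patterns —
    with the oriented-bar probe set, normalizing trajectory volumes across
    the three so the largest is 1.
    """
    if condition_id not in CONDITION_OBJECTIVES:
        raise ValueError(f"unknown condition id: {condition_id}")
    if scale not in PRESETS:
        raise ValueError(f"unknown scale preset: {scale!r}")
    preset = PRESETS[scale]
    params = params if params is not None else ReservoirParams()
    hebb = hebb if hebb is not None else HebbParams()
    info_cfg = info_cfg if info_cfg is not None else InfoEstimatorConfig()
    layout = build_layout()

    train, val = build_series(preset, seed)
    cfg = EvolutionConfig(
        generations=preset.generations,
        n_survivors=preset.n_survivors,
        n_offspring=preset.n_offspring,
        objectives=CONDITION_OBJECTIVES[condition_id],
    )
    logger.info(
        "condition %d (%s) at scale %s: Gen=%d P=%d Q=%d train=%d val=%d",
        condition_id, "+".join(cfg.objectives), scale, cfg.generations,
        cfg.n_survivors, cfg.n_offspring, len(train), len(val),
    )
    history = evolve(cfg, params, hebb, info_cfg, train, val, seed=seed, layout=layout)
    for _, row in history.summary.iterrows():
        logger.info(
            "gen %3d: best TE %.3f mean cost %.1f mean density %.3f",
            row["gen"], row["te_max"], row["cost_mean"], row["density_mean"],
        )

    top_ids, bottom_ids = top_bottom_sets(
        history.archive, top_bottom_fraction, source=top_bottom_source
    )
    manifest = RunManifest(
        condition_id=condition_id,
        objectives=cfg.objectives,
        preset=scale,
        seed=seed,
        summary=history.summary,
        archive=history.archive,
        top_ids=top_ids,
        bottom_ids=bottom_ids,
        history=history,
    )

    if characterize_entities:
        ctx = EvalContext(params, hebb, info_cfg, layout, train, val)
        probe = make_probe_series(n_hold=preset.probe_hold, seed=seed + 7)
        rand = init_pattern(params, seed + 11, layout=layout, pattern_id="rand")
        rand = tune_reservoir(rand, params, hebb, seed=seed + 12)
        entities = {
            "random": rand,
            "top": history.patterns[top_ids[0]],
            "bottom": history.patterns[bottom_ids[-1]],
        }
        embeddings = {}
        for name, pat in entities.items():
            rec, emb = _characterize_entity(pat, ctx, probe, seed + 20)
            manifest.characterization[name] = rec
            embeddings[name] = emb.points
        manifest.volumes = normalized_volumes(embeddings)
    return manifest


__all__ = [
    "CONDITION_OBJECTIVES",
    "PRESETS",
    "RunManifest",
    "ScalePreset",
    "build_series",
    "consensus_connectivity",
    "expected_pattern_count",
    "run_condition",
    "top_bottom_sets",
]
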