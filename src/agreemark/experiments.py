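"""Reproducible experiment runner: seeding, series, population turnover.

A *series* is one fresh world (ontology, vocabulary, agents) plus a
sequence of games between randomly paired agents.  An *experiment* repeats
the series with seeds derived deterministically from a master seed and
aggregates the measure curves across series (mean and standard deviation).
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import Agent, GameRecord, play_game
from .interpretation import Interpreter
from .lexicon import Vocabulary, build_vocabulary
from .matrices import PropertySpace
from .measures import MeasureSeries
from .strategies import (
    CoercionStrategy,
    _StrategyBase,
    build_controller_agreement,
    build_initial_marker_system,
    make_strategy,
)
from .world import (
    GenerationConfig,
    Ontology,
    choose_topic,
    generate_ontology,
    generate_situation,
)

__all__ = [
    "ExperimentConfig",
    "inventory_dump",
    "preference_snapshot",
    "SeriesResult",
    "RunResult",
    "run_single_series",
    "run_series",
    "replace_agent",
    "derive_seeds",
    "DEFAULT_ELABORATION_RATE",
]

#: Over-specification probability of the speaker (see docs/methods.md for
#: the calibration against the target utterance-length distribution).
DEFAULT_ELABORATION_RATE = 0.8


class NullStrategy(_StrategyBase):
    """No markers at all: used for ambiguity accounting baselines."""

    name = "none"

    def speaker_assign(self, agent, groups, rng, game_index):
        return [None] * len(groups), [None] * len(groups), []

    def recognize_markers(self, hearer, utterance, rng):
        return {
            "occurrences": {},
            "constraints": {},
            "matched": {},
            "unknown_multi": [],
            "unknown_single": [],
        }

    def hearer_update(self, *args, **kwargs):
        return None

    def counterfactual(self, hearer, groups, rng):
        return [None] * len(groups)


@dataclass
class ExperimentConfig:
    """Full description of one experiment (YAML/JSON serializable)."""

    strategy: str = "formal"
    population: int = 10
    games: int = 1000
    series: int = 10
    window: int = 50
    gamma: float = 0.2
    sigma0: float = 0.5
    reduction_rate: float = 0.1
    reduction_start: int = 2000
    turnover: float = 0.005
    controller_fraction: float = 0.5
    elaboration_rate: float = DEFAULT_ELABORATION_RATE
    max_marker_attributes: int = 1
    #: re-entrance also flags marker need when more than this many
    #: hypotheses survive selection restrictions (None: ambiguity only)
    reentrance_threshold: int | None = 8
    seed: int = 0
    measure_stride: int = 1
    #: record population-mean marker preference scores every N games
    #: (0 = off); powers preference-trace plots
    snapshot_interval: int = 0
    generation: GenerationConfig = field(default_factory=GenerationConfig)

    def validate(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in ("gamma", "sigma0", "reduction_rate", "turnover",
                     "controller_fraction", "elaboration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.games < 1 or self.series < 1 or self.window < 1:
            raise ValueError("games, series and window must be >= 1")
        self.generation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        gen = d.pop("generation", None)
        cfg = cls(**d)
        if gen is not None:
            gen = dict(gen)
            for key in ("type_attributes", "type_values"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            cfg = dataclasses.replace(cfg, generation=GenerationConfig(**gen))
        return cfg


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Per-series seeds from the master seed (documented splitting scheme:
    a dedicated generator seeded with the master seed draws 31-bit ints)."""
    src = random.Random(master_seed)
    return [src.randrange(2**31) for _ in range(n)]


def _build_strategy(config: ExperimentConfig, ontology, vocabulary, rng):
    kwargs = dict(gamma=config.gamma, sigma0=config.sigma0)
    if config.strategy == "none":
        return NullStrategy(**kwargs)
    if config.strategy in ("meaningful", "reuse"):
        kwargs["max_marker_attributes"] = config.max_marker_attributes
    if config.strategy == "reduce":
        kwargs.update(
            max_marker_attributes=config.max_marker_attributes,
            reduction_rate=config.reduction_rate,
            reduction_start=config.reduction_start,
        )
    if config.strategy == "coerce":
        kwargs.update(
            max_marker_attributes=config.max_marker_attributes,
            initial_system=build_initial_marker_system(ontology, vocabulary, rng),
            agreement_base=build_controller_agreement(vocabulary, rng),
        )
    return make_strategy(config.strategy, **kwargs)


def inventory_dump(agents: list[Agent]) -> str:
    """TSV snapshot of every agent's marker inventory: agent, form, score,
    expressed features, pending variant counts."""
    lines = ["agent\tform\tscore\tfeatures\tvariants"]
    for a in agents:
        for c in a.inventory:
            feats = (
                "" if c.matrix is None
                else ",".join(f"{x}={v}" for x, v in sorted(c.matrix.required()))
            )
            variants = ",".join(f"{f}:{n}" for f, n in c.variants.items())
            lines.append(
                f"{a.agent_id}\t{c.form}\t{c.score:.4f}\t{feats}\t{variants}"
            )
    return "\n".join(lines) + "\n"


def preference_snapshot(agents: list[Agent], game: int) -> list[tuple]:
    """(game, form, mean score, holder count) rows across the population."""
    totals: dict[str, list[float]] = {}
    for a in agents:
        for c in a.inventory:
            totals.setdefault(c.form, []).append(c.score)
    return [
        (game, form, float(np.mean(scores)), len(scores))
        for form, scores in sorted(totals.items())
    ]


@dataclass
class SeriesResult:
    seed: int
    records: list[GameRecord]
    ontology: Ontology
    vocabulary: Vocabulary
    agents: list[Agent]
    initial_forms: tuple[str, ...]
    preference_rows: list[tuple] = field(default_factory=list)

    def measures(self, window: int = 50, stride: int = 1) -> MeasureSeries:
        return MeasureSeries.compute(
            self.records, window, self.initial_forms, stride
        )

    def agent_inventory_sizes(self) -> list[int]:
        """Distinct marker forms per agent."""
        return [len({c.form for c in a.inventory}) for a in self.agents]

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r.to_dict()) + "\n")

    def preference_trace(self) -> pd.DataFrame:
        """Per-marker population-mean preference scores over time (needs
        ``snapshot_interval`` > 0 in the config)."""
        return pd.DataFrame(
            self.preference_rows,
            columns=["game", "form", "mean_score", "holders"],
        )

    def write_inventory_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(inventory_dump(self.agents))


def replace_agent(
    agents: list[Agent], rng: random.Random, next_id: int,
    vocabulary: Vocabulary,
) -> int:
    """Swap one uniformly chosen agent for a fresh one that knows the
    shared vocabulary but has no marker inventory."""
    idx = rng.randrange(len(agents))
    agents[idx] = Agent(next_id, vocabulary)
    return next_id + 1


def run_single_series(config: ExperimentConfig, seed: int) -> SeriesResult:
    """One fresh world and one sequence of games, fully seeded."""
    config.validate()
    rng = random.Random(seed)
    ontology = generate_ontology(config.generation, rng)
    space = PropertySpace(ontology)
    vocabulary = build_vocabulary(
        ontology, rng, space, controller_fraction=config.controller_fraction
    )
    strategy = _build_strategy(config, ontology, vocabulary, rng)
    agents = [
        Agent(i, vocabulary, strategy.new_agent_state())
        for i in range(config.population)
    ]
    initial_forms = tuple(
        sorted({c.form for a in agents for c in a.inventory})
    )
    interpreter = Interpreter(ontology)
    next_id = config.population
    records: list[GameRecord] = []
    preference_rows: list[tuple] = []
    for n in range(1, config.games + 1):
        speaker, hearer = rng.sample(agents, 2)
        situation = generate_situation(
            ontology, config.generation.n_objects, rng
        )
        topic = choose_topic(situation, rng, config.generation.max_topic_size)
        rec = play_game(
            n, speaker, hearer, situation, topic, strategy, interpreter,
            rng, config.elaboration_rate, config.reentrance_threshold,
        )
        if config.turnover > 0 and rng.random() < config.turnover:
            next_id = replace_agent(agents, rng, next_id, vocabulary)
            rec.replaced = True
        records.append(rec)
        if config.snapshot_interval and n % config.snapshot_interval == 0:
            preference_rows.extend(preference_snapshot(agents, n))
    return SeriesResult(
        seed, records, ontology, vocabulary, agents, initial_forms,
        preference_rows,
    )


@dataclass
class RunResult:
    config: ExperimentConfig
    seeds: list[int]
    series: list[SeriesResult]
    aggregate: pd.DataFrame  # mean/std of every measure across series

    def summary(self) -> dict:
        last = self.aggregate.iloc[-1]
        return {k: float(last[k]) for k in self.aggregate.columns if k != "game"}

    def write_csv(self, path) -> None:
        self.aggregate.to_csv(path, index=False)


def run_series(config: ExperimentConfig) -> RunResult:
    """Run ``config.series`` independent series and aggregate measures."""
    config.validate()
    seeds = derive_seeds(config.seed, config.series)
    series = [run_single_series(config, s) for s in seeds]
    frames = [
        s.measures(config.window, config.measure_stride).frame for s in series
    ]
    merged = pd.concat(frames, keys=range(len(frames)), names=["series"])
    grouped = merged.groupby("game")
    mean = grouped.mean()
    std = grouped.std()
    agg = mean.join(std, lsuffix="", rsuffix="_sd").reset_index()
    return RunResult(config=config, seeds=seeds, series=series, aggregate=agg)


def ambiguity_statistics(records: list[GameRecord]) -> pd.DataFrame:
    """Per-utterance-length complexity accounting (marker-free runs): mean
    percentage of hypotheses surviving selection restrictions and
    situation-model grounding, plus residual ambiguity."""
    rows = []
    for r in records:
        if r.aborted or r.n_partitions_total == 0:
            continue
        rows.append(
            (
                r.n_words,
                100.0 * r.n_after_restrictions / r.n_partitions_total,
                100.0 * r.n_readings / r.n_partitions_total,
                r.n_readings,
                int(r.n_readings > 1),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "n_words", "pct_after_restrictions", "pct_grounded",
            "n_readings", "ambiguous",
        ],
    )
    return df.groupby("n_words").mean().reset_index()
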