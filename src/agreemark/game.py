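"""One round of the reference game: production, interpretation, success.

The speaker picks a topic (a subset of the situation's objects), finds for
every topic object a combination of properties that singles it out, covers
those properties with a minimal set of words, optionally adds agreement
markers (delegated to the active strategy), and utters everything in random
order.  The hearer parses, uses whatever markers it recognizes to constrain
the co-reference partition, prunes with selection restrictions and the
shared situation model, and points when a single reading remains.  The game
succeeds iff the pointed-at objects are exactly the topic.

Speakers detect the need for markers by *re-entrance*: feeding the planned
utterance through their own interpretation system and checking whether more
than one reading would survive.  Once an agent owns marker constructions it
applies them routinely and skips the simulation.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .interpretation import InterpretationResult, Interpreter
from .lexicon import CoverError, Vocabulary, VocabularyEntry, minimal_word_cover
from .matrices import FeatureMatrix
from .world import ObjectInstance, Property, SituationModel

__all__ = [
    "Agent",
    "WordGroup",
    "Utterance",
    "GameRecord",
    "distinctive_combination",
    "conceptualize",
    "speaker_produce",
    "hearer_interpret",
    "reenter",
    "play_game",
]


@dataclass(slots=True)
class Agent:
    """A population member: shared vocabulary plus private marker state."""

    agent_id: int
    vocabulary: Vocabulary
    inventory: list = field(default_factory=list)  # MarkerConstruction
    # coercion memory: controller form -> list[ControllerVariant]
    controller_variants: dict = field(default_factory=dict)


@dataclass(slots=True)
class WordGroup:
    """The words describing one topic object (a co-reference block on the
    speaker side)."""

    obj: ObjectInstance
    entries: list[VocabularyEntry]

    def meanings(self) -> list[frozenset[Property]]:
        return [e.meaning for e in self.entries]

    def group_matrix(self) -> FeatureMatrix:
        m = self.entries[0].matrix
        for e in self.entries[1:]:
            u = m.unify(e.matrix)
            if u is None:  # cannot happen for truthful same-object words
                raise AssertionError("word matrices of one object clash")
            m = u
        return m

    def controller(self) -> VocabularyEntry:
        """The group's controller word; falls back to the widest-coverage
        word when no entry carries the controller flag."""
        ctrl = [e for e in self.entries if e.is_controller]
        if len(ctrl) == 1:
            return ctrl[0]
        pool = ctrl or self.entries
        return max(pool, key=lambda e: (e.coverage, e.form))


@dataclass(slots=True)
class Utterance:
    """Ordered tokens (word form, optional marker form); the order is a
    random permutation and carries no meaning."""

    tokens: list[tuple[str, str | None]]

    def __len__(self) -> int:
        return len(self.tokens)

    def render(self) -> str:
        return " ".join(
            w if m is None else f"{w}-{m}" for w, m in self.tokens
        )


@dataclass(slots=True)
class GameRecord:
    index: int
    speaker_id: int
    hearer_id: int
    topic_size: int
    n_words: int
    success: bool
    aborted: bool
    n_partitions_total: int
    n_after_restrictions: int
    n_readings: int
    markers_used: tuple[str, ...]
    invented: tuple[str, ...]
    counterfactual_match: float | None
    replaced: bool = False

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "speaker": self.speaker_id,
            "hearer": self.hearer_id,
            "topic_size": self.topic_size,
            "n_words": self.n_words,
            "success": self.success,
            "aborted": self.aborted,
            "n_partitions_total": self.n_partitions_total,
            "n_after_restrictions": self.n_after_restrictions,
            "n_readings": self.n_readings,
            "markers_used": list(self.markers_used),
            "invented": list(self.invented),
            "counterfactual_match": self.counterfactual_match,
            "replaced": self.replaced,
        }


def distinctive_combination(
    obj: ObjectInstance,
    situation: SituationModel,
    rng: random.Random,
) -> frozenset[Property] | None:
    """A minimal-size property subset true of ``obj`` whose conjunction is
    false of every other object; ``None`` when even the full property set
    fails to distinguish (degenerate situation)."""
    others = [o.properties for o in situation.objects if o.object_id != obj.object_id]
    props = sorted(obj.properties)
    for size in range(1, len(props) + 1):
        hits = [
            frozenset(c)
            for c in itertools.combinations(props, size)
            if not any(frozenset(c) <= op for op in others)
        ]
        if hits:
            return hits[rng.randrange(len(hits))] if len(hits) > 1 else hits[0]
    return None


def conceptualize(
    obj: ObjectInstance,
    situation: SituationModel,
    rng: random.Random,
    elaboration_rate: float = 0.0,
) -> frozenset[Property] | None:
    """Properties the speaker decides to express for one topic object: a
    minimal distinctive combination, over-specified by including each
    remaining true property with probability ``elaboration_rate``.

    Over-specification keeps the expressed set distinctive (supersets of a
    distinctive set stay distinctive) and reproduces the redundancy human
    speakers show in referring expressions."""
    core = distinctive_combination(obj, situation, rng)
    if core is None:
        return None
    if elaboration_rate <= 0.0:
        return core
    extra = [
        p for p in sorted(obj.properties - core) if rng.random() < elaboration_rate
    ]
    return core | frozenset(extra)


def reenter(
    interpreter: Interpreter,
    groups: list[WordGroup],
    situation: SituationModel,
    complexity_threshold: int | None = None,
) -> bool:
    """Speaker self-simulation on the unmarked utterance: markers are
    needed when the hearer would face residual semantic ambiguity (more
    than one grounded reading) or -- when ``complexity_threshold`` is set
    -- combinatorial complexity (more than that many hypotheses left after
    selection restrictions)."""
    meanings = [m for g in groups for m in g.meanings()]
    result = interpreter.interpret(meanings, situation)
    if result.ambiguous:
        return True
    return (
        complexity_threshold is not None
        and result.n_after_restrictions > complexity_threshold
    )


def speaker_produce(
    agent: Agent,
    topic: tuple[ObjectInstance, ...],
    situation: SituationModel,
    strategy,
    interpreter: Interpreter,
    rng: random.Random,
    elaboration_rate: float = 0.0,
    game_index: int = 0,
    complexity_threshold: int | None = None,
):
    """Full production: conceptualization, lexical cover, marker step,
    random token order.

    Returns ``(utterance, groups, marker_forms, constructions, invented)``
    or ``None`` when some topic object has no distinguishing combination
    (the game is then aborted as a failure).
    """
    groups: list[WordGroup] = []
    for obj in topic:
        expressed = conceptualize(obj, situation, rng, elaboration_rate)
        if expressed is None:
            return None
        entries = minimal_word_cover(
            expressed, obj, agent.vocabulary, rng,
            require_controller=strategy.requires_controller_cover,
        )
        groups.append(WordGroup(obj, entries))

    if agent.inventory:
        need_markers = True  # routine application
    else:
        need_markers = reenter(
            interpreter, groups, situation, complexity_threshold
        )
    if need_markers:
        forms, constructions, invented = strategy.speaker_assign(
            agent, groups, rng, game_index
        )
    else:
        forms = [None] * len(groups)
        constructions = [None] * len(groups)
        invented = []

    tokens = [
        (e.form, forms[gi])
        for gi, g in enumerate(groups)
        for e in g.entries
    ]
    rng.shuffle(tokens)
    return Utterance(tokens), groups, forms, constructions, invented


def hearer_interpret(
    hearer: Agent,
    utterance: Utterance,
    situation: SituationModel,
    strategy,
    interpreter: Interpreter,
    rng: random.Random,
) -> tuple[InterpretationResult, frozenset[str] | None, dict]:
    """Parse, apply recognized markers as grouping constraints, run the
    enumerate/restrict/ground funnel and point when a unique reading
    remains.  Returns the result, the pointed-at object ids (or None) and
    the marker-recognition report the strategy needs for its updates."""
    meanings = []
    for word_form, _marker in utterance.tokens:
        entry = hearer.vocabulary.parse_word(word_form)
        if entry is None:  # cannot happen: the vocabulary is shared
            raise KeyError(f"unknown word form {word_form!r}")
        meanings.append(entry.meaning)

    recognition = strategy.recognize_markers(hearer, utterance, rng)
    result = interpreter.interpret(
        meanings, situation, marker_groups=recognition["constraints"]
    )
    pointing = result.referents()
    return result, pointing, recognition


def play_game(
    index: int,
    speaker: Agent,
    hearer: Agent,
    situation: SituationModel,
    topic: tuple[ObjectInstance, ...],
    strategy,
    interpreter: Interpreter,
    rng: random.Random,
    elaboration_rate: float = 0.0,
    complexity_threshold: int | None = None,
) -> GameRecord:
    """One complete speaker/hearer interaction plus learning updates."""
    production = speaker_produce(
        speaker, topic, situation, strategy, interpreter, rng,
        elaboration_rate, game_index=index,
        complexity_threshold=complexity_threshold,
    )
    if production is None:
        return GameRecord(
            index, speaker.agent_id, hearer.agent_id, len(topic), 0,
            success=False, aborted=True, n_partitions_total=0,
            n_after_restrictions=0, n_readings=0, markers_used=(),
            invented=(), counterfactual_match=None,
        )
    utterance, groups, forms, constructions, invented = production

    result, pointing, recognition = hearer_interpret(
        hearer, utterance, situation, strategy, interpreter, rng
    )
    topic_ids = frozenset(o.object_id for o in topic)
    success = pointing is not None and pointing == topic_ids

    used_forms = tuple(f for f in forms if f is not None)
    cf_match: float | None = None
    if used_forms:
        cf = strategy.counterfactual(hearer, groups, rng)
        cf_match = strategy.compare_choices(forms, cf)

    strategy.hearer_update(
        hearer, utterance, recognition, result, success, situation, rng
    )

    return GameRecord(
        index, speaker.agent_id, hearer.agent_id, len(topic),
        len(utterance), success, False,
        result.n_partitions_total, result.n_after_restrictions,
        result.n_readings, used_forms, tuple(invented), cf_match,
    )
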