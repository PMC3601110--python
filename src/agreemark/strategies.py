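"""The five marker strategies and their cultural dynamics.

* formal      -- meaningless sticker markers; lateral-inhibition alignment.
* meaningful  -- markers carry feature matrices invented de novo from
                 attributes that are distinctive across the topic objects;
                 hearers induce matrices for unknown markers and align
                 form/matrix associations by lateral inhibition.
* reuse       -- identical to meaningful except that invention recruits an
                 existing word expressing the distinctive feature(s),
                 preferring the word with the fewest properties.
* reduce      -- reuse plus phonological erosion: speakers truncate a
                 marker's final character with probability R; hearers
                 recognize one-character variants and adopt a variant as
                 the new norm after encountering it twice (voter dynamics),
                 with a syncretism guard that blocks truncations colliding
                 with other markers.
* coerce      -- reuse plus re-categorization: when a marker family almost
                 applies, controllers that are undecided on the marker's
                 attribute are conventionally assigned the marker's values;
                 coerced controller matrices compete by lateral inhibition.

All scores live in [0, 1]: reinforcement is s <- s + g*(1-s), inhibition is
s <- s*(1-g) with alignment rate g.  Only the hearer updates scores.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .game import Agent, Utterance, WordGroup
from .lexicon import Vocabulary, random_form
from .matrices import FeatureMatrix, PropertySpace
from .world import Ontology, Property

__all__ = [
    "MarkerConstruction",
    "ControllerVariant",
    "FormalStrategy",
    "MeaningfulStrategy",
    "ReuseStrategy",
    "ReductionStrategy",
    "CoercionStrategy",
    "make_strategy",
    "build_initial_marker_system",
    "build_controller_agreement",
]


@dataclass(slots=True)
class MarkerConstruction:
    """One association in an agent's marker inventory: a (current norm)
    form, an optional feature matrix, a preference score and the variant
    forms currently competing for the norm."""

    form: str
    matrix: FeatureMatrix | None
    score: float
    origin: str = "invented"  # invented | adopted | reused | initial
    variants: dict[str, int] = field(default_factory=dict)

    def combo(self) -> frozenset[Property] | None:
        return None if self.matrix is None else self.matrix.required()

    def matrix_key(self):
        return None if self.matrix is None else self.matrix.key()


@dataclass(slots=True)
class ControllerVariant:
    """A (possibly coerced) feature matrix competing for one controller."""

    matrix: FeatureMatrix
    score: float
    origin: str = "lexical"  # lexical | coerced


def _reinforce(score: float, gamma: float) -> float:
    return score + gamma * (1.0 - score)


def _inhibit(score: float, gamma: float) -> float:
    return score * (1.0 - gamma)


def _one_char_variant(a: str, b: str) -> bool:
    """True iff one string is the other minus its final character."""
    return (len(a) == len(b) + 1 and a[:-1] == b) or (
        len(b) == len(a) + 1 and b[:-1] == a
    )


class _StrategyBase:
    """Shared plumbing: alignment arithmetic and marker bookkeeping."""

    name = "base"
    requires_controller_cover = False

    def __init__(self, gamma: float = 0.2, sigma0: float = 0.5):
        self.gamma = gamma
        self.sigma0 = sigma0

    # -- helpers -------------------------------------------------------
    def reinforce(self, c) -> None:
        c.score = _reinforce(c.score, self.gamma)

    def inhibit(self, c) -> None:
        c.score = _inhibit(c.score, self.gamma)

    def fresh_marker_form(
        self, agent: Agent, rng: random.Random,
        syllables: tuple[int, int] = (2, 3), taken: set[str] | None = None,
    ) -> str:
        used = set(agent.vocabulary.by_form)
        used.update(c.form for c in agent.inventory)
        if taken:
            used |= taken
        form = random_form(rng, syllables)
        while form in used:
            form = random_form(rng, syllables)
        return form

    def new_agent_state(self) -> list[MarkerConstruction]:
        return []

    def realize(
        self, agent: Agent, c: MarkerConstruction, rng: random.Random,
        game_index: int,
    ) -> str:
        """Surface form the speaker actually utters for a construction."""
        return c.form

    def compare_choices(self, speaker_forms, counterfactual_forms) -> float:
        """Variation indicator in [0, 1]: the fraction of marked groups for
        which the hearer's counterfactual marker choice equalled the
        speaker's (1.0 = full agreement)."""
        pairs = [
            (f, counterfactual_forms[i])
            for i, f in enumerate(speaker_forms)
            if f is not None
        ]
        if not pairs:
            return 1.0
        return sum(a == b for a, b in pairs) / len(pairs)


class FormalStrategy(_StrategyBase):
    """Meaningless markers: the only decision is which forms to prefer.

    The speaker attaches one distinct marker per topic object (highest
    scores first, routine once the inventory is non-empty).  Markers are
    morphologically overt (hyphen-suffixed), so the hearer adopts any
    unknown marker form; a repeated unknown form additionally yields a
    co-reference constraint in the same game, while a singleton unknown
    form carries no grouping information and is only adopted.  Setting
    ``adoption_occurrences=2`` restricts adoption to repeated forms.
    Alignment is usage-based: appearing markers are reinforced,
    non-appearing ones inhibited (hearer only).
    """

    name = "formal"

    def __init__(
        self, gamma: float = 0.2, sigma0: float = 0.5,
        adoption_occurrences: int = 1,
    ):
        super().__init__(gamma, sigma0)
        self.adoption_occurrences = adoption_occurrences

    def speaker_assign(self, agent: Agent, groups, rng, game_index):
        n = len(groups)
        ranked = sorted(
            agent.inventory, key=lambda c: (-c.score, rng.random())
        )
        chosen = ranked[:n]
        invented = []
        taken: set[str] = {c.form for c in chosen}
        while len(chosen) < n:
            form = self.fresh_marker_form(agent, rng, taken=taken)
            c = MarkerConstruction(form, None, self.sigma0, "invented")
            agent.inventory.append(c)
            chosen.append(c)
            taken.add(form)
            invented.append(form)
        forms = [self.realize(agent, c, rng, game_index) for c in chosen]
        return forms, chosen, invented

    # -- hearer side ---------------------------------------------------
    def recognize_markers(self, hearer: Agent, utterance: Utterance, rng):
        occurrences: dict[str, list[int]] = {}
        for i, (_w, m) in enumerate(utterance.tokens):
            if m is not None:
                occurrences.setdefault(m, []).append(i)
        known = {c.form: c for c in hearer.inventory}
        constraints: dict[int, int] = {}
        label = 0
        matched: dict[str, MarkerConstruction] = {}
        unknown_multi: list[str] = []
        unknown_single: list[str] = []
        for form, idxs in occurrences.items():
            c = known.get(form)
            if c is not None:
                matched[form] = c
            elif len(idxs) >= 2:
                unknown_multi.append(form)
            else:
                unknown_single.append(form)
            # markers are overt suffixes: every distinct marker form
            # separates its words from differently-marked ones
            for i in idxs:
                constraints[i] = label
            label += 1
        return {
            "occurrences": occurrences,
            "constraints": constraints,
            "matched": matched,
            "unknown_multi": unknown_multi,
            "unknown_single": unknown_single,
        }

    def hearer_update(
        self, hearer, utterance, recognition, result, success, situation, rng
    ):
        appeared = set(recognition["occurrences"])
        if not appeared:
            return
        adopt = list(recognition["unknown_multi"])
        if self.adoption_occurrences <= 1:
            adopt += recognition["unknown_single"]
        for form in adopt:
            hearer.inventory.append(
                MarkerConstruction(form, None, self.sigma0, "adopted")
            )
        for c in hearer.inventory:
            if c.form in appeared:
                self.reinforce(c)
            else:
                self.inhibit(c)

    def counterfactual(self, hearer: Agent, groups, rng):
        ranked = sorted(
            hearer.inventory, key=lambda c: (-c.score, rng.random())
        )
        forms = [c.form for c in ranked[: len(groups)]]
        forms += [None] * (len(groups) - len(forms))
        return forms

    def compare_choices(self, speaker_forms, counterfactual_forms) -> float:
        # formal markers are interchangeable across groups: the convention
        # is *which* forms are in use, not their assignment to objects
        sp = [f for f in speaker_forms if f is not None]
        if not sp:
            return 1.0
        cf = [f for f in counterfactual_forms if f is not None]
        return len(set(sp) & set(cf)) / len(sp)


class MeaningfulStrategy(_StrategyBase):
    """Markers carry feature matrices; selection demands a marker *family*:
    an attribute set on which the topic objects take pairwise different
    values, with a fitting marker for every object's value combination."""

    name = "meaningful"
    reuse = False

    def __init__(
        self, gamma: float = 0.2, sigma0: float = 0.5,
        max_marker_attributes: int = 1,
    ):
        super().__init__(gamma, sigma0)
        self.max_marker_attributes = max_marker_attributes

    # -- semantics helpers ----------------------------------------------
    def _candidate_attr_sets(self, objs) -> list[tuple[str, ...]]:
        """Attribute sets (smallest first) on which every object has a
        value and the value tuples are pairwise distinct."""
        valuations = [dict(o.properties) for o in objs]
        shared = set(valuations[0])
        for v in valuations[1:]:
            shared &= set(v)
        shared = sorted(shared)
        out: list[tuple[str, ...]] = []
        import itertools

        for size in range(1, self.max_marker_attributes + 1):
            for A in itertools.combinations(shared, size):
                tuples = [tuple(v[a] for a in A) for v in valuations]
                if len(set(tuples)) == len(tuples):
                    out.append(A)
            if out:
                break  # prefer the smallest distinctive attribute sets
        return out

    def _combo_for(self, obj_values: dict[str, str], attrs) -> frozenset[Property]:
        return frozenset((a, obj_values[a]) for a in attrs)

    def _constructions_for_combo(self, agent, combo):
        return [
            c for c in agent.inventory
            if c.matrix is not None and c.combo() == combo
        ]

    def _best(self, cands, rng):
        return max(cands, key=lambda c: (c.score, rng.random()))

    # -- invention -------------------------------------------------------
    def _invent_form(self, agent, combo, rng, taken) -> tuple[str, str]:
        """(form, origin) for a new marker expressing ``combo``."""
        if self.reuse:
            words = agent.vocabulary.words_expressing(combo)
            if words:
                least = min(w.coverage for w in words)
                pool = [w for w in words if w.coverage == least]
                w = pool[rng.randrange(len(pool))] if len(pool) > 1 else pool[0]
                return w.form, "reused"
        return self.fresh_marker_form(agent, rng, (1, 2), taken), "invented"

    # -- selection -------------------------------------------------------
    def select_markers(self, agent, groups, rng, allow_invent=True):
        """Choose one construction per word group, inventing when no
        family applies.  Returns (constructions|None list, invented forms).
        """
        cand_sets = self._candidate_attr_sets([g.obj for g in groups])
        if not cand_sets:
            # no attribute set is distinctive across the topic objects:
            # meaningful markers do not apply here
            return [None] * len(groups), []
        valuations = [dict(g.obj.properties) for g in groups]
        matrices = [g.group_matrix() for g in groups]

        best_assign = None
        best_score = -1.0
        for A in cand_sets:
            assign = []
            assigned_ids: set[int] = set()
            total = 0.0
            for vi, (vals, gm) in enumerate(zip(valuations, matrices)):
                combo = self._combo_for(vals, A)
                cands = [
                    c for c in self._constructions_for_combo(agent, combo)
                    if c.matrix.fits(gm) and id(c) not in assigned_ids
                ]
                if not cands:
                    assign = None
                    break
                pick = self._best(cands, rng)
                assign.append(pick)
                assigned_ids.add(id(pick))
                total += pick.score
            if assign is not None and total > best_score:
                best_assign, best_score = assign, total
        if best_assign is not None:
            return best_assign, []

        if not allow_invent or not cand_sets:
            # no applicable marker family (and, for invention, no attribute
            # set distinctive across the topic objects): the utterance goes
            # out unmarked -- meaningful markers only apply in contexts
            # their semantics license
            return [None] * len(groups), []

        # cognitive economy: invent within the candidate attribute set that
        # needs the fewest new markers; remaining ties are broken at random
        def missing(A) -> int:
            n = 0
            for vals, gm in zip(valuations, matrices):
                combo = self._combo_for(vals, A)
                if not any(
                    c.matrix.fits(gm)
                    for c in self._constructions_for_combo(agent, combo)
                ):
                    n += 1
            return n

        need = [(missing(A), A) for A in cand_sets]
        least = min(n for n, _ in need)
        pool = [A for n, A in need if n == least]
        A = pool[rng.randrange(len(pool))]
        chosen = []
        chosen_ids: set[int] = set()
        invented = []
        taken: set[str] = set()
        for vals, gm in zip(valuations, matrices):
            combo = self._combo_for(vals, A)
            existing = [
                c for c in self._constructions_for_combo(agent, combo)
                if c.matrix.fits(gm) and id(c) not in chosen_ids
            ]
            if existing:
                pick = self._best(existing, rng)
                chosen.append(pick)
                chosen_ids.add(id(pick))
                continue
            form, origin = self._invent_form(agent, combo, rng, taken)
            matrix = FeatureMatrix.from_meaning(
                agent.vocabulary.space, combo, grounded=False
            )
            c = MarkerConstruction(form, matrix, self.sigma0, origin)
            agent.inventory.append(c)
            chosen.append(c)
            chosen_ids.add(id(c))
            taken.add(form)
            invented.append(form)
        return chosen, invented

    def speaker_assign(self, agent, groups, rng, game_index):
        constructions, invented = self.select_markers(agent, groups, rng)
        forms = [
            None if c is None else self.realize(agent, c, rng, game_index)
            for c in constructions
        ]
        return forms, constructions, invented

    # -- hearer side -----------------------------------------------------
    def _match_form(self, hearer, form):
        """Constructions of the hearer matching an incoming marker form
        (exact match here; the reduction strategy widens this)."""
        return [c for c in hearer.inventory if c.form == form]

    def recognize_markers(self, hearer: Agent, utterance: Utterance, rng):
        occurrences: dict[str, list[int]] = {}
        for i, (_w, m) in enumerate(utterance.tokens):
            if m is not None:
                occurrences.setdefault(m, []).append(i)
        constraints: dict[int, int] = {}
        matched: dict[str, list[MarkerConstruction]] = {}
        unknown_multi: list[str] = []
        unknown_single: list[str] = []
        label = 0
        for form, idxs in occurrences.items():
            cands = self._match_form(hearer, form)
            if cands:
                matched[form] = cands
            elif len(idxs) >= 2:
                unknown_multi.append(form)
            else:
                unknown_single.append(form)
            for i in idxs:
                constraints[i] = label
            label += 1
        return {
            "occurrences": occurrences,
            "constraints": constraints,
            "matched": matched,
            "unknown_multi": unknown_multi,
            "unknown_single": unknown_single,
        }

    def _bound_marker_groups(self, utterance, recognition, result, situation):
        """(form, word indices, bound object) per marker form.

        A marker group is *bound* when every surviving reading keeps its
        words in one block and assigns that block the same object; residual
        ambiguity elsewhere in the utterance does not block learning."""
        if not result.interpretations:
            return []
        objects = {o.object_id: o for o in situation.objects}
        out = []
        for form, idxs in recognition["occurrences"].items():
            first = idxs[0]
            oids: set[str | None] = set()
            for partition, binding in result.interpretations:
                for block, oid in zip(partition, binding):
                    if first in block:
                        oids.add(
                            oid if all(i in block for i in idxs) else None
                        )
                        break
            if len(oids) == 1 and None not in oids:
                out.append((form, idxs, objects[oids.pop()]))
        return out

    def hearer_update(
        self, hearer, utterance, recognition, result, success, situation, rng
    ):
        space = hearer.vocabulary.space
        marker_groups = self._bound_marker_groups(
            utterance, recognition, result, situation
        )
        marked_objs = [o for _f, _i, o in marker_groups]
        used: list[MarkerConstruction] = []

        cand_sets = (
            self._candidate_attr_sets(marked_objs) if marked_objs else []
        )
        for form, idxs, obj in marker_groups:
            vals = dict(obj.properties)
            # meanings the marker could have under the distinctiveness
            # principle the speaker's selection obeys in this context
            licensed = {
                self._combo_for(vals, A)
                for A in cand_sets
                if all(a in vals for a in A)
            }
            cands = recognition["matched"].get(form)
            if cands is None:
                entry = (
                    hearer.vocabulary.parse_word(form) if self.reuse else None
                )
                if entry is not None:
                    # a reused word as marker: its meaning is immediately
                    # clear, no guessing needed
                    matrix = FeatureMatrix.from_meaning(
                        space, entry.meaning, grounded=False
                    )
                    if not any(
                        c.form == form and c.matrix_key() == matrix.key()
                        for c in hearer.inventory
                    ):
                        c = MarkerConstruction(
                            form, matrix, self.sigma0, "adopted"
                        )
                        hearer.inventory.append(c)
                        used.append(c)
                    continue
                # unknown marker: induce candidate meanings from the
                # distinctiveness principle.  Every licensed reading enters
                # the inventory at the initial score; lateral inhibition
                # later prunes the wrong guesses.
                added = []
                for combo in sorted(licensed, key=lambda m: sorted(m)):
                    matrix = FeatureMatrix.from_meaning(space, combo, grounded=False)
                    key = matrix.key()
                    if not any(
                        c.form == form and c.matrix_key() == key
                        for c in hearer.inventory
                    ):
                        c = MarkerConstruction(form, matrix, self.sigma0, "adopted")
                        hearer.inventory.append(c)
                        added.append(c)
                if added:
                    used.append(added[rng.randrange(len(added))])
                continue

            # register any licensed reading of this marker that the hearer
            # does not have yet (alternative formulation); the new
            # associations compete with the stored ones from now on.  A
            # form received as a truncation variant is registered under the
            # matched construction's norm, not the surface form.
            canonical = cands[0].form if cands else form
            known_keys = {
                c.matrix_key() for c in hearer.inventory if c.form == canonical
            }
            fresh = []
            for combo in sorted(licensed, key=lambda m: sorted(m)):
                matrix = FeatureMatrix.from_meaning(space, combo, grounded=False)
                if matrix.key() not in known_keys:
                    alt = MarkerConstruction(canonical, matrix, self.sigma0, "adopted")
                    hearer.inventory.append(alt)
                    fresh.append(alt)
            fitting = [
                c for c in cands
                if c.matrix is not None and c.combo() in licensed
            ]
            if fitting:
                used.append(self._best(fitting, rng))
            elif fresh:
                used.append(fresh[rng.randrange(len(fresh))])

        self._vote_variants(hearer, recognition)

        if success and used:
            self.align(hearer, used)

    def _vote_variants(self, hearer, recognition) -> None:
        """Hook for the reduction strategy's voter dynamics."""

    def align(self, hearer, used: list[MarkerConstruction]) -> None:
        """Lateral inhibition: reinforce each used association, inhibit its
        competitors (same form with another matrix, or same matrix with
        another form)."""
        used_set = set(map(id, used))
        for c in used:
            self.reinforce(c)
        for c in used:
            for other in hearer.inventory:
                if id(other) in used_set:
                    continue
                same_form = other.form == c.form
                same_matrix = (
                    c.matrix is not None
                    and other.matrix_key() == c.matrix_key()
                )
                if same_form or same_matrix:
                    self.inhibit(other)

    def counterfactual(self, hearer: Agent, groups, rng):
        constructions, _ = self.select_markers(
            hearer, groups, rng, allow_invent=False
        )
        return [None if c is None else c.form for c in constructions]


class ReductionStrategy(MeaningfulStrategy):
    """Reuse plus phonological erosion with voter-style norm shifts."""

    name = "reduce"
    reuse = True

    def __init__(
        self, gamma: float = 0.2, sigma0: float = 0.5,
        max_marker_attributes: int = 1,
        reduction_rate: float = 0.1, reduction_start: int = 2000,
        adoption_threshold: int = 2,
    ):
        super().__init__(gamma, sigma0, max_marker_attributes)
        self.reduction_rate = reduction_rate
        self.reduction_start = reduction_start
        self.adoption_threshold = adoption_threshold

    def _collides(self, agent, c, form) -> bool:
        """Syncretism guard: the truncation may not coincide with any other
        marker's norm or stored variant."""
        for other in agent.inventory:
            if other is c:
                continue
            if other.form == form or form in other.variants:
                return True
        return False

    def realize(self, agent, c, rng, game_index):
        if c.variants:
            # a candidate truncation is pending: norm or variant, 50/50
            variant = next(reversed(c.variants))
            return variant if rng.random() < 0.5 else c.form
        if (
            game_index >= self.reduction_start
            and rng.random() < self.reduction_rate
        ):
            t = c.form[:-1]
            if len(t) >= 1 and not self._collides(agent, c, t):
                c.variants[t] = 0
                return t
        return c.form

    def _match_form(self, hearer, form):
        exact = [c for c in hearer.inventory if c.form == form]
        if exact:
            return exact
        cands = []
        for c in hearer.inventory:
            if form in c.variants or _one_char_variant(form, c.form) or any(
                _one_char_variant(form, v) for v in c.variants
            ):
                cands.append(c)
        # a variant match is ambiguous -- hence unknown -- only when it
        # points at more than one distinct norm form
        norms = {c.form for c in cands}
        return cands if len(norms) == 1 else []

    def _vote_variants(self, hearer, recognition) -> None:
        for form in recognition["occurrences"]:
            cands = recognition["matched"].get(form)
            if not cands:
                continue
            for c in cands:
                if c.form == form:
                    continue
                c.variants[form] = c.variants.get(form, 0) + 1
                if c.variants[form] >= self.adoption_threshold:
                    c.form = form  # variant becomes the new norm
                    c.variants = {}

    def compare_choices(self, speaker_forms, counterfactual_forms) -> float:
        pairs = [
            (f, counterfactual_forms[i])
            for i, f in enumerate(speaker_forms)
            if f is not None
        ]
        if not pairs:
            return 1.0
        return sum(
            b is not None and (a == b or _one_char_variant(a, b))
            for a, b in pairs
        ) / len(pairs)


class CoercionStrategy(MeaningfulStrategy):
    """Reuse plus conventional re-categorization of controllers.

    Marker choice is driven by the *controller* word of each group: its
    effective feature matrix (highest-scoring variant) supplies the values
    compared across groups.  When an existing single-attribute marker
    family almost applies, controllers that are open on that attribute are
    coerced -- assigned the marker's values by convention -- instead of
    prompting the invention of yet another marker family.
    """

    name = "coerce"
    reuse = True
    requires_controller_cover = True

    def __init__(
        self, gamma: float = 0.2, sigma0: float = 0.5,
        max_marker_attributes: int = 1,
        initial_system: list[tuple[str, FeatureMatrix]] | None = None,
        agreement_base: dict[str, FeatureMatrix] | None = None,
    ):
        super().__init__(gamma, sigma0, max_marker_attributes)
        self.initial_system = initial_system or []
        #: shared convention: the *agreement* matrix a controller word
        #: starts from.  Lexically grounded controllers carry their
        #: meaning-derived matrix; the rest start fully open (agreement
        #: features decoupled from word meaning, hence conventionalizable).
        self.agreement_base = agreement_base or {}

    def _base_matrix(self, entry) -> FeatureMatrix:
        return self.agreement_base.get(entry.form, entry.matrix)

    def new_agent_state(self) -> list[MarkerConstruction]:
        return [
            MarkerConstruction(form, matrix, self.sigma0, "initial")
            for form, matrix in self.initial_system
        ]

    # -- controller memory ----------------------------------------------
    def _variants_of(self, agent, entry) -> list[ControllerVariant]:
        lst = agent.controller_variants.get(entry.form)
        if lst is None:
            lst = [
                ControllerVariant(self._base_matrix(entry), self.sigma0, "lexical")
            ]
            agent.controller_variants[entry.form] = lst
        return lst

    def effective_matrix(self, agent, entry) -> FeatureMatrix:
        lst = agent.controller_variants.get(entry.form)
        if not lst:
            return self._base_matrix(entry)
        return max(lst, key=lambda v: v.score).matrix

    def _store_variant(self, agent, entry, matrix) -> ControllerVariant:
        lst = self._variants_of(agent, entry)
        for v in lst:
            if v.matrix.key() == matrix.key():
                return v
        v = ControllerVariant(matrix, self.sigma0, "coerced")
        lst.append(v)
        return v

    def coerce_controller(self, agent, entry, marker) -> ControllerVariant | None:
        """unify(controller matrix, marker matrix); refusal (None) on a
        clash with grounded or already-determined cells."""
        base = self.effective_matrix(agent, entry)
        unified = base.unify(marker.matrix)
        if unified is None:
            return None
        if unified.key() == base.key():
            return None  # already compatible: nothing to coerce
        return self._store_variant(agent, entry, unified)

    # -- selection --------------------------------------------------------
    def _marker_value(self, matrix: FeatureMatrix, attr: str) -> str | None:
        for a, v in matrix.required():
            if a == attr:
                return v
        return None

    def select_markers(self, agent, groups, rng, allow_invent=True):
        controllers = [g.controller() for g in groups]
        eff = [self.effective_matrix(agent, c) for c in controllers]

        # single-attribute families present in the inventory
        families: dict[str, dict[str, list[MarkerConstruction]]] = {}
        for c in agent.inventory:
            if c.matrix is None:
                continue
            req = c.matrix.required()
            if len(req) != 1:
                continue
            (a, v), = req
            families.setdefault(a, {}).setdefault(v, []).append(c)

        best = None  # (needs_coercion, -total_score) minimized
        best_key = None
        for attr, by_value in families.items():
            det = [self._marker_value(m, attr) for m in eff]
            if any(
                d is not None and det.count(d) > 1 for d in det
            ):
                continue  # two controllers determined to the same value
            available = {
                v: cs for v, cs in by_value.items() if v not in det
            }
            assign: list[MarkerConstruction] = []
            assigned_ids: set[int] = set()
            coercions: list[int] = []
            ok = True
            for gi, d in enumerate(det):
                if d is not None:
                    cands = [
                        c for c in by_value.get(d, [])
                        if id(c) not in assigned_ids
                    ]
                    if not cands:
                        ok = False
                        break
                    pick = self._best(cands, rng)
                    assign.append(pick)
                    assigned_ids.add(id(pick))
                else:
                    # undecided controller: coercible to any free value
                    pick = None
                    for v in sorted(available):
                        cands = [
                            c for c in available[v]
                            if id(c) not in assigned_ids
                            and eff[gi].fits(c.matrix)
                        ]
                        if cands:
                            pick = self._best(cands, rng)
                            del available[v]
                            break
                    if pick is None:
                        ok = False
                        break
                    assign.append(pick)
                    assigned_ids.add(id(pick))
                    coercions.append(gi)
            if not ok:
                continue
            total = sum(c.score for c in assign)
            key = (len(coercions), -total)
            if best is None or key < best_key:
                best, best_key = (assign, coercions), key

        if best is not None:
            assign, coercions = best
            if allow_invent:  # counterfactuals must not mutate memory
                for gi in coercions:
                    self.coerce_controller(agent, controllers[gi], assign[gi])
            return assign, []

        if not allow_invent:
            return [None] * len(groups), []
        return super().select_markers(agent, groups, rng, allow_invent=True)

    # -- hearer side ------------------------------------------------------
    def hearer_update(
        self, hearer, utterance, recognition, result, success, situation, rng
    ):
        marker_groups = self._bound_marker_groups(
            utterance, recognition, result, situation
        )
        entries = {
            w: hearer.vocabulary.parse_word(w) for w, _m in utterance.tokens
        }
        used_variants: list[ControllerVariant] = []
        used_controllers: list[str] = []
        for form, idxs, obj in marker_groups:
            cands = recognition["matched"].get(form)
            if not cands:
                continue
            marker = self._best(
                [c for c in cands if c.matrix is not None] or cands, rng
            )
            if marker.matrix is None:
                continue
            words = [entries[utterance.tokens[i][0]] for i in idxs]
            group = WordGroup(obj, words)
            ctrl = group.controller()
            effective = self.effective_matrix(hearer, ctrl)
            if effective.fits(marker.matrix):
                target = effective.unify(marker.matrix)
                if target.key() == effective.key():
                    lst = self._variants_of(hearer, ctrl)
                    used_variants.append(
                        max(lst, key=lambda v: v.score)
                    )
                else:
                    used_variants.append(
                        self._store_variant(hearer, ctrl, target)
                    )
                used_controllers.append(ctrl.form)
            else:
                # incompatible: re-categorize from the base matrix
                unified = self._base_matrix(ctrl).unify(marker.matrix)
                if unified is not None:
                    used_variants.append(
                        self._store_variant(hearer, ctrl, unified)
                    )
                    used_controllers.append(ctrl.form)
        # marker-level adoption/induction/alignment from the base class
        super().hearer_update(
            hearer, utterance, recognition, result, success, situation, rng
        )
        if success:
            for form, v in zip(used_controllers, used_variants):
                self.reinforce(v)
                for other in hearer.controller_variants.get(form, ()):
                    if other is not v:
                        self.inhibit(other)


def build_controller_agreement(
    vocabulary: Vocabulary,
    rng: random.Random,
    open_fraction: float = 0.5,
    row_open_probability: float = 0.1,
) -> dict[str, "FeatureMatrix"]:
    """Shared agreement-matrix convention for controller words.

    A random ``open_fraction`` of controllers get agreement matrices that
    are open on some (possibly all) of their attributes: each
    meaning-derived row is blanked with ``row_open_probability``, modelling
    features with no semantic grounding for that word (like gender on
    inanimates) that are therefore conventionalizable.  The remaining
    controllers keep their fully grounded meaning-derived matrix."""
    base = {}
    for e in vocabulary.entries:
        if e.is_controller and rng.random() < open_fraction:
            kept = {p for p in e.meaning if rng.random() >= row_open_probability}
            base[e.form] = FeatureMatrix.from_meaning(vocabulary.space, kept)
    return base


def build_initial_marker_system(
    ontology: Ontology,
    vocabulary: Vocabulary,
    rng: random.Random,
) -> list[tuple[str, FeatureMatrix]]:
    """A minimal shared marker system for coercion runs: one marker per
    value of one randomly chosen attribute, recruited from the word with
    the fewest properties expressing that value."""
    attr = ontology.attributes[rng.randrange(len(ontology.attributes))]
    system = []
    for v in ontology.values[attr]:
        combo = frozenset({(attr, v)})
        words = vocabulary.words_expressing(combo)
        if words:
            least = min(w.coverage for w in words)
            pool = [w for w in words if w.coverage == least]
            form = pool[rng.randrange(len(pool))].form
        else:
            form = random_form(rng, (1, 2))
        matrix = FeatureMatrix.from_meaning(vocabulary.space, combo, grounded=False)
        system.append((form, matrix))
    return system


class ReuseStrategy(MeaningfulStrategy):
    """Meaningful markers recruited from existing words."""

    name = "reuse"
    reuse = True


def make_strategy(name: str, **kwargs):
    """Factory used by the experiment runner and the CLI."""
    table = {
        "formal": FormalStrategy,
        "meaningful": MeaningfulStrategy,
        "reuse": ReuseStrategy,
        "reduce": ReductionStrategy,
        "coerce": CoercionStrategy,
    }
    if name not in table:
        raise ValueError(f"unknown strategy {name!r}")
    return table[name](**kwargs)
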