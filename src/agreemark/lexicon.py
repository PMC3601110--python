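"""The shared, synonym-free compositional vocabulary.

For every object type, all meaning combinations of at most three of its
attributes (one allowed value per chosen attribute) receive exactly one
word; a combination useful for several types still gets a single word, so
the vocabulary has neither synonyms nor homonyms.  Word forms are random
pronounceable syllable strings.  Production lookup retrieves a minimal set
of words covering a chosen property set, preferring words with the largest
coverage; parsing maps a form back to its stored meaning applied to a fresh
object variable.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field

from .matrices import FeatureMatrix, PropertySpace
from .world import ObjectInstance, Ontology, Property

__all__ = [
    "VocabularyEntry",
    "Vocabulary",
    "build_vocabulary",
    "minimal_word_cover",
    "random_form",
    "CoverError",
]

_CONSONANTS = "bdfghjklmnpqrstvwyz"
_VOWELS = "aeiou"
_CLUSTERS = ("sh", "ch", "th", "qu", "zh", "kr", "pl", "st")

MAX_MEANING_ATTRIBUTES = 3


class CoverError(RuntimeError):
    """No set of truthful words covers the requested properties."""


def _syllable(rng: random.Random) -> str:
    onset = rng.choice(_CLUSTERS) if rng.random() < 0.3 else rng.choice(_CONSONANTS)
    nucleus = rng.choice(_VOWELS)
    if rng.random() < 0.4:
        nucleus += rng.choice(_VOWELS)
    coda = rng.choice(_CONSONANTS) if rng.random() < 0.3 else ""
    return onset + nucleus + coda


def random_form(rng: random.Random, syllables: tuple[int, int] = (2, 3)) -> str:
    """A random pronounceable form of 2-3 syllables (e.g. 'shuqfon')."""
    n = rng.randint(*syllables)
    return "".join(_syllable(rng) for _ in range(n))


@dataclass(frozen=True, slots=True)
class VocabularyEntry:
    form: str
    meaning: frozenset[Property]
    matrix: FeatureMatrix
    is_controller: bool = False

    @property
    def coverage(self) -> int:
        return len(self.meaning)


class Vocabulary:
    """Entries indexed by form, by meaning and by single property."""

    def __init__(self, entries: list[VocabularyEntry], space: PropertySpace):
        self.entries = entries
        self.space = space
        self.by_form: dict[str, VocabularyEntry] = {}
        self.by_meaning: dict[frozenset[Property], VocabularyEntry] = {}
        self.by_property: dict[Property, list[VocabularyEntry]] = {}
        for e in entries:
            if e.form in self.by_form:
                raise ValueError(f"duplicate form {e.form!r}")
            if e.meaning in self.by_meaning:
                raise ValueError("duplicate meaning set (synonym)")
            self.by_form[e.form] = e
            self.by_meaning[e.meaning] = e
            for p in e.meaning:
                self.by_property.setdefault(p, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def parse_word(self, form: str) -> VocabularyEntry | None:
        """Lookup of an uttered form; ``None`` flags an unknown string
        (candidate marker).  Each call site must introduce its own fresh
        variable for the entry's referent."""
        return self.by_form.get(form)

    def word_for_meaning(self, meaning: frozenset[Property]) -> VocabularyEntry | None:
        return self.by_meaning.get(meaning)

    def words_expressing(self, props: frozenset[Property]) -> list[VocabularyEntry]:
        """Entries whose meaning includes all of ``props``."""
        if not props:
            return []
        first, *rest = props
        out = []
        for e in self.by_property.get(first, ()):
            if all(p in e.meaning for p in rest):
                out.append(e)
        return out

    # -- serialization -------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {"form": e.form,
             "meaning": sorted(map(list, e.meaning)),
             "is_controller": e.is_controller}
            for e in self.entries
        ]

    def to_json(self) -> str:
        return json.dumps(self.to_records(), indent=2)

    def to_tsv(self) -> str:
        lines = ["form\tmeaning\tis_controller"]
        for e in self.entries:
            meaning = ",".join(f"{a}={v}" for a, v in sorted(e.meaning))
            lines.append(f"{e.form}\t{meaning}\t{int(e.is_controller)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_records(cls, records: list[dict], space: PropertySpace) -> "Vocabulary":
        entries = []
        for r in records:
            meaning = frozenset(tuple(p) for p in r["meaning"])
            entries.append(
                VocabularyEntry(
                    r["form"], meaning,
                    FeatureMatrix.from_meaning(space, meaning),
                    bool(r.get("is_controller", False)),
                )
            )
        return cls(entries, space)

    @classmethod
    def from_json(cls, text: str, space: PropertySpace) -> "Vocabulary":
        return cls.from_records(json.loads(text), space)


def enumerate_meanings(ontology: Ontology) -> list[frozenset[Property]]:
    """All distinct meaning combinations of at most three attributes of some
    type, one allowed value per chosen attribute."""
    meanings: set[frozenset[Property]] = set()
    for t in ontology.types:
        attrs = t.attributes
        for k in range(1, min(MAX_MEANING_ATTRIBUTES, len(attrs)) + 1):
            for subset in itertools.combinations(attrs, k):
                for combo in itertools.product(*(t.allowed[a] for a in subset)):
                    meanings.add(frozenset(zip(subset, combo)))
    return sorted(meanings, key=lambda m: sorted(m))


def build_vocabulary(
    ontology: Ontology,
    rng: random.Random,
    space: PropertySpace | None = None,
    controller_fraction: float = 0.0,
) -> Vocabulary:
    """One word per distinct meaning combination; unique random forms;
    controller flags drawn at ``controller_fraction`` (coercion runs)."""
    space = space or PropertySpace(ontology)
    meanings = enumerate_meanings(ontology)
    used_forms: set[str] = set()
    entries = []
    for meaning in meanings:
        form = random_form(rng)
        while form in used_forms:
            form = random_form(rng)
        used_forms.add(form)
        entries.append(
            VocabularyEntry(
                form,
                meaning,
                FeatureMatrix.from_meaning(space, meaning),
                rng.random() < controller_fraction,
            )
        )
    return Vocabulary(entries, space)


def minimal_word_cover(
    distinctive: frozenset[Property] | set[Property],
    obj: ObjectInstance,
    vocabulary: Vocabulary,
    rng: random.Random,
    require_controller: bool = False,
) -> list[VocabularyEntry]:
    """Minimal-count word cover of ``distinctive``.

    Every candidate word's full meaning must be true of ``obj`` (words may
    carry extra, truthful properties).  Among minimal-count covers the
    largest total coverage wins; remaining ties are broken by a seeded
    random draw.  With ``require_controller`` covers containing exactly one
    controller word are preferred (agreement word-groups need a controller),
    falling back to unconstrained covers when impossible.
    """
    distinctive = frozenset(distinctive)
    if not distinctive:
        raise CoverError("empty distinctive set")
    if not distinctive <= obj.properties:
        raise CoverError("distinctive properties must be true of the object")
    candidates = {
        e.form: e
        for p in distinctive
        for e in vocabulary.by_property.get(p, ())
        if e.meaning <= obj.properties
    }
    cands = sorted(candidates.values(), key=lambda e: (-e.coverage, e.form))
    if not cands:
        raise CoverError("no truthful word covers any distinctive property")

    found: dict[frozenset[str], list[VocabularyEntry]] = {}
    best_size = len(distinctive) + 1

    def search(remaining: frozenset[Property], chosen: list[VocabularyEntry]) -> None:
        nonlocal found, best_size
        if not remaining:
            key = frozenset(e.form for e in chosen)
            if len(chosen) < best_size:
                found, best_size = {key: list(chosen)}, len(chosen)
            elif len(chosen) == best_size:
                found.setdefault(key, list(chosen))
            return
        if len(chosen) + 1 > best_size:
            return
        # branch on one fixed uncovered property: every cover must contain
        # a word covering it, so this enumerates all minimal covers
        target = min(remaining)
        for e in cands:
            if target in e.meaning and e not in chosen:
                search(remaining - e.meaning, chosen + [e])

    search(distinctive, [])
    if not found:
        raise CoverError("no valid cover exists")
    best = sorted(found.values(), key=lambda c: sorted(e.form for e in c))
    if require_controller:
        with_ctrl = [c for c in best
                     if sum(e.is_controller for e in c) == 1]
        if with_ctrl:
            best = with_ctrl
    top = max(
        len(frozenset().union(*(e.meaning for e in c))) for c in best
    )
    best = [c for c in best
            if len(frozenset().union(*(e.meaning for e in c))) == top]
    chosen = best[rng.randrange(len(best))] if len(best) > 1 else best[0]
    return sorted(chosen, key=lambda e: e.form)
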