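import itertools
import random

import pytest

from agreemark import (
    FeatureMatrix,
    GenerationConfig,
    PropertySpace,
    Vocabulary,
    build_vocabulary,
    generate_ontology,
    minimal_word_cover,
)
from agreemark.lexicon import CoverError, VocabularyEntry, enumerate_meanings
from agreemark.world import ObjectInstance, Ontology, TypeSpec


def tiny_ontology(allowed_by_type):
    """Hand-built ontology helper for oracle tests."""
    attrs = sorted({a for allowed in allowed_by_type for a in allowed})
    values = {a: tuple(f"{a}-{i}" for i in (1, 2, 3)) for a in attrs}
    types = tuple(
        TypeSpec(f"t-{k + 1}", {a: tuple(vs) for a, vs in allowed.items()})
        for k, allowed in enumerate(allowed_by_type)
    )
    return Ontology(attributes=tuple(attrs), values=values, types=types)


def test_meaning_enumeration_matches_brute_force():
    ontology = tiny_ontology([{"a": ("a-1",), "b": ("b-1",)}])
    meanings = set(enumerate_meanings(ontology))
    assert meanings == {
        frozenset({("a", "a-1")}),
        frozenset({("b", "b-1")}),
        frozenset({("a", "a-1"), ("b", "b-1")}),
    }


def test_brute_force_combination_count_on_random_type(rng):
    allowed = {"a": ("a-1", "a-2"), "b": ("b-1",), "c": ("c-1", "c-2", "c-3")}
    ontology = tiny_ontology([allowed])
    # oracle: enumerate attribute subsets of size <= 3 and value products
    expected = set()
    for k in (1, 2, 3):
        for sub in itertools.combinations(sorted(allowed), k):
            for combo in itertools.product(*(allowed[a] for a in sub)):
                expected.add(frozenset(zip(sub, combo)))
    assert set(enumerate_meanings(ontology)) == expected


def test_vocabulary_has_no_synonyms_or_homonyms(default_world):
    _, _, vocabulary = default_world
    meanings = [e.meaning for e in vocabulary.entries]
    forms = [e.form for e in vocabulary.entries]
    assert len(set(meanings)) == len(meanings)
    assert len(set(forms)) == len(forms)
    # bijectivity between forms and meanings
    assert {vocabulary.by_form[f].meaning for f in forms} == set(meanings)


def test_vocabulary_serialization_round_trips(default_world):
    _, space, vocabulary = default_world
    again = Vocabulary.from_json(vocabulary.to_json(), space)
    assert [e.form for e in again.entries] == [e.form for e in vocabulary.entries]
    assert [e.meaning for e in again.entries] == [
        e.meaning for e in vocabulary.entries
    ]
    tsv = vocabulary.to_tsv()
    assert tsv.startswith("form\tmeaning\tis_controller")
    assert len(tsv.strip().splitlines()) == len(vocabulary) + 1


def test_parse_word_known_and_unknown(default_world):
    _, _, vocabulary = default_world
    entry = vocabulary.entries[0]
    assert vocabulary.parse_word(entry.form) is entry
    assert vocabulary.parse_word("zzzzzz-not-a-word") is None


def _cover_oracle(distinctive, obj, entries):
    """Exhaustive search over entry subsets: minimal count, then maximal
    union coverage."""
    usable = [e for e in entries if e.meaning <= obj.properties]
    best = None
    for k in range(1, len(usable) + 1):
        found = []
        for combo in itertools.combinations(usable, k):
            union = frozenset().union(*(e.meaning for e in combo))
            if distinctive <= union:
                found.append((len(union), frozenset(e.form for e in combo)))
        if found:
            top = max(c for c, _ in found)
            return k, {forms for c, forms in found if c == top}
    return None


def _make_vocab(ontology, entries_spec, space):
    entries = [
        VocabularyEntry(
            form, frozenset(meaning), FeatureMatrix.from_meaning(space, meaning)
        )
        for form, meaning in entries_spec
    ]
    return Vocabulary(entries, space)


def test_cover_matches_exhaustive_oracle_on_random_toys(rng):
    ontology = tiny_ontology(
        [{"a": ("a-1", "a-2"), "b": ("b-1", "b-2"), "c": ("c-1",),
          "d": ("d-1", "d-2"), "e": ("e-1",)}]
    )
    space = PropertySpace(ontology)
    all_props = sorted(ontology.types[0].possible_properties())
    for trial in range(40):
        obj_props = frozenset(
            (a, rng.choice([v for p, v in
                            [(x, y) for x, y in all_props if x == a]]))
            for a in ontology.attributes
        )
        obj = ObjectInstance("o-1", "t-1", obj_props)
        pool = []
        seen = set()
        while len(pool) < 10:
            size = rng.randint(1, 3)
            meaning = frozenset(rng.sample(all_props, size))
            if len({a for a, _ in meaning}) != size or meaning in seen:
                continue
            seen.add(meaning)
            pool.append((f"w{len(pool)}", meaning))
        vocab = _make_vocab(ontology, pool, space)
        distinctive = frozenset(rng.sample(sorted(obj_props), rng.randint(1, 2)))
        oracle = _cover_oracle(distinctive, obj, vocab.entries)
        if oracle is None:
            with pytest.raises(CoverError):
                minimal_word_cover(distinctive, obj, vocab, rng)
            continue
        k, optimal_sets = oracle
        cover = minimal_word_cover(distinctive, obj, vocab, rng)
        assert len(cover) == k
        assert {e.form for e in cover} in optimal_sets
        # every extra covered property is true of the object
        for e in cover:
            assert e.meaning <= obj.properties


def test_cover_prefers_largest_coverage(default_world, rng):
    ontology, space, _ = default_world
    t = ontology.types[0]
    a = t.attributes[0]
    obj_props = frozenset((x, vs[0]) for x, vs in t.allowed.items())
    obj = ObjectInstance("o-1", t.type_id, obj_props)
    single = (a, t.allowed[a][0])
    pool = [("w1", frozenset({single}))]
    if len(obj_props) >= 3:
        big = frozenset(sorted(obj_props)[:3])
        if single not in big:
            big = frozenset(list(sorted(big))[:2] + [single])
        pool.append(("w2", big))
        vocab = _make_vocab(ontology, pool, space)
        cover = minimal_word_cover(frozenset({single}), obj, vocab, rng)
        assert [e.form for e in cover] == ["w2"]


def test_exact_meaning_word_is_single_cover(default_world, rng):
    ontology, _, vocabulary = default_world
    t = ontology.types[0]
    obj_props = frozenset((a, vs[0]) for a, vs in t.allowed.items())
    obj = ObjectInstance("o-1", t.type_id, obj_props)
    distinctive = frozenset(sorted(obj_props)[: min(3, len(obj_props))])
    cover = minimal_word_cover(distinctive, obj, vocabulary, rng)
    assert len(cover) == 1
    assert distinctive <= cover[0].meaning <= obj_props


def test_mean_vocabulary_size_near_reference():
    sizes = []
    for s in range(30):
        rng = random.Random(999 + s)
        ontology = generate_ontology(GenerationConfig(), rng)
        sizes.append(len(build_vocabulary(ontology, rng)))
    mean = sum(sizes) / len(sizes)
    assert 200 <= mean <= 320
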