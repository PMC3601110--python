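"""Abstract world generation: ontology, situation models and topic choice.

The simulated world is deliberately schematic.  An ontology fixes a small set
of attributes (e.g. size, colour), each with a handful of mutually exclusive
values, plus a set of object *types* that restrict which attribute-value
pairs their instances may carry.  A situation model is a set of fully
specified objects drawn from the ontology; it is shared verbatim by both
participants of a language game, so all referential uncertainty comes from
the utterance, never from perception.
"""

from __future__ import annotations

import itertools
import json
import random
import string
from dataclasses import dataclass, field

__all__ = [
    "Property",
    "GenerationConfig",
    "TypeSpec",
    "Ontology",
    "ObjectInstance",
    "SituationModel",
    "generate_ontology",
    "generate_situation",
    "choose_topic",
]

#: A property is an attribute-value pair, e.g. ``("a", "a-1")``.
Property = tuple[str, str]


class ConfigurationError(ValueError):
    """Raised for structurally impossible generation parameters."""


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the world generator.

    Defaults reproduce the canonical study conditions: 5 attributes with 3
    values each, 10 types with 1-5 attributes and 1-3 allowed values per
    attribute, and 3 objects per situation.
    """

    n_attributes: int = 5
    n_values: int = 3
    n_types: int = 10
    type_attributes: tuple[int, int] = (1, 5)
    type_values: tuple[int, int] = (1, 3)
    n_objects: int = 3
    max_topic_size: int = 3
    #: one value per attribute of the object's type (config switch; the
    #: alternative would allow objects with unvalued attributes)
    one_value_per_attribute: bool = True

    def validate(self) -> None:
        if min(self.n_attributes, self.n_values, self.n_types) < 1:
            raise ConfigurationError("attribute/value/type counts must be >= 1")
        lo, hi = self.type_attributes
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid type_attributes range")
        vlo, vhi = self.type_values
        if not (1 <= vlo <= vhi):
            raise ConfigurationError("invalid type_values range")
        if vlo > self.n_values:
            raise ConfigurationError("values-per-type exceeds global values")
        if self.n_objects < 1:
            raise ConfigurationError("n_objects must be >= 1")


@dataclass(frozen=True)
class TypeSpec:
    """An object type: which values each of its attributes may take."""

    type_id: str
    allowed: dict[str, tuple[str, ...]]

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.allowed)

    def possible_properties(self) -> frozenset[Property]:
        return frozenset(
            (a, v) for a, vals in self.allowed.items() for v in vals
        )


@dataclass(frozen=True)
class Ontology:
    attributes: tuple[str, ...]
    values: dict[str, tuple[str, ...]]
    types: tuple[TypeSpec, ...]
    # caches, derived in __post_init__
    _type_props: tuple[frozenset[Property], ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_type_props", tuple(t.possible_properties() for t in self.types)
        )

    @property
    def type_property_sets(self) -> tuple[frozenset[Property], ...]:
        """Possible-property set of every type, for selection restrictions."""
        return self._type_props

    def all_properties(self) -> list[Property]:
        return [(a, v) for a in self.attributes for v in self.values[a]]

    def siblings(self, prop: Property) -> tuple[Property, ...]:
        a, v = prop
        return tuple((a, w) for w in self.values[a] if w != v)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "attributes": list(self.attributes),
            "values": {a: list(vs) for a, vs in self.values.items()},
            "types": [
                {"type_id": t.type_id,
                 "allowed": {a: list(vs) for a, vs in t.allowed.items()}}
                for t in self.types
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ontology":
        return cls(
            attributes=tuple(d["attributes"]),
            values={a: tuple(vs) for a, vs in d["values"].items()},
            types=tuple(
                TypeSpec(t["type_id"], {a: tuple(vs) for a, vs in t["allowed"].items()})
                for t in d["types"]
            ),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class ObjectInstance:
    object_id: str
    type_id: str
    properties: frozenset[Property]

    def value_of(self, attribute: str) -> str | None:
        for a, v in self.properties:
            if a == attribute:
                return v
        return None


@dataclass(frozen=True)
class SituationModel:
    """A shared context: the objects both agents can see."""

    objects: tuple[ObjectInstance, ...]
    shared: bool = True

    def __len__(self) -> int:
        return len(self.objects)

    def to_dict(self) -> dict:
        return {
            "shared": self.shared,
            "objects": [
                {"object_id": o.object_id, "type_id": o.type_id,
                 "properties": sorted(map(list, o.properties))}
                for o in self.objects
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SituationModel":
        return cls(
            objects=tuple(
                ObjectInstance(o["object_id"], o["type_id"],
                               frozenset(tuple(p) for p in o["properties"]))
                for o in d["objects"]
            ),
            shared=d.get("shared", True),
        )


def _attribute_names(n: int) -> list[str]:
    """a, b, ..., z, a1, b1, ... for arbitrarily many attributes."""
    letters = string.ascii_lowercase
    names = []
    for i in range(n):
        suffix = "" if i < 26 else str(i // 26)
        names.append(letters[i % 26] + suffix)
    return names


def generate_ontology(config: GenerationConfig, rng: random.Random) -> Ontology:
    """Draw a random ontology.

    Deterministic for a fixed ``rng`` state.  Every type gets a uniformly
    drawn number of attributes within ``config.type_attributes`` and, per
    attribute, a uniformly drawn number of allowed values within
    ``config.type_values``.
    """
    config.validate()
    attrs = tuple(_attribute_names(config.n_attributes))
    values = {a: tuple(f"{a}-{i + 1}" for i in range(config.n_values)) for a in attrs}
    lo, hi = config.type_attributes
    hi = min(hi, config.n_attributes)
    lo = min(lo, hi)
    vlo, vhi = config.type_values
    vhi = min(vhi, config.n_values)
    types = []
    for k in range(config.n_types):
        n_attr = rng.randint(lo, hi)
        chosen = sorted(rng.sample(attrs, n_attr))
        allowed = {}
        for a in chosen:
            n_val = rng.randint(vlo, vhi)
            allowed[a] = tuple(sorted(rng.sample(values[a], n_val)))
        types.append(TypeSpec(f"t-{k + 1}", allowed))
    return Ontology(attributes=attrs, values=values, types=tuple(types))


def generate_situation(
    ontology: Ontology,
    n_objects: int,
    rng: random.Random,
    start_index: int = 1,
) -> SituationModel:
    """Sample a situation: per object a uniform type, then one allowed value
    for every attribute of that type."""
    if n_objects < 1:
        raise ConfigurationError("n_objects must be >= 1")
    if not ontology.types:
        raise ConfigurationError("ontology has no types")
    objs = []
    for i in range(n_objects):
        tspec = ontology.types[rng.randrange(len(ontology.types))]
        props = frozenset(
            (a, vals[rng.randrange(len(vals))]) for a, vals in tspec.allowed.items()
        )
        objs.append(
            ObjectInstance(f"o-{start_index + i}", tspec.type_id, props)
        )
    return SituationModel(objects=tuple(objs))


def choose_topic(
    situation: SituationModel,
    rng: random.Random,
    max_size: int = 3,
) -> tuple[ObjectInstance, ...]:
    """Choose the topic: size uniform on {1..max_size}, members without
    replacement."""
    max_size = min(max_size, len(situation.objects))
    size = rng.randint(1, max_size)
    return tuple(rng.sample(situation.objects, size))
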