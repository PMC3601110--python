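"""Feature matrices over attribute x value cells and their unification.

A feature matrix assigns each (attribute, value) cell one of three states:
required (+), excluded (-) or open (?).  Word matrices are derived from
lexical meanings (the + and sibling - cells are then *grounded*); marker
matrices are purely conventional.  Two matrices are merged cellwise by
logical unification: +/- on the same cell is a clash, open cells adopt the
counterpart's state.  Unification failure is returned as ``None`` (a value,
not an exception), so search loops can use it as a pruning signal.

Internally a matrix is a pair of bitmasks over the flattened cell grid,
which makes unification a couple of integer operations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .world import Ontology, Property

__all__ = ["PropertySpace", "FeatureMatrix"]


class PropertySpace:
    """Flattened indexing of every (attribute, value) cell of an ontology.

    All matrices of one experiment share a single space instance; matrices
    from different spaces refuse to unify (dimension mismatch).
    """

    __slots__ = ("cells", "index", "attr_masks", "sibling_masks", "attributes")

    def __init__(self, ontology: Ontology):
        self.cells: tuple[Property, ...] = tuple(ontology.all_properties())
        self.index: dict[Property, int] = {p: i for i, p in enumerate(self.cells)}
        self.attributes = ontology.attributes
        self.attr_masks: dict[str, int] = {}
        for i, (a, _v) in enumerate(self.cells):
            self.attr_masks[a] = self.attr_masks.get(a, 0) | (1 << i)
        self.sibling_masks: dict[Property, int] = {
            p: self.attr_masks[p[0]] & ~(1 << i) for p, i in self.index.items()
        }

    def __len__(self) -> int:
        return len(self.cells)

    def bit(self, prop: Property) -> int:
        try:
            return 1 << self.index[prop]
        except KeyError:
            raise KeyError(f"unknown property {prop!r}") from None


@dataclass(frozen=True, slots=True)
class FeatureMatrix:
    """States are encoded as two disjoint bitmasks; a cell with neither bit
    set is open.  ``grounded`` marks cells whose state derives from lexical
    meaning (never open by construction)."""

    space: PropertySpace
    plus: int = 0
    minus: int = 0
    grounded: int = 0

    def __post_init__(self) -> None:
        if self.plus & self.minus:
            raise ValueError("a cell cannot be both required and excluded")
        if self.grounded & ~(self.plus | self.minus):
            raise ValueError("grounded cells must be determined")

    # -- constructors --------------------------------------------------
    @classmethod
    def open(cls, space: PropertySpace) -> "FeatureMatrix":
        return cls(space)

    @classmethod
    def from_meaning(
        cls,
        space: PropertySpace,
        meaning: frozenset[Property] | set[Property],
        grounded: bool = True,
    ) -> "FeatureMatrix":
        """+ on each meaning property, - on its attribute siblings, every
        untouched attribute row fully open."""
        plus = minus = 0
        for p in meaning:
            plus |= space.bit(p)
            minus |= space.sibling_masks[p]
        if plus & minus:
            raise ValueError("meaning assigns two values to one attribute")
        g = (plus | minus) if grounded else 0
        return cls(space, plus, minus, g)

    # -- unification ---------------------------------------------------
    def unify(self, other: "FeatureMatrix") -> "FeatureMatrix | None":
        """Cellwise merge; ``None`` on a +/- clash."""
        if self.space is not other.space:
            raise ValueError("feature matrices come from different spaces")
        if (self.plus & other.minus) or (self.minus & other.plus):
            return None
        return FeatureMatrix(
            self.space,
            self.plus | other.plus,
            self.minus | other.minus,
            self.grounded | other.grounded,
        )

    def fits(self, other: "FeatureMatrix") -> bool:
        """True iff the two matrices unify (symmetric)."""
        if self.space is not other.space:
            raise ValueError("feature matrices come from different spaces")
        return not ((self.plus & other.minus) or (self.minus & other.plus))

    # -- inspection ----------------------------------------------------
    def state(self, prop: Property) -> str:
        b = self.space.bit(prop)
        if self.plus & b:
            return "+"
        if self.minus & b:
            return "-"
        return "?"

    def required(self) -> frozenset[Property]:
        return frozenset(
            p for p, i in self.space.index.items() if self.plus >> i & 1
        )

    def required_attributes(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.required())

    def n_required(self) -> int:
        return self.plus.bit_count()

    def is_open_row(self, attribute: str) -> bool:
        mask = self.space.attr_masks[attribute]
        return not ((self.plus | self.minus) & mask)

    def key(self) -> tuple[int, int]:
        """Equality key on the cell grid (ignores grounding)."""
        return (self.plus, self.minus)

    def render(self) -> str:
        """One row per attribute, symbols + - ?, visual grid layout."""
        rows = []
        for a in self.space.attributes:
            syms = " ".join(
                self.state(p) for p in self.space.cells if p[0] == a
            )
            rows.append(f"{a}: {syms}")
        return "\n".join(rows)


def random_matrix(space: PropertySpace, rng: random.Random) -> FeatureMatrix:
    """A random consistent matrix (used by property tests)."""
    plus = minus = 0
    for i in range(len(space)):
        r = rng.random()
        if r < 1 / 3:
            plus |= 1 << i
        elif r < 2 / 3:
            minus |= 1 << i
    return FeatureMatrix(space, plus, minus & ~plus)
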