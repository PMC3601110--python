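"""Co-reference hypothesis enumeration and pruning.

A hearer who receives an n-word utterance in a word-order-free language
must consider every set partition of the words as a co-reference hypothesis
(the number of partitions of n items is the Bell number B(n)).  Hypotheses
are then pruned by three knowledge sources: agreement markers (words
sharing a marker co-refer, distinct markers mean distinct referents),
selection restrictions (a block's combined properties must belong to a
single object type) and the situation model (blocks must be injectively
assignable to objects that satisfy them).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .world import Ontology, ObjectInstance, Property, SituationModel

__all__ = [
    "bell_number",
    "set_partitions",
    "enumerate_partitions",
    "apply_selection_restrictions",
    "ground_in_situation",
    "InterpretationResult",
    "Interpreter",
]

Partition = tuple[tuple[int, ...], ...]


def bell_number(n: int) -> int:
    """Exact number of set partitions of n labelled items (B(0)=1),
    computed with the Bell-triangle recurrence in arbitrary precision."""
    if n < 0:
        raise ValueError("n must be >= 0")
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for x in row:
            nxt.append(nxt[-1] + x)
        row = nxt
    return row[0]


@lru_cache(maxsize=32)
def set_partitions(n: int) -> tuple[Partition, ...]:
    """All partitions of {0..n-1} in canonical restricted-growth order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: list[Partition] = []

    def extend(i: int, blocks: list[list[int]]) -> None:
        if i == n:
            out.append(tuple(tuple(b) for b in blocks))
            return
        for b in blocks:
            b.append(i)
            extend(i + 1, blocks)
            b.pop()
        blocks.append([i])
        extend(i + 1, blocks)
        blocks.pop()

    extend(0, [])
    return tuple(out)


def _satisfies_grouping(partition: Partition, groups: dict[int, int]) -> bool:
    """Words with equal labels must share a block; words with different
    labels must not."""
    label_block: dict[int, int] = {}
    word_block: dict[int, int] = {}
    for bi, block in enumerate(partition):
        for w in block:
            word_block[w] = bi
    for w, lab in groups.items():
        bi = word_block[w]
        if lab in label_block:
            if label_block[lab] != bi:
                return False
        else:
            if bi in label_block.values():
                return False
            label_block[lab] = bi
    # two labels may not share a block
    return len(set(label_block.values())) == len(label_block)


def enumerate_partitions(
    n_words: int,
    marker_groups: dict[int, int] | None = None,
) -> list[Partition]:
    """All B(n) partitions, or only those consistent with a marker-induced
    grouping (word index -> group label)."""
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    parts = set_partitions(n_words)
    if not marker_groups:
        return list(parts)
    for w in marker_groups:
        if not 0 <= w < n_words:
            raise ValueError(f"marker grouping references absent word {w}")
    return [p for p in parts if _satisfies_grouping(p, marker_groups)]


@dataclass(slots=True)
class InterpretationResult:
    """Counts and survivors of the enumerate -> restrict -> ground funnel.

    ``interpretations`` holds (partition, binding) readings, a binding being
    a tuple of object ids aligned with the partition's blocks.  A partition
    with several consistent bindings contributes several readings;
    ``n_grounded`` counts surviving partitions, ``n_readings`` counts
    readings (ambiguity is judged on readings).
    """

    n_words: int
    n_partitions_total: int
    n_after_restrictions: int
    n_grounded: int
    n_readings: int
    interpretations: list[tuple[Partition, tuple[str, ...]]]

    @property
    def unique(self) -> bool:
        return self.n_readings == 1

    @property
    def ambiguous(self) -> bool:
        return self.n_readings > 1

    def referents(self) -> frozenset[str] | None:
        """Objects of the unique reading, if any."""
        if not self.unique:
            return None
        return frozenset(self.interpretations[0][1])


class Interpreter:
    """Pruning engine bound to one ontology; meanings and objects are
    compiled to property bitmasks so per-game work stays cheap."""

    def __init__(self, ontology: Ontology):
        self.ontology = ontology
        cells = ontology.all_properties()
        self.prop_bit = {p: 1 << i for i, p in enumerate(cells)}
        self.type_masks = [
            self._mask(props) for props in ontology.type_property_sets
        ]
        self._type_ok: dict[int, bool] = {}

    def _mask(self, props) -> int:
        m = 0
        for p in props:
            m |= self.prop_bit[p]
        return m

    def _block_ok(self, mask: int) -> bool:
        ok = self._type_ok.get(mask)
        if ok is None:
            ok = any((mask & ~t) == 0 for t in self.type_masks)
            self._type_ok[mask] = ok
        return ok

    def restrict(
        self, partitions: list[Partition], word_masks: list[int]
    ) -> list[Partition]:
        out = []
        for part in partitions:
            for block in part:
                m = 0
                for w in block:
                    m |= word_masks[w]
                if not self._block_ok(m):
                    break
            else:
                out.append(part)
        return out

    def ground(
        self,
        partitions: list[Partition],
        word_masks: list[int],
        situation: SituationModel,
        injective: bool = True,
    ) -> list[tuple[Partition, tuple[str, ...]]]:
        obj_masks = [self._mask(o.properties) for o in situation.objects]
        obj_ids = [o.object_id for o in situation.objects]
        readings = []
        for part in partitions:
            block_masks = []
            for block in part:
                m = 0
                for w in block:
                    m |= word_masks[w]
                block_masks.append(m)
            # candidate objects per block
            cand = [
                [j for j, om in enumerate(obj_masks) if (bm & ~om) == 0]
                for bm in block_masks
            ]
            if any(not c for c in cand):
                continue

            def assign(i: int, used: int, picked: list[int]) -> None:
                if i == len(cand):
                    readings.append(
                        (part, tuple(obj_ids[j] for j in picked))
                    )
                    return
                for j in cand[i]:
                    if injective and (used >> j) & 1:
                        continue
                    assign(i + 1, used | (1 << j), picked + [j])

            assign(0, 0, [])
        return readings

    def interpret(
        self,
        meanings: list[frozenset[Property]],
        situation: SituationModel,
        marker_groups: dict[int, int] | None = None,
        injective: bool = True,
    ) -> InterpretationResult:
        """Full funnel for one utterance."""
        n = len(meanings)
        word_masks = [self._mask(m) for m in meanings]
        partitions = enumerate_partitions(n, marker_groups)
        restricted = self.restrict(partitions, word_masks)
        readings = self.ground(restricted, word_masks, situation, injective)
        return InterpretationResult(
            n_words=n,
            n_partitions_total=bell_number(n),
            n_after_restrictions=len(restricted),
            n_grounded=len({tuple(p) for p, _ in readings}),
            n_readings=len(readings),
            interpretations=readings,
        )


def apply_selection_restrictions(
    partitions: list[Partition],
    meanings: list[frozenset[Property]],
    ontology: Ontology,
) -> list[Partition]:
    """Keep a hypothesis iff every block's combined properties fit within a
    single type's possible properties."""
    interp = Interpreter(ontology)
    return interp.restrict(partitions, [interp._mask(m) for m in meanings])


def ground_in_situation(
    partitions: list[Partition],
    meanings: list[frozenset[Property]],
    situation: SituationModel,
    ontology: Ontology,
    injective: bool = True,
) -> InterpretationResult:
    """Ground pre-restricted hypotheses in a shared situation model."""
    interp = Interpreter(ontology)
    word_masks = [interp._mask(m) for m in meanings]
    readings = interp.ground(partitions, word_masks, situation, injective)
    n = len(meanings)
    return InterpretationResult(
        n_words=n,
        n_partitions_total=bell_number(n),
        n_after_restrictions=len(partitions),
        n_grounded=len({tuple(p) for p, _ in readings}),
        n_readings=len(readings),
        interpretations=readings,
    )
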