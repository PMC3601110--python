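"""Population-level measures computed from game logs.

* usage U(n, w): distinct marker forms effectively used in the window of w
  games ending at game n (the whole prefix while n < w).
* variation V(n, w): 1 minus the fraction of windowed games in which the
  hearer's counterfactual marker choice equalled the speaker's; only games
  where the speaker used at least one marker carry the indicator.
* inventory size I(n): distinct marker forms introduced by the whole
  population up to game n (inventions plus any seeded initial system).
* efficiency E(n) = U(n, w) / I(n): how well superfluous inventions were
  avoided; undefined (NaN) while I(n) = 0.
* population change P(n): cumulative number of agent replacements.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game import GameRecord

__all__ = [
    "usage",
    "variation",
    "efficiency",
    "population_change",
    "marker_frequency",
    "MeasureSeries",
]


def _window(records: list[GameRecord], n: int, w: int) -> list[GameRecord]:
    lo = max(1, n - w + 1)  # w games ending at n; the prefix while n < w
    return [r for r in records if lo <= r.index <= n]


def usage(records: list[GameRecord], n: int, w: int) -> int:
    forms = {f for r in _window(records, n, w) for f in r.markers_used}
    return len(forms)


def variation(records: list[GameRecord], n: int, w: int) -> float | None:
    flags = [
        r.counterfactual_match
        for r in _window(records, n, w)
        if r.counterfactual_match is not None
    ]
    if not flags:
        return None
    return 1.0 - sum(flags) / len(flags)


def inventory_size(
    records: list[GameRecord], n: int, initial_forms: tuple[str, ...] = ()
) -> int:
    forms = set(initial_forms)
    for r in records:
        if r.index > n:
            break
        forms.update(r.invented)
    return len(forms)


def efficiency(
    records: list[GameRecord], n: int, w: int,
    initial_forms: tuple[str, ...] = (),
) -> float | None:
    i = inventory_size(records, n, initial_forms)
    if i == 0:
        return None
    return usage(records, n, w) / i


def population_change(records: list[GameRecord], n: int) -> int:
    return sum(1 for r in records if r.index <= n and r.replaced)


def marker_frequency(records: list[GameRecord]) -> pd.Series:
    """Per-form usage counts, sorted descending (rank-frequency export)."""
    counts = Counter(f for r in records for f in r.markers_used)
    s = pd.Series(counts, dtype=int).sort_values(ascending=False)
    s.index.name = "marker"
    s.name = "count"
    return s


@dataclass
class MeasureSeries:
    """Per-game traces of all measures, computed in one sweep."""

    frame: pd.DataFrame
    window: int

    @classmethod
    def compute(
        cls,
        records: list[GameRecord],
        window: int = 50,
        initial_forms: tuple[str, ...] = (),
        stride: int = 1,
    ) -> "MeasureSeries":
        w = window
        use_counts: Counter = Counter()
        win: deque[GameRecord] = deque()
        cf_total = cf_match = 0
        len_sum = len_cnt = 0
        succ = 0
        invented = set(initial_forms)
        replacements = 0
        rows = []
        for r in records:
            win.append(r)
            for f in r.markers_used:
                use_counts[f] += 1
                len_sum += len(f)
                len_cnt += 1
            if r.counterfactual_match is not None:
                cf_total += 1
                cf_match += r.counterfactual_match
            succ += int(r.success)
            invented.update(r.invented)
            replacements += int(r.replaced)
            while len(win) > w:
                old = win.popleft()
                for f in old.markers_used:
                    use_counts[f] -= 1
                    if not use_counts[f]:
                        del use_counts[f]
                    len_sum -= len(f)
                    len_cnt -= 1
                if old.counterfactual_match is not None:
                    cf_total -= 1
                    cf_match -= old.counterfactual_match
                succ -= int(old.success)
            if r.index % stride == 0 or r.index == records[-1].index:
                rows.append(
                    (
                        r.index,
                        len(use_counts),
                        (1.0 - cf_match / cf_total) if cf_total else np.nan,
                        len(invented),
                        len(use_counts) / len(invented) if invented else np.nan,
                        replacements,
                        succ / len(win),
                        len_sum / len_cnt if len_cnt else np.nan,
                    )
                )
        frame = pd.DataFrame(
            rows,
            columns=["game", "U", "V", "I", "E", "P", "success", "marker_len"],
        )
        return cls(frame=frame, window=w)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
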