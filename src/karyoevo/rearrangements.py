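"""Chromosome-rearrangement event calculus on karyotype formulae.

Three event types drive diploid-number and morphology evolution in helicoid
land snails:

* translocation (tandem/Robertsonian fusion): two pairs merge into one
  biarmed pair, 2n decreases by 2;
* fission: one biarmed pair splits into two telocentric pairs, 2n increases
  by 2;
* pericentric inversion: one pair changes morphology class, 2n unchanged.

Minimal event counts between two karyotypes follow directly: the
translocation/fission count is |delta 2n| / 2, and with equal pair numbers the
minimal inversion count is half the L1 distance between the class-count
vectors (each inversion re-classifies exactly one pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import BIARMED_CLASSES, MORPH_CLASSES, KaryotypeFormula

DEFAULT_DIPLOID_RANGE: tuple[int, int] = (30, 80)


@dataclass(frozen=True)
class EventCount:
    """Counts of the three rearrangement event types."""

    translocations: int = 0
    fissions: int = 0
    inversions: int = 0

    def __post_init__(self) -> None:
        for name in ("translocations", "fissions", "inversions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.translocations + self.fissions + self.inversions

    def __add__(self, other: "EventCount") -> "EventCount":
        return EventCount(
            self.translocations + other.translocations,
            self.fissions + other.fissions,
            self.inversions + other.inversions,
        )


# --- individual events, applicable to formulae ------------------------------


@dataclass(frozen=True)
class Translocation:
    """Merge one pair of class ``class_a`` and one of ``class_b`` into a
    single biarmed pair of class ``result`` (2n decreases by 2)."""

    class_a: str
    class_b: str
    result: str = "m"

    def apply(self, f: KaryotypeFormula) -> KaryotypeFormula:
        for c in (self.class_a, self.class_b):
            if c not in MORPH_CLASSES:
                raise ValueError(f"unknown morphology class {c!r}")
        if self.result not in BIARMED_CLASSES:
            raise ValueError("translocation product must be biarmed")
        counts = dict(f.counts)
        counts[self.class_a] -= 1
        counts[self.class_b] -= 1
        counts[self.result] += 1
        if min(counts.values()) < 0:
            blocking = [c for c, k in counts.items() if k < 0]
            raise ValueError(
                f"translocation infeasible: no pair available in class(es) {blocking}"
            )
        return KaryotypeFormula(counts)

    def describe(self) -> str:
        return f"T\tmerge {self.class_a}+{self.class_b} -> {self.result}"


@dataclass(frozen=True)
class Fission:
    """Split one biarmed pair of class ``class_a`` into two pairs of the
    classes in ``result`` (2n increases by 2)."""

    class_a: str
    result: tuple[str, str] = ("t", "t")

    def apply(self, f: KaryotypeFormula) -> KaryotypeFormula:
        if self.class_a not in BIARMED_CLASSES:
            raise ValueError(
                f"fission requires a biarmed pair, got class {self.class_a!r}"
            )
        counts = dict(f.counts)
        counts[self.class_a] -= 1
        if counts[self.class_a] < 0:
            raise ValueError(
                f"fission infeasible: no pair available in class {self.class_a!r}"
            )
        for c in self.result:
            counts[c] += 1
        return KaryotypeFormula(counts)

    def describe(self) -> str:
        return f"F\tsplit {self.class_a} -> {'+'.join(self.result)}"


@dataclass(frozen=True)
class Inversion:
    """Move one pair from ``class_a`` to ``class_b`` (pericentric inversion)."""

    class_a: str
    class_b: str

    def apply(self, f: KaryotypeFormula) -> KaryotypeFormula:
        if self.class_a == self.class_b:
            raise ValueError("inversion must change the morphology class")
        counts = dict(f.counts)
        counts[self.class_a] -= 1
        counts[self.class_b] += 1
        if counts[self.class_a] < 0:
            raise ValueError(
                f"inversion infeasible: no pair available in class {self.class_a!r}"
            )
        return KaryotypeFormula(counts)

    def describe(self) -> str:
        return f"I\t{self.class_a} -> {self.class_b}"


Event = Translocation | Fission | Inversion


def apply_events(
    formula: KaryotypeFormula, events: Sequence[Event]
) -> KaryotypeFormula:
    """Apply a sequence of events to a formula, left to right."""
    f = formula
    for e in events:
        f = e.apply(f)
    return f


# --- minimal pairwise counts ------------------------------------------------


def _check_diploid(value: int, diploid_range: tuple[int, int]) -> int:
    v = int(value)
    if v % 2:
        raise ValueError(f"diploid number must be even, got {v}")
    lo, hi = diploid_range
    if not lo <= v <= hi:
        raise ValueError(f"diploid number {v} outside allowed range [{lo}, {hi}]")
    return v


def count_translocations_fissions(
    diploid_a: int,
    diploid_b: int,
    diploid_range: tuple[int, int] = DEFAULT_DIPLOID_RANGE,
) -> EventCount:
    """Minimal translocation/fission count from ``diploid_a`` to ``diploid_b``.

    Each translocation reduces 2n by 2 and each fission raises it by 2, so the
    minimal count is ``|diploid_a - diploid_b| / 2`` events of a single type;
    the direction is a -> b.
    """
    a = _check_diploid(diploid_a, diploid_range)
    b = _check_diploid(diploid_b, diploid_range)
    if a > b:
        return EventCount(translocations=(a - b) // 2)
    if a < b:
        return EventCount(fissions=(b - a) // 2)
    return EventCount()


def inversion_distance(
    formula_a: KaryotypeFormula, formula_b: KaryotypeFormula
) -> int:
    """Minimal number of inversions transforming ``formula_a`` into ``formula_b``.

    Valid only for equal pair numbers. One inversion moves exactly one pair
    between classes, so the minimum is the number of pairs that must change
    class: half the L1 distance between the class-count vectors.
    """
    if formula_a.n_pairs != formula_b.n_pairs:
        raise ValueError(
            f"pair numbers differ ({formula_a.n_pairs} vs {formula_b.n_pairs}); "
            "inversions conserve 2n — use combined_event_path for mixed events"
        )
    l1 = sum(
        abs(formula_a.counts[c] - formula_b.counts[c]) for c in MORPH_CLASSES
    )
    assert l1 % 2 == 0
    return l1 // 2


def combined_event_path(
    formula_a: KaryotypeFormula,
    formula_b: KaryotypeFormula,
    merge_result: str = "m",
    fission_result: tuple[str, str] = ("t", "t"),
) -> list[Event]:
    """An explicit event path from ``formula_a`` to ``formula_b``.

    First |delta 2n|/2 translocations (or fissions) adjust the pair number,
    then the minimal inversions reconcile the class counts. Merged pairs
    become ``merge_result`` (default m) and fission products ``fission_result``
    (default two telocentrics), following the usual Robertsonian expectation.
    Translocations preferentially consume pairs from the classes holding the
    largest surplus relative to the target, which keeps intermediates feasible
    and the inversion tail short; the rule is deterministic.

    Replaying the returned events on ``formula_a`` yields ``formula_b``.
    """
    events: list[Event] = []
    current = formula_a
    n_merges = max(0, formula_a.n_pairs - formula_b.n_pairs)
    n_splits = max(0, formula_b.n_pairs - formula_a.n_pairs)

    def surplus_order(counts: dict[str, int]) -> list[str]:
        # classes by descending surplus over the target, class order breaking ties
        return [
            c
            for c in sorted(
                MORPH_CLASSES,
                key=lambda c: (
                    -(counts[c] - formula_b.counts[c]),
                    MORPH_CLASSES.index(c),
                ),
            )
            if counts[c] > 0
        ]

    for _ in range(n_merges):
        avail = surplus_order(dict(current.counts))
        if not avail:
            raise ValueError("translocation infeasible: no pairs available")
        a = avail[0]
        remaining = dict(current.counts)
        remaining[a] -= 1
        avail2 = surplus_order(remaining)
        if not avail2:
            raise ValueError(
                f"translocation infeasible: only one pair left (class {a!r})"
            )
        ev = Translocation(a, avail2[0], merge_result)
        current = ev.apply(current)
        events.append(ev)

    for _ in range(n_splits):
        biarmed = [
            c
            for c in sorted(
                BIARMED_CLASSES,
                key=lambda c: (
                    -(current.counts[c] - formula_b.counts[c]),
                    MORPH_CLASSES.index(c),
                ),
            )
            if current.counts[c] > 0
        ]
        if not biarmed:
            raise ValueError(
                "fission infeasible: no biarmed pair available (blocking class: t)"
            )
        ev = Fission(biarmed[0], fission_result)
        current = ev.apply(current)
        events.append(ev)

    # inversion tail: move surplus pairs into deficit classes
    surplus = {
        c: current.counts[c] - formula_b.counts[c]
        for c in MORPH_CLASSES
        if current.counts[c] > formula_b.counts[c]
    }
    deficit = {
        c: formula_b.counts[c] - current.counts[c]
        for c in MORPH_CLASSES
        if formula_b.counts[c] > current.counts[c]
    }
    for src in MORPH_CLASSES:
        while surplus.get(src, 0) > 0:
            dst = next(c for c in MORPH_CLASSES if deficit.get(c, 0) > 0)
            ev = Inversion(src, dst)
            current = ev.apply(current)
            events.append(ev)
            surplus[src] -= 1
            deficit[dst] -= 1
    assert current == formula_b, "event path failed to reach target formula"
    return events
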