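"""Karyotype data model: arm measurements, centromeric index, morphology classes.

A karyotype is described by its chromosome pairs. Each pair has a short and a
long arm; from these we derive the relative length (RL, percent of the total
haploid complement length) and the centromeric index (CI, short-arm length as a
percent of the whole chromosome). The CI places the pair in one of four
morphology classes of the Levan convention:

    m  (metacentric)     CI in [37.5, 50]
    sm (submetacentric)  CI in [25.0, 37.5)
    st (subtelocentric)  CI in [12.5, 25.0)
    t  (telocentric)     CI in [ 0.0, 12.5)

A karyotype *formula* such as ``10m+1sm+16t`` summarises the complement as a
multiset of morphology classes over the haploid number of pairs, and is the
unit on which rearrangement arithmetic operates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Morphology classes ordered from most to least metacentric.
MORPH_CLASSES: tuple[str, ...] = ("m", "sm", "st", "t")

#: Classes with two arms; only "t" is single-armed.
BIARMED_CLASSES: tuple[str, ...] = ("m", "sm", "st")

# Lower CI bound of each class, most metacentric first. Boundary values assign
# to the more metacentric side (CI = 37.5 is "m", CI = 25.0 is "sm", ...).
_CLASS_LOWER_BOUNDS: tuple[tuple[str, float], ...] = (
    ("m", 37.5),
    ("sm", 25.0),
    ("st", 12.5),
    ("t", 0.0),
)


def classify_pair(centromeric_index: float) -> str:
    """Assign a morphology class from a centromeric index.

    Parameters
    ----------
    centromeric_index : float
        Short-arm percentage of total chromosome length, in [0, 50].

    Returns
    -------
    str
        One of ``"m"``, ``"sm"``, ``"st"``, ``"t"``.
    """
    ci = float(centromeric_index)
    if not 0.0 <= ci <= 50.0:
        raise ValueError(
            f"centromeric index must lie in [0, 50], got {centromeric_index!r}"
        )
    for cls, lower in _CLASS_LOWER_BOUNDS:
        if ci >= lower:
            return cls
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class ChromosomePair:
    """One chromosome pair of a measured karyotype.

    Attributes
    ----------
    index : int
        1-based rank by decreasing relative length.
    short_arm, long_arm : float
        Arm lengths in arbitrary units (``short_arm <= long_arm``).
    relative_length : float
        Percent of the total haploid complement length.
    centromeric_index : float
        ``100 * short_arm / (short_arm + long_arm)``, in [0, 50].
    morph_class : str
        Levan morphology class derived from the centromeric index.
    """

    index: int
    short_arm: float
    long_arm: float
    relative_length: float
    centromeric_index: float
    morph_class: str

    def __post_init__(self) -> None:
        if self.short_arm > self.long_arm:
            raise ValueError("short arm exceeds long arm")
        if not 0.0 <= self.centromeric_index <= 50.0:
            raise ValueError("centromeric index outside [0, 50]")
        if self.morph_class != classify_pair(self.centromeric_index):
            raise ValueError("morph_class inconsistent with centromeric index")


@dataclass(frozen=True)
class KaryotypeFormula:
    """A karyotype summarised as pair counts per morphology class.

    ``counts`` maps each of the four classes to a non-negative number of
    chromosome *pairs*; the haploid number ``n_pairs`` is their sum and the
    diploid number is twice that.
    """

    counts: Mapping[str, int] = field()

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for cls in MORPH_CLASSES:
            k = int(self.counts.get(cls, 0))
            if k < 0:
                raise ValueError(f"negative pair count for class {cls!r}: {k}")
            clean[cls] = k
        unknown = set(self.counts) - set(MORPH_CLASSES)
        if unknown:
            raise ValueError(f"unknown morphology classes: {sorted(unknown)}")
        if sum(clean.values()) == 0:
            raise ValueError("formula must contain at least one pair")
        object.__setattr__(self, "counts", clean)

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def diploid_number(self) -> int:
        return 2 * self.n_pairs

    def __getitem__(self, cls: str) -> int:
        return self.counts[cls]

    def __str__(self) -> str:
        return format_formula(self)

    def as_vector(self) -> tuple[int, int, int, int]:
        """Counts in fixed class order (m, sm, st, t)."""
        return tuple(self.counts[c] for c in MORPH_CLASSES)  # type: ignore[return-value]

    def replace(self, **deltas: int) -> "KaryotypeFormula":
        """Return a new formula with per-class count deltas applied."""
        new = dict(self.counts)
        for cls, d in deltas.items():
            new[cls] = new.get(cls, 0) + d
        return KaryotypeFormula(new)

    @classmethod
    def from_chromosome_counts(
        cls, chromosome_counts: Mapping[str, int], haploid: bool = False
    ) -> "KaryotypeFormula":
        """Build a formula from per-class *chromosome* (element) counts.

        Haploid complements (``haploid=True``, e.g. counts read off an n-plate)
        translate directly into pair counts. Diploid complements must contain
        an even element count in every class.
        """
        if haploid:
            return cls(dict(chromosome_counts))
        pairs: dict[str, int] = {}
        for c, k in chromosome_counts.items():
            k = int(k)
            if k % 2:
                raise ValueError(
                    f"diploid chromosome count for class {c!r} is odd ({k}); "
                    "cannot form whole pairs"
                )
            pairs[c] = k // 2
        return cls(pairs)


class FormulaParseError(ValueError):
    """Raised when a karyotype formula string cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


_TOKEN_RE = re.compile(r"(\d+)\s*(sm|st|m|t)\s*", re.IGNORECASE)
_SEP_RE = re.compile(r"[+,\s]+")


def parse_formula(text: str) -> KaryotypeFormula:
    """Parse a karyotype formula string such as ``"10m+1sm+16t"``.

    Tokens are ``<count><class>`` with optional space before the class symbol
    ("24 m" and "24m" are equivalent); separators may be "+", commas or
    whitespace, mirroring the mixed styles of printed formulae.
    """
    if not isinstance(text, str):
        raise FormulaParseError(f"expected a string, got {type(text).__name__}")
    pos = 0
    counts: dict[str, int] = {c: 0 for c in MORPH_CLASSES}
    n = len(text)
    # skip leading separators
    m = _SEP_RE.match(text, pos)
    if m:
        pos = m.end()
    if pos >= n:
        raise FormulaParseError("empty formula string", pos)
    while pos < n:
        tok = _TOKEN_RE.match(text, pos)
        if not tok:
            raise FormulaParseError(
                f"unrecognised token {text[pos:pos + 8]!r}", pos
            )
        count, cls = int(tok.group(1)), tok.group(2).lower()
        if counts[cls] and count:
            logger.debug("class %s repeated in formula %r; counts summed", cls, text)
        counts[cls] += count
        pos = tok.end()
        sep = _SEP_RE.match(text, pos)
        if sep:
            pos = sep.end()
        elif pos < n and text[pos] == "+":
            pos += 1
    return KaryotypeFormula(counts)


def format_formula(formula: KaryotypeFormula) -> str:
    """Canonical formula string: ``"<k>m+<k>sm+<k>st+<k>t"``, zero classes omitted."""
    parts = [
        f"{formula.counts[c]}{c}" for c in MORPH_CLASSES if formula.counts[c] > 0
    ]
    return "+".join(parts)


def fundamental_number(formula: KaryotypeFormula) -> int:
    """Fundamental number NF: total chromosome arms in the diploid complement.

    Biarmed pairs (m, sm, st) contribute two arms per chromosome, telocentric
    pairs one; each pair holds two chromosomes.
    """
    biarmed = sum(formula.counts[c] for c in BIARMED_CLASSES)
    return 2 * (2 * biarmed + formula.counts["t"])


@dataclass(frozen=True)
class Karyotype:
    """An ordered, measured karyotype (pairs sorted by decreasing RL)."""

    pairs: tuple[ChromosomePair, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("karyotype must contain at least one pair")
        total_rl = sum(p.relative_length for p in self.pairs)
        if abs(total_rl - 100.0) > 1e-6:
            raise ValueError(f"relative lengths sum to {total_rl}, expected 100")
        rls = [p.relative_length for p in self.pairs]
        if any(a < b - 1e-12 for a, b in zip(rls, rls[1:])):
            raise ValueError("pairs must be sorted by decreasing relative length")

    @property
    def formula(self) -> KaryotypeFormula:
        counts: dict[str, int] = {c: 0 for c in MORPH_CLASSES}
        for p in self.pairs:
            counts[p.morph_class] += 1
        return KaryotypeFormula(counts)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def diploid_number(self) -> int:
        return 2 * len(self.pairs)


def compute_measurements(
    arm_lengths: Sequence[tuple[float, float]] | Iterable[tuple[float, float]],
) -> Karyotype:
    """Build a :class:`Karyotype` from per-pair (short, long) arm lengths.

    Relative length is each pair's share (percent) of the summed haploid
    complement length; the centromeric index is the short arm's share of its
    own chromosome. Pairs listed with the arms in the wrong order are swapped
    with a logged warning, since measurement tables list arms in either order.
    """
    rows = [(float(s), float(l)) for s, l in arm_lengths]
    if not rows:
        raise ValueError("at least one chromosome pair is required")
    fixed: list[tuple[float, float]] = []
    for i, (short, long) in enumerate(rows, start=1):
        if short < 0 or long < 0:
            raise ValueError(f"negative arm length in pair {i}: ({short}, {long})")
        if short > long:
            logger.warning(
                "pair %d lists short arm (%g) > long arm (%g); swapping", i, short, long
            )
            short, long = long, short
        if long <= 0:
            raise ValueError(f"pair {i} has no positive arm length")
        fixed.append((short, long))
    total = sum(s + l for s, l in fixed)
    # stable sort: ties keep input order
    order = sorted(range(len(fixed)), key=lambda i: -(fixed[i][0] + fixed[i][1]))
    pairs = []
    for rank, i in enumerate(order, start=1):
        short, long = fixed[i]
        length = short + long
        ci = 100.0 * short / length
        pairs.append(
            ChromosomePair(
                index=rank,
                short_arm=short,
                long_arm=long,
                relative_length=100.0 * length / total,
                centromeric_index=ci,
                morph_class=classify_pair(ci),
            )
        )
    return Karyotype(tuple(pairs))
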