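"""Curated karyotype records, tabular I/O, and small molecular utilities.

The package ships two curated record sets for helicoid land snails: the
newly karyotyped populations (15 species, one of them sampled twice) and the
literature/clade-level karyotypes quoted alongside them, together with a
Newick transcription of the source phylogeny's named clades. Records travel
as a tab-separated table; empty cells mean "not reported", never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .core import KaryotypeFormula, format_formula, parse_formula
from .parsimony import PhyloTree

logger = logging.getLogger(__name__)

TABLE_COLUMNS = (
    "species",
    "family",
    "subfamily",
    "tribe",
    "diploid_number",
    "formula",
    "nor_pairs",
    "source",
    "locality",
    "notes",
)
REQUIRED_COLUMNS = ("species", "diploid_number")


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon's karyotype plus taxonomy and annotations.

    ``species`` may name a species, a genus, or a higher clade when only a
    clade-level karyotype is reported. ``nor_pairs`` counts NOR-bearing
    chromosome pairs (single-pair location is the ancestral condition in
    mollusks). ``notes`` carries provenance and conflict flags as free text.
    """

    species: str
    family: str = ""
    subfamily: str = ""
    tribe: str = ""
    diploid_number: int | None = None
    formula: KaryotypeFormula | None = None
    nor_pairs: int | None = None
    source: str = ""
    locality: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label is required")
        if self.nor_pairs is not None and self.nor_pairs < 1:
            raise ValueError("nor_pairs must be >= 1 when reported")
        if (
            self.formula is not None
            and self.diploid_number is not None
            and self.formula.diploid_number != self.diploid_number
        ):
            raise ValueError(
                f"{self.species}: formula implies 2n={self.formula.diploid_number} "
                f"but diploid_number is {self.diploid_number}"
            )

    @property
    def taxonomy(self) -> str:
        return "/".join(p for p in (self.family, self.subfamily, self.tribe) if p)


@dataclass(frozen=True)
class RowError:
    """A malformed table row, reported but not fatal."""

    row: int  # 1-based data-row number (header excluded)
    message: str


def _cell(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def read_karyotype_table(path: str | Path) -> tuple[list[TaxonRecord], list[RowError]]:
    """Read a tab-separated karyotype table.

    Returns the valid records and a list of row-level errors (odd diploid
    numbers, unparsable formulae, formula/2n mismatches); valid rows are
    still returned when others fail. Missing required columns raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"karyotype table lacks required column(s): {missing}")
    records: list[TaxonRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(_row_to_record(row._asdict()))
        except (ValueError, KeyError) as exc:
            errors.append(RowError(i, str(exc)))
    if errors:
        logger.warning("%d malformed row(s) in %s", len(errors), path)
    return records, errors


def _row_to_record(row: Mapping[str, object]) -> TaxonRecord:
    diploid: int | None = None
    cell = _cell(row.get("diploid_number"))
    if cell:
        diploid = int(cell)
        if diploid % 2:
            raise ValueError(f"diploid number must be even, got {diploid}")
        if diploid <= 0:
            raise ValueError(f"diploid number must be positive, got {diploid}")
    formula = None
    cell = _cell(row.get("formula"))
    if cell:
        formula = parse_formula(cell)
    nor = None
    cell = _cell(row.get("nor_pairs"))
    if cell:
        nor = int(cell)
    return TaxonRecord(
        species=_cell(row.get("species")),
        family=_cell(row.get("family")),
        subfamily=_cell(row.get("subfamily")),
        tribe=_cell(row.get("tribe")),
        diploid_number=diploid,
        formula=formula,
        nor_pairs=nor,
        source=_cell(row.get("source")),
        locality=_cell(row.get("locality")),
        notes=_cell(row.get("notes")),
    )


def write_karyotype_table(records: Iterable[TaxonRecord], path: str | Path) -> None:
    """Write records as a tab-separated table (round-trip stable)."""
    rows = []
    for r in records:
        rows.append(
            {
                "species": r.species,
                "family": r.family,
                "subfamily": r.subfamily,
                "tribe": r.tribe,
                "diploid_number": "" if r.diploid_number is None else r.diploid_number,
                "formula": "" if r.formula is None else format_formula(r.formula),
                "nor_pairs": "" if r.nor_pairs is None else r.nor_pairs,
                "source": r.source,
                "locality": r.locality,
                "notes": r.notes,
            }
        )
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# --- built-in fixtures ------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("karyoevo").joinpath("data", name)))


def study_records() -> list[TaxonRecord]:
    """The 16 newly karyotyped records (15 species; *Theba pisana* twice)."""
    records, errors = read_karyotype_table(_data_path("study_karyotypes.tsv"))
    assert not errors, errors
    return records


def literature_records() -> list[TaxonRecord]:
    """Literature and clade-level karyotypes quoted in the source synthesis."""
    records, errors = read_karyotype_table(_data_path("literature.tsv"))
    assert not errors, errors
    return records


def fixture_tree() -> PhyloTree:
    """The transcription of the source phylogeny's named clades."""
    return PhyloTree.from_newick(_data_path("helicoidea_tree.nwk"))


def paper_fixtures() -> tuple[list[TaxonRecord], PhyloTree]:
    """All built-in records (new + literature) and the fixture phylogeny."""
    return study_records() + literature_records(), fixture_tree()


def tip_states_from_records(
    records: Iterable[TaxonRecord], tree: PhyloTree | None = None
) -> dict[str, int]:
    """Map taxon labels to diploid numbers, for use as reconstruction tips.

    Records without a diploid number are skipped; duplicate labels must agree
    (as the two *Theba pisana* populations do) or raise.
    """
    states: dict[str, int] = {}
    for r in records:
        if r.diploid_number is None:
            continue
        if r.species in states and states[r.species] != r.diploid_number:
            raise ValueError(
                f"conflicting diploid numbers for {r.species!r}: "
                f"{states[r.species]} vs {r.diploid_number}"
            )
        states[r.species] = r.diploid_number
    if tree is not None:
        states = {l: s for l, s in states.items() if l in set(tree.tip_labels())}
    return states


# --- molecular utilities ----------------------------------------------------

_VALID_BASES = frozenset("ACGT")


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Only columns where both symbols are unambiguous bases (ACGT) are compared;
    gap or N columns are excluded from numerator and denominator.
    """
    a, b = str(seq_a).upper(), str(seq_b).upper()
    if len(a) != len(b):
        raise ValueError(
            f"aligned lengths differ: {len(a)} vs {len(b)}"
        )
    comparable = 0
    diffs = 0
    for x, y in zip(a, b):
        if x in _VALID_BASES and y in _VALID_BASES:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        raise ValueError("no comparable (ungapped, unambiguous) columns")
    return diffs / comparable


def identity_percent(seq_a: str, seq_b: str) -> float:
    """Percent identity over comparable columns: ``100 * (1 - p_distance)``."""
    return 100.0 * (1.0 - p_distance(seq_a, seq_b))


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA file into an {id: sequence} mapping."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return seqs
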