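"""Data model and I/O for microbe sets and microbe-disease association records.

A *microbe set* is a named group of microbes sharing one annotation: either
association with the same disease or colonization of the same body position.
Sets live in a :class:`SetDatabase`, whose universe (the union of all member
names) is the default background for over-representation analysis.

Signed microbe-disease association records (one row per curated report of a
microbe increasing or decreasing in a disease) are held in an
:class:`AssociationTable`; record multiplicity is meaningful — it is the
evidence count ``W_ij`` used by the disease-similarity weighting — so
duplicate rows are preserved.

Name matching throughout the package is by normalized string equality:
lowercase, single-space separated, underscores treated as spaces. No
taxonomy-aware synonym resolution is attempted.
"""

from __future__ import annotations

import enum
import os
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Category",
    "Rank",
    "MicrobeSet",
    "SetDatabase",
    "AssociationRecord",
    "AssociationTable",
    "InvalidNameError",
    "ParseError",
    "normalize_name",
    "read_set_database",
    "write_set_database",
    "read_associations",
    "write_associations",
    "read_name_list",
    "sets_from_associations",
]


class InvalidNameError(ValueError):
    """Raised for empty or whitespace-only microbe names."""


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


class Category(str, enum.Enum):
    """Annotation rule that defines a microbe set."""

    DISEASE = "disease"
    POSITION = "position"


class Rank(str, enum.Enum):
    """Taxonomic resolution of a microbe name."""

    SPECIES = "species"
    GENUS = "genus"
    OTHER = "other"


_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Return the canonical lookup key for a microbe name.

    Lowercases, replaces underscores with spaces, collapses runs of
    whitespace to single spaces and strips the ends. Idempotent.

    Raises
    ------
    InvalidNameError
        If ``raw`` is empty or whitespace-only.
    """
    if not isinstance(raw, str):
        raise InvalidNameError(f"microbe name must be a string, got {type(raw).__name__}")
    key = _WS.sub(" ", raw.replace("_", " ")).strip().lower()
    if not key:
        raise InvalidNameError(f"empty microbe name: {raw!r}")
    return key


@dataclass(frozen=True)
class MicrobeSet:
    """A named, de-duplicated collection of normalized microbe names."""

    name: str
    category: Category
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("set name must be non-empty")
        object.__setattr__(self, "category", Category(self.category))
        members = frozenset(normalize_name(m) for m in self.members)
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


class SetDatabase:
    """An ordered collection of uniquely named :class:`MicrobeSet` objects.

    Sets may overlap; the universe is the exact union of all members and
    serves as the default background for enrichment.
    """

    def __init__(self, sets: Iterable[MicrobeSet]):
        self.sets: tuple[MicrobeSet, ...] = tuple(sets)
        names = [s.name for s in self.sets]
        dup = [n for n, c in Counter(names).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate set name(s): {sorted(dup)}")
        self._by_name = {s.name: s for s in self.sets}

    @property
    def universe(self) -> frozenset[str]:
        return frozenset().union(*(s.members for s in self.sets)) if self.sets else frozenset()

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[MicrobeSet]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> MicrobeSet:
        return self._by_name[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SetDatabase):
            return NotImplemented
        return sorted(self.sets, key=lambda s: s.name) == sorted(other.sets, key=lambda s: s.name)

    def filter(self, category: Category | str | None = None, min_size: int = 1) -> "SetDatabase":
        """Database restricted to one category and/or a minimum set size."""
        cat = Category(category) if category is not None else None
        return SetDatabase(
            s for s in self.sets if (cat is None or s.category == cat) and len(s) >= min_size
        )


@dataclass(frozen=True)
class AssociationRecord:
    """One curated report: ``microbe`` increased (+1) or decreased (-1) in ``disease``."""

    disease: str
    microbe: str
    direction: int

    def __post_init__(self) -> None:
        if not self.disease or not self.disease.strip():
            raise ValueError("disease label must be non-empty")
        object.__setattr__(self, "disease", self.disease.strip())
        object.__setattr__(self, "microbe", normalize_name(self.microbe))
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction!r}")


class AssociationTable:
    """A multiset of signed microbe-disease association records.

    ``diseases`` and ``microbes`` are the sorted distinct labels present in
    the records; their counts are the N (number of diseases) and M (number
    of microbes) of the disease-similarity method. The record count for a
    (disease, microbe) pair is the evidence weight ``W_ij``; the number of
    diseases with at least one record for microbe j is its disease
    frequency ``n_j``, irrespective of direction.
    """

    def __init__(self, records: Iterable[AssociationRecord]):
        self.records: tuple[AssociationRecord, ...] = tuple(records)
        if not self.records:
            raise ValueError("association table must contain at least one record")
        self.diseases: tuple[str, ...] = tuple(sorted({r.disease for r in self.records}))
        self.microbes: tuple[str, ...] = tuple(sorted({r.microbe for r in self.records}))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationTable):
            return NotImplemented
        return Counter(self.records) == Counter(other.records)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    def pair_count(self, disease: str, microbe: str) -> int:
        """W_ij: number of records (any direction) for the pair."""
        return sum(1 for r in self.records if r.disease == disease and r.microbe == microbe)

    def disease_frequency(self, microbe: str) -> int:
        """n_j: number of distinct diseases with at least one record for ``microbe``."""
        return len({r.disease for r in self.records if r.microbe == microbe})

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame with columns disease, microbe, direction."""
        return pd.DataFrame(
            {
                "disease": [r.disease for r in self.records],
                "microbe": [r.microbe for r in self.records],
                "direction": [r.direction for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# I/O


def read_set_database(path: str | os.PathLike) -> SetDatabase:
    """Read a GMT-style microbe-set file.

    One set per line: ``name<TAB>category<TAB>member1<TAB>member2...`` with
    ``category`` either ``disease`` or ``position``. Lines starting with
    ``#`` and blank lines are ignored. Members are normalized and
    de-duplicated within each line; duplicate set names are an error.
    """
    sets: list[MicrobeSet] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated fields "
                    f"(name, category, members...), got {len(fields)}"
                )
            name, cat_token, *members = fields
            name = name.strip()
            if not name:
                raise ParseError(f"{path}: line {lineno}: empty set name")
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            try:
                category = Category(cat_token.strip().lower())
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: unknown category {cat_token!r} "
                    f"(expected 'disease' or 'position')"
                ) from None
            members = [m for m in members if m.strip()]
            try:
                mset = MicrobeSet(name=name, category=category, members=frozenset(members))
            except InvalidNameError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            seen.add(name)
            sets.append(mset)
    return SetDatabase(sets)


def write_set_database(db: SetDatabase, path: str | os.PathLike) -> None:
    """Write ``db`` in the GMT-style dialect read by :func:`read_set_database`.

    Members are emitted in sorted order so output is deterministic.
    """
    lines = [
        "\t".join([s.name, s.category.value, *sorted(s.members)]) for s in db
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


_DIRECTION_TOKENS: Mapping[str, int] = {
    "increase": 1,
    "decrease": -1,
    "+1": 1,
    "1": 1,
    "-1": -1,
}


def read_associations(path: str | os.PathLike) -> AssociationTable:
    """Read a microbe-disease association TSV.

    Header ``disease<TAB>microbe<TAB>direction``; direction tokens are
    ``increase``/``decrease`` (case-insensitive) or ``+1``/``-1``. Duplicate
    rows are preserved — each row is one curated association record.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty association file") from None
    required = ["disease", "microbe", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; header must be "
                         f"'disease<TAB>microbe<TAB>direction'")
    if df.empty:
        raise ParseError(f"{path}: association file has a header but no records")
    records: list[AssociationRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        token = str(row.direction).strip().lower()
        if token not in _DIRECTION_TOKENS:
            raise ParseError(
                f"{path}: line {idx}: unknown direction token {row.direction!r} "
                f"(expected increase/decrease or +1/-1)"
            )
        try:
            records.append(
                AssociationRecord(
                    disease=str(row.disease),
                    microbe=str(row.microbe),
                    direction=_DIRECTION_TOKENS[token],
                )
            )
        except (ValueError, InvalidNameError) as exc:
            raise ParseError(f"{path}: line {idx}: {exc}") from None
    return AssociationTable(records)


def write_associations(table: AssociationTable, path: str | os.PathLike) -> None:
    """Write an association table as the TSV dialect read by :func:`read_associations`."""
    df = table.to_frame()
    df["direction"] = df["direction"].map({1: "increase", -1: "decrease"})
    df.to_csv(path, sep="\t", index=False)


def read_name_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text microbe list (one name per line) and normalize it.

    Blank lines and ``#`` comments are skipped; duplicates after
    normalization are collapsed, preserving first-seen order.
    """
    out: list[str] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key = normalize_name(line)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def sets_from_associations(table: AssociationTable, min_size: int = 2) -> SetDatabase:
    """Build disease-category microbe sets from association records.

    Each distinct disease yields one set equal to the union of its
    associated microbes across all records, ignoring direction — studies of
    the same disease are pooled because individual studies are too variable
    to define a consensus set. Sets smaller than ``min_size`` (default 2)
    are dropped.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    members: dict[str, set[str]] = {}
    for r in table.records:
        members.setdefault(r.disease, set()).add(r.microbe)
    return SetDatabase(
        MicrobeSet(name=d, category=Category.DISEASE, members=frozenset(ms))
        for d, ms in sorted(members.items())
        if len(ms) >= min_size
    )
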