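"""Packaged query data and seeded synthetic-data generators.

The real curated microbe-set database (47 sets built from 483 literature
associations) lives on a web server and is not redistributable, so every
other module is exercised against synthetic miniatures generated here:

* a set database whose size distribution is heavily skewed toward small
  sets (most annotated disease sets contain only a handful of genus- or
  species-rank microbes), with a handful of large body-position sets;
* a query list "planted" to overlap one target set far above chance, for
  benchmarking enrichment recovery;
* a signed association table with repeated disease-microbe records and an
  optional planted disease pair sharing most of their microbe profile, for
  benchmarking similarity recovery.

All generators are pure functions of (spec, seed): the same spec yields
byte-identical files. Synthetic microbe names are latinate-looking
binomials from a fixed token pool; no real taxonomy is implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .setdb import (
    AssociationRecord,
    AssociationTable,
    Category,
    MicrobeSet,
    SetDatabase,
    normalize_name,
)

__all__ = [
    "FixtureSpec",
    "PlantedPair",
    "table1_query",
    "microbe_name_pool",
    "generate_set_database",
    "generate_planted_query",
    "generate_association_table",
    "default_planted_set",
]


def table1_query() -> list[str]:
    """The packaged animal-based-diet query list, normalized and distinct.

    51 microbes (29 species-rank, 22 genus-rank) reported as significantly
    changed in the human gut after an animal-based diet intervention,
    transcribed from the published table. Order of the source table is
    preserved.
    """
    text = resources.files("micropattern.data").joinpath("animal_diet_query.txt").read_text(
        encoding="utf-8"
    )
    out: list[str] = []
    seen: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key = normalize_name(line)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


# Invented latinate tokens; combinations are synthetic binomials, not taxa.
_GENERA = (
    "brevibacter", "flavimonas", "rugosicoccus", "septovibrio", "lentispira",
    "cavernicola", "aurantimonas", "pallidibacter", "torulispora", "glareococcus",
    "umbrivirga", "nitidispira", "fuscimonas", "arenibacterium", "vitreococcus",
    "limosivibrio", "cretabacter", "ochraceospira", "pluviomonas", "sordidicoccus",
)
_EPITHETS = (
    "intestini", "variabilis", "minutus", "copiosus", "tardus", "velox",
    "obscurus", "lucidus", "palustris", "arenosus", "fervidus", "frigidus",
    "tenuis", "crassus", "sinuosus",
)


def microbe_name_pool(n: int) -> list[str]:
    """First ``n`` names from the deterministic synthetic binomial pool."""
    if n > len(_GENERA) * len(_EPITHETS):
        raise ValueError(
            f"requested pool of {n} exceeds the {len(_GENERA) * len(_EPITHETS)} "
            "available synthetic names"
        )
    return [f"{g} {e}" for e in _EPITHETS for g in _GENERA][:n]


@dataclass(frozen=True)
class PlantedPair:
    """Two diseases built from a largely shared microbe profile."""

    disease_a: str = "disease-planted-a"
    disease_b: str = "disease-planted-b"
    shared_fraction: float = 0.8
    concordant: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic miniature database.

    Defaults miniaturize the curated database (which holds 47 sets over a
    few hundred microbes, and 483 signed records covering 39 diseases and
    292 microbes) to sizes the test suite runs in seconds: 40 sets and 10
    diseases over a 60-microbe pool. ``size_bins`` mirrors the curated
    database's skew, where over three quarters of the sets have at most 5
    members and a few large sets reach into the hundreds.
    """

    seed: int = 0
    n_sets: int = 40
    # ((lo, hi) size bin, probability); weights follow the curated skew.
    size_bins: tuple[tuple[tuple[int, int], float], ...] = (
        ((1, 5), 0.77),
        ((6, 10), 0.11),
        ((11, 15), 0.02),
        ((16, 20), 0.04),
        ((21, 40), 0.06),
    )
    position_set_fraction: float = 0.2
    n_diseases: int = 10
    n_microbes: int = 60
    records_per_disease: tuple[int, int] = (3, 12)
    pair_repeat_rate: float = 0.2
    planted_set: tuple[str, float] | None = None
    query_noise: int = 5
    planted_pair: PlantedPair | None = None
    planted_profile_size: int = 8

    def __post_init__(self) -> None:
        if self.n_sets < 0 or self.n_diseases < 1 or self.n_microbes < 1:
            raise ValueError("counts must be positive")
        total = sum(w for _, w in self.size_bins)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"size_bins weights must sum to 1, got {total}")
        if not 0.0 <= self.pair_repeat_rate <= 1.0:
            raise ValueError("pair_repeat_rate must lie in [0, 1]")
        if self.planted_set is not None and not 0.0 <= self.planted_set[1] <= 1.0:
            raise ValueError("planted overlap fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "size_bins" in raw:
            raw["size_bins"] = tuple(
                ((int(lo), int(hi)), float(w)) for (lo, hi), w in raw["size_bins"]
            )
        if raw.get("planted_pair") is not None:
            raw["planted_pair"] = PlantedPair(**raw["planted_pair"])
        if raw.get("planted_set") is not None:
            name, frac = raw["planted_set"]
            raw["planted_set"] = (str(name), float(frac))
        return cls(**raw)


def generate_set_database(spec: FixtureSpec) -> SetDatabase:
    """Draw ``spec.n_sets`` synthetic microbe sets, deterministically under the seed.

    Set sizes come from the binned size distribution; members are sampled
    without replacement from the synthetic name pool. Roughly
    ``position_set_fraction`` of the sets are body-position sets, the rest
    disease sets.
    """
    if spec.n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    max_size = max(hi for (lo, hi), _ in spec.size_bins)
    if max_size > spec.n_microbes:
        raise ValueError(
            f"largest size bin ({max_size}) exceeds the microbe pool ({spec.n_microbes})"
        )
    rng = np.random.default_rng(spec.seed)
    pool = np.array(microbe_name_pool(spec.n_microbes))
    bins = [b for b, _ in spec.size_bins]
    weights = np.array([w for _, w in spec.size_bins])
    sets: list[MicrobeSet] = []
    n_position = int(round(spec.position_set_fraction * spec.n_sets))
    for i in range(spec.n_sets):
        lo, hi = bins[rng.choice(len(bins), p=weights)]
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(pool, size=size, replace=False)
        if i < spec.n_sets - n_position:
            name, cat = f"disease-{i + 1:02d}", Category.DISEASE
        else:
            name, cat = f"position-{i + 1:02d}", Category.POSITION
        sets.append(MicrobeSet(name=name, category=cat, members=frozenset(members.tolist())))
    return SetDatabase(sets)


def default_planted_set(db: SetDatabase) -> str:
    """Name of the largest set (ties broken lexicographically) — the natural
    target for a planted-enrichment benchmark."""
    return max(db, key=lambda s: (len(s), s.name)).name


def generate_planted_query(db: SetDatabase, spec: FixtureSpec) -> list[str]:
    """A query list overlapping one target set far above chance.

    Takes ``overlap_fraction`` of the planted set's members (rounded) plus ``spec.query_noise`` microbes sampled from the rest
    of the universe, shuffled deterministically under the seed.
    """
    if spec.planted_set is None:
        raise ValueError("spec.planted_set is not configured")
    name, frac = spec.planted_set
    if name not in db:
        raise ValueError(f"unknown planted set {name!r}")
    target = db[name]
    if len(target) < 2:
        raise ValueError(f"planted set {name!r} must have at least 2 members")
    rng = np.random.default_rng(spec.seed + 1)
    members = np.array(sorted(target.members))
    k = int(round(frac * len(members)))
    picked = rng.choice(members, size=k, replace=False).tolist() if k else []
    rest = np.array(sorted(db.universe - target.members))
    n_noise = min(spec.query_noise, len(rest))
    noise = rng.choice(rest, size=n_noise, replace=False).tolist()
    query = picked + noise
    rng.shuffle(query)
    return query


def generate_association_table(spec: FixtureSpec) -> AssociationTable:
    """Random signed association records, with an optional planted disease pair.

    Each disease receives a random profile of distinct microbes (size drawn
    from ``records_per_disease``), each with direction +1 or -1 and a
    chance ``pair_repeat_rate`` of a duplicate record (repeated curation of
    the same pair). If ``planted_pair`` is set, its two diseases share
    ``shared_fraction`` of a profile of ``planted_profile_size`` microbes
    with identical evidence counts and concordant (or flipped) directions;
    the rest of each profile is disease-specific.
    """
    rng = np.random.default_rng(spec.seed + 2)
    pool = np.array(microbe_name_pool(spec.n_microbes))
    lo, hi = spec.records_per_disease
    if not 1 <= lo <= hi <= spec.n_microbes:
        raise ValueError("records_per_disease range infeasible for the microbe pool")
    records: list[AssociationRecord] = []

    def add(disease: str, microbe: str, direction: int, count: int) -> None:
        records.extend(
            AssociationRecord(disease=disease, microbe=microbe, direction=direction)
            for _ in range(count)
        )

    planted_labels: list[str] = []
    if spec.planted_pair is not None:
        if spec.n_diseases < 2:
            raise ValueError("planted_pair requires n_diseases >= 2")
        pp = spec.planted_pair
        planted_labels = [pp.disease_a, pp.disease_b]
        s = min(spec.planted_profile_size, spec.n_microbes)
        n_shared = int(round(pp.shared_fraction * s))
        profile = rng.choice(pool, size=min(2 * s - n_shared, spec.n_microbes), replace=False)
        shared, own = profile[:n_shared], profile[n_shared:]
        own_a, own_b = own[: s - n_shared], own[s - n_shared : 2 * (s - n_shared)]
        for mic in shared:
            direction = int(rng.choice([1, -1]))
            count = 1 + int(rng.random() < spec.pair_repeat_rate)
            add(pp.disease_a, mic, direction, count)
            add(pp.disease_b, direction=direction if pp.concordant else -direction,
                microbe=mic, count=count)
        for label, extras in ((pp.disease_a, own_a), (pp.disease_b, own_b)):
            for mic in extras:
                add(label, mic, int(rng.choice([1, -1])),
                    1 + int(rng.random() < spec.pair_repeat_rate))

    n_random = spec.n_diseases - len(planted_labels)
    for i in range(n_random):
        disease = f"disease-{i + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        for mic in rng.choice(pool, size=size, replace=False):
            add(disease, mic, int(rng.choice([1, -1])),
                1 + int(rng.random() < spec.pair_repeat_rate))
    return AssociationTable(records)
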