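"""Data model and I/O for diploid genotype tables, population registries,
reproductive events and territory distances.

The genotype table holds unordered diploid allele pairs at named loci.
Microsatellite alleles are opaque string labels (fragment sizes are *not*
interpreted); MHC loci additionally carry an allele-to-protein map and a
per-protein functionality flag, because several alleles may translate to one
protein and a protein carrying a premature stop codon is treated as
non-functional by the downstream estimators.

Missing data is always a whole-locus call (no half calls).  The tokens
``NA``, the empty string and ``0`` all denote missing on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "LocusKind",
    "Locus",
    "GenotypeTable",
    "AlleleFrequencies",
    "allele_frequencies",
    "read_genotypes",
    "write_genotypes",
    "write_genepop",
    "read_genepop",
    "Status",
    "Individual",
    "DistanceMatrix",
    "PopulationRegistry",
    "ReproductiveEvent",
    "read_events",
    "write_events",
    "read_registry",
    "write_registry",
    "loci_to_records",
    "loci_from_records",
    "validate_dataset",
]

#: tokens recognised as a missing allele on input (case-insensitive)
MISSING_TOKENS = {"", "na", "nan", "none", "0", "?", "missing"}


class LocusKind(str, Enum):
    MICROSATELLITE = "microsatellite"
    MHC_CLASS_I = "mhc_class_I"
    MHC_CLASS_II = "mhc_class_II"

    @property
    def is_mhc(self) -> bool:
        return self is not LocusKind.MICROSATELLITE


@dataclass(frozen=True)
class Locus:
    """A named locus, optionally with an allele -> protein translation map.

    Parameters
    ----------
    name
        Locus identifier, used as the column header in genotype files.
    kind
        Marker class.  MHC loci must provide ``allele_to_protein``.
    allele_to_protein
        Map from allele label to the protein it translates to (MHC only).
    functional
        Map from protein label to a bool; proteins absent from the map are
        functional.  At most one protein may be flagged non-functional, and
        only at an MHC class II locus (a stop-codon product).
    """

    name: str
    kind: LocusKind = LocusKind.MICROSATELLITE
    allele_to_protein: Mapping[str, str] | None = None
    functional: Mapping[str, bool] | None = None

    def __post_init__(self) -> None:
        if self.kind is LocusKind.MICROSATELLITE:
            if self.allele_to_protein is not None or self.functional is not None:
                raise ValueError(
                    f"microsatellite locus {self.name!r} cannot carry a protein map"
                )
            return
        if self.allele_to_protein is None:
            raise ValueError(f"MHC locus {self.name!r} requires an allele_to_protein map")
        nonfunc = [p for p, ok in (self.functional or {}).items() if not ok]
        if nonfunc and self.kind is not LocusKind.MHC_CLASS_II:
            raise ValueError(
                f"non-functional proteins are only allowed at class II loci, got {nonfunc}"
            )
        if len(nonfunc) > 1:
            raise ValueError(
                f"at most one protein may be non-functional at {self.name!r}, got {nonfunc}"
            )

    def protein(self, allele: str) -> str:
        """Protein label translated by *allele* (MHC loci only)."""
        if self.allele_to_protein is None:
            raise ValueError(f"{self.name!r} is not an MHC locus")
        try:
            return self.allele_to_protein[allele]
        except KeyError:
            raise KeyError(
                f"allele {allele!r} at {self.name!r} has no protein-label entry"
            ) from None

    def is_functional(self, protein: str) -> bool:
        if self.functional is None:
            return True
        return bool(self.functional.get(protein, True))


def _canonical(call) -> tuple[str, str] | None:
    """Canonicalise an allele pair: string labels, sorted, or None."""
    if call is None:
        return None
    a, b = call
    if a is None or b is None:
        return None
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


class GenotypeTable:
    """Per-individual diploid genotypes at an ordered panel of loci.

    Allele pairs are unordered (stored in a canonical sorted order) and a
    missing call is always the whole locus.  Allele labels are opaque
    strings.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[Locus],
        calls: Mapping[str, Mapping[str, tuple | None]],
        *,
        parse_warnings: int = 0,
    ) -> None:
        individuals = [str(i) for i in individuals]
        if len(set(individuals)) != len(individuals):
            dupes = sorted({i for i in individuals if individuals.count(i) > 1})
            raise ValueError(f"duplicate individual id(s): {dupes}")
        self._individuals = tuple(individuals)
        self._loci = tuple(loci)
        self._index = {ind: i for i, ind in enumerate(self._individuals)}
        self._locus_index = {l.name: j for j, l in enumerate(self._loci)}
        if len(self._locus_index) != len(self._loci):
            raise ValueError("duplicate locus names")
        n, m = len(self._individuals), len(self._loci)
        self._calls: list[list[tuple[str, str] | None]] = [
            [None] * m for _ in range(n)
        ]
        for ind, row in calls.items():
            i = self._index[str(ind)]
            for lname, call in row.items():
                self._calls[i][self._locus_index[lname]] = _canonical(call)
        self.parse_warnings = parse_warnings
        self._validate_mhc()

    # -- construction helpers -------------------------------------------------

    def _validate_mhc(self) -> None:
        for j, locus in enumerate(self._loci):
            if not locus.kind.is_mhc:
                continue
            for i in range(len(self._individuals)):
                call = self._calls[i][j]
                if call is None:
                    continue
                for allele in call:
                    locus.protein(allele)  # raises on unmapped allele

    # -- basic access ---------------------------------------------------------

    @property
    def individuals(self) -> tuple[str, ...]:
        return self._individuals

    @property
    def loci(self) -> tuple[Locus, ...]:
        return self._loci

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self._loci)

    def locus(self, name: str) -> Locus:
        return self._loci[self._locus_index[name]]

    def loci_of_kind(self, kind: LocusKind) -> tuple[Locus, ...]:
        return tuple(l for l in self._loci if l.kind is kind)

    @property
    def microsat_loci(self) -> tuple[Locus, ...]:
        return self.loci_of_kind(LocusKind.MICROSATELLITE)

    def __contains__(self, ind: str) -> bool:
        return ind in self._index

    def __len__(self) -> int:
        return len(self._individuals)

    def call(self, ind: str, locus: str) -> tuple[str, str] | None:
        """Unordered allele pair of *ind* at *locus*, or None if missing."""
        return self._calls[self._index[ind]][self._locus_index[locus]]

    def is_missing(self, ind: str, locus: str) -> bool:
        return self.call(ind, locus) is None

    def typed_loci(self, ind: str, kind: LocusKind | None = None) -> list[Locus]:
        row = self._calls[self._index[ind]]
        return [
            l
            for j, l in enumerate(self._loci)
            if row[j] is not None and (kind is None or l.kind is kind)
        ]

    def subset(self, individuals: Iterable[str]) -> "GenotypeTable":
        individuals = [str(i) for i in individuals]
        calls = {
            ind: {l.name: self.call(ind, l.name) for l in self._loci}
            for ind in individuals
        }
        return GenotypeTable(individuals, self._loci, calls)

    def __eq__(self, other) -> bool:  # bit-identical calls, same panel order
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self._individuals == other._individuals
            and self.locus_names == other.locus_names
            and self._calls == other._calls
        )


# -- allele frequencies -------------------------------------------------------


@dataclass
class AlleleFrequencies:
    """Per-locus empirical allele frequencies (non-missing copies only)."""

    freqs: dict[str, dict[str, float]]
    n_copies: dict[str, int]

    def __getitem__(self, locus: str) -> dict[str, float]:
        return self.freqs[locus]

    def loci(self) -> list[str]:
        return list(self.freqs)


def allele_frequencies(
    gt: GenotypeTable,
    subset: Sequence[str] | None = None,
    loci: Sequence[str] | None = None,
) -> AlleleFrequencies:
    """Empirical allele frequencies over non-missing allele copies.

    The reference set defaults to every individual in the table; a subset
    hook is provided because the appropriate reference population is an
    analysis choice.

    Raises
    ------
    ValueError
        If a locus has no non-missing call in the subset.
    """
    inds = list(gt.individuals) if subset is None else [str(i) for i in subset]
    unknown = [i for i in inds if i not in gt]
    if unknown:
        raise ValueError(f"subset ids not in table: {unknown[:5]}")
    names = list(gt.locus_names) if loci is None else list(loci)
    freqs: dict[str, dict[str, float]] = {}
    n_copies: dict[str, int] = {}
    for name in names:
        counts: dict[str, int] = {}
        for ind in inds:
            call = gt.call(ind, name)
            if call is None:
                continue
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {name!r} entirely missing in subset")
        freqs[name] = {a: c / total for a, c in sorted(counts.items())}
        n_copies[name] = total
    return AlleleFrequencies(freqs, n_copies)


# -- CSV genotype I/O ---------------------------------------------------------


def _parse_allele(token: str) -> str | None:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return None
    return token


def read_genotypes(path, loci_spec: Sequence[Locus]) -> GenotypeTable:
    """Read a genotype CSV into a validated :class:`GenotypeTable`.

    Two dialects are auto-detected per locus: two columns ``<locus>_1`` /
    ``<locus>_2``, or a single ``<locus>`` column holding ``a/b``.
    Unparseable or half-missing calls become missing with a counted warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0].lower() not in ("id", "individual", "ind"):
        raise ValueError("first column must be the individual id")
    id_col = df.columns[0]
    claimed = {id_col}
    layout: dict[str, tuple[str, ...]] = {}
    for locus in loci_spec:
        two = (f"{locus.name}_1", f"{locus.name}_2")
        if all(c in df.columns for c in two):
            layout[locus.name] = two
            claimed.update(two)
        elif locus.name in df.columns:
            layout[locus.name] = (locus.name,)
            claimed.add(locus.name)
        else:
            raise ValueError(f"locus {locus.name!r} not found in headers")
    unknown = [c for c in df.columns if c not in claimed]
    if unknown:
        raise ValueError(f"unknown locus header(s): {unknown}")

    warnings = 0
    calls: dict[str, dict[str, tuple | None]] = {}
    for _, row in df.iterrows():
        ind = str(row[id_col]).strip()
        if ind in calls:
            raise ValueError(f"duplicate individual id: {ind!r}")
        rec: dict[str, tuple | None] = {}
        for lname, cols in layout.items():
            if len(cols) == 2:
                a, b = _parse_allele(row[cols[0]]), _parse_allele(row[cols[1]])
            else:
                cell = row[cols[0]].strip()
                parts = cell.split("/")
                if len(parts) != 2:
                    if _parse_allele(cell) is not None:
                        warnings += 1  # unparseable cell
                    a = b = None
                else:
                    a, b = _parse_allele(parts[0]), _parse_allele(parts[1])
            if (a is None) != (b is None):
                warnings += 1  # half call -> whole-locus missing
                a = b = None
            rec[lname] = None if a is None else (a, b)
        calls[ind] = rec
    if warnings:
        log.warning("read_genotypes: %d call(s) coerced to missing", warnings)
    return GenotypeTable(list(calls), loci_spec, calls, parse_warnings=warnings)


def write_genotypes(gt: GenotypeTable, path) -> None:
    """Write a genotype CSV in the single-column ``a/b`` dialect."""
    rows = []
    for ind in gt.individuals:
        rec: dict[str, str] = {"id": ind}
        for name in gt.locus_names:
            call = gt.call(ind, name)
            rec[name] = "NA" if call is None else f"{call[0]}/{call[1]}"
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


# -- Genepop export -----------------------------------------------------------


def _allele_sort_key(label: str):
    return (0, int(label), label) if label.isdigit() else (1, 0, label)


def write_genepop(gt: GenotypeTable, path, title: str = "matechoice export") -> dict:
    """Write microsatellite genotypes as a Genepop 4 file (one POP block).

    Alleles are mapped to stable 3-digit codes (sorted label order); the
    mapping is emitted alongside as ``<path>.allele_codes.csv`` and returned.
    Missing calls are written as ``000000`` per Genepop convention.
    """
    path = Path(path)
    loci = gt.microsat_loci
    codes: dict[str, dict[str, str]] = {}
    for locus in loci:
        alleles: set[str] = set()
        for ind in gt.individuals:
            call = gt.call(ind, locus.name)
            if call is not None:
                alleles.update(call)
        if len(alleles) > 999:
            raise ValueError(f">999 distinct alleles at {locus.name!r}")
        codes[locus.name] = {
            a: f"{i + 1:03d}"
            for i, a in enumerate(sorted(alleles, key=_allele_sort_key))
        }
    lines = [title]
    lines.extend(l.name for l in loci)
    lines.append("POP")
    for ind in gt.individuals:
        fields = []
        for locus in loci:
            call = gt.call(ind, locus.name)
            if call is None:
                fields.append("000000")
            else:
                c = codes[locus.name]
                fields.append(c[call[0]] + c[call[1]])
        lines.append(f"{ind} ,  " + " ".join(fields))
    path.write_text("\n".join(lines) + "\n")
    mapping = pd.DataFrame(
        [
            {"locus": lname, "allele": a, "code": code}
            for lname, amap in codes.items()
            for a, code in amap.items()
        ]
    )
    mapping.to_csv(path.with_name(path.name + ".allele_codes.csv"), index=False)
    return codes


def read_genepop(path, allele_codes: Mapping[str, Mapping[str, str]] | None = None) -> GenotypeTable:
    """Parse a Genepop 4 file (single or multiple POP blocks).

    If *allele_codes* (as returned by :func:`write_genepop`) is given, codes
    are decoded back to allele labels; otherwise the 3-digit codes themselves
    are the labels.
    """
    lines = [l.rstrip("\n") for l in Path(path).read_text().splitlines()]
    if not lines:
        raise ValueError("empty genepop file")
    body = lines[1:]
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        # locus names may be one per line or comma-separated
        locus_names.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    decode: dict[str, dict[str, str]] = {}
    for lname in locus_names:
        if allele_codes and lname in allele_codes:
            decode[lname] = {code: a for a, code in allele_codes[lname].items()}
        else:
            decode[lname] = {}
    loci = [Locus(n) for n in locus_names]
    inds: list[str] = []
    calls: dict[str, dict[str, tuple | None]] = {}
    for line in body[i:]:
        if line.strip().upper() == "POP" or not line.strip():
            continue
        if "," not in line:
            raise ValueError(f"malformed genepop line: {line!r}")
        ind, rest = line.split(",", 1)
        ind = ind.strip()
        fields = rest.split()
        if len(fields) != len(locus_names):
            raise ValueError(f"wrong number of genotype fields for {ind!r}")
        rec: dict[str, tuple | None] = {}
        for lname, f in zip(locus_names, fields):
            if len(f) not in (4, 6):
                raise ValueError(f"bad genotype field {f!r}")
            half = len(f) // 2
            c1, c2 = f[:half], f[half:]
            if int(c1) == 0 or int(c2) == 0:
                rec[lname] = None
            else:
                d = decode[lname]
                rec[lname] = (d.get(c1, c1), d.get(c2, c2))
        inds.append(ind)
        calls[ind] = rec
    return GenotypeTable(inds, loci, calls)


# -- population registry ------------------------------------------------------


class Status(str, Enum):
    DOMINANT = "dominant"
    SUBORDINATE = "subordinate"
    PUP = "pup"
    ABSENT = "absent"


@dataclass
class Individual:
    id: str
    sex: str  # 'F' or 'M'
    birth_year: int
    territory_by_year: dict[int, str] = field(default_factory=dict)
    status_by_year: dict[int, Status] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


class DistanceMatrix:
    """Symmetric pairwise territory distances (zero diagonal)."""

    def __init__(self, territories: Sequence[str], matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        n = len(territories)
        if matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(matrix), 0.0):
            raise ValueError("distance matrix must be zero on the diagonal")
        if (matrix < 0).any():
            raise ValueError("distances must be non-negative")
        self.territories = tuple(str(t) for t in territories)
        self._index = {t: i for i, t in enumerate(self.territories)}
        self.matrix = matrix

    @classmethod
    def from_coordinates(cls, coords: Mapping[str, tuple[float, float]]) -> "DistanceMatrix":
        terrs = list(coords)
        xy = np.array([coords[t] for t in terrs], dtype=float)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
        return cls(terrs, d)

    @classmethod
    def from_pairs(cls, df: pd.DataFrame) -> "DistanceMatrix":
        terrs = sorted(set(df.iloc[:, 0].astype(str)) | set(df.iloc[:, 1].astype(str)))
        idx = {t: i for i, t in enumerate(terrs)}
        m = np.zeros((len(terrs), len(terrs)))
        for _, row in df.iterrows():
            i, j = idx[str(row.iloc[0])], idx[str(row.iloc[1])]
            m[i, j] = m[j, i] = float(row.iloc[2])
        return cls(terrs, m)

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])


class PopulationRegistry:
    """Individuals with sex, birth year and yearly territory/status, plus
    pairwise territory distances.

    A year in which an individual has no recorded status is treated as
    :attr:`Status.ABSENT`.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        distances: DistanceMatrix,
    ) -> None:
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            for year, status in ind.status_by_year.items():
                if status is not Status.ABSENT and year < ind.birth_year:
                    raise ValueError(
                        f"{ind.id!r} has status {status.value} in {year} before birth"
                    )
            self.individuals[ind.id] = ind
        self.distances = distances

    def __contains__(self, ind: str) -> bool:
        return ind in self.individuals

    def sex(self, ind: str) -> str:
        return self.individuals[ind].sex

    def age(self, ind: str, year: int) -> int:
        return year - self.individuals[ind].birth_year

    def status(self, ind: str, year: int) -> Status:
        return self.individuals[ind].status_by_year.get(year, Status.ABSENT)

    def territory(self, ind: str, year: int) -> str | None:
        return self.individuals[ind].territory_by_year.get(year)

    def present(self, ind: str, year: int) -> bool:
        return self.status(ind, year) is not Status.ABSENT

    def males_present(self, year: int, min_age: int = 0) -> list[str]:
        return [
            i
            for i, rec in self.individuals.items()
            if rec.sex == "M" and self.present(i, year) and self.age(i, year) >= min_age
        ]

    def distance(self, territory_a: str, territory_b: str) -> float:
        return self.distances.distance(territory_a, territory_b)


@dataclass(frozen=True)
class ReproductiveEvent:
    """One female-year: the social male, the litter and the family context."""

    female: str
    year: int
    social_male: str
    pups: tuple[str, ...]
    n_mature_sub_males: int = 0
    territory: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.pups) <= 7:
            raise ValueError(
                f"litter size must be in 1..7, got {len(self.pups)} "
                f"({self.female} {self.year})"
            )
        if self.n_mature_sub_males < 0:
            raise ValueError("n_mature_sub_males must be >= 0")

    @property
    def litter_size(self) -> int:
        return len(self.pups)

    @property
    def litter_id(self) -> str:
        return f"{self.female}:{self.year}"


# -- registry / event CSV plumbing -------------------------------------------


def write_registry(registry: PopulationRegistry, ind_path, status_path, dist_path) -> None:
    ind_rows = [
        {"id": i, "sex": r.sex, "birth_year": r.birth_year}
        for i, r in registry.individuals.items()
    ]
    pd.DataFrame(ind_rows).to_csv(ind_path, index=False)
    status_rows = [
        {
            "id": i,
            "year": year,
            "territory": r.territory_by_year.get(year, ""),
            "status": r.status_by_year[year].value,
        }
        for i, r in registry.individuals.items()
        for year in sorted(r.status_by_year)
    ]
    pd.DataFrame(status_rows).to_csv(status_path, index=False)
    d = registry.distances
    dist_rows = [
        {"territory_a": a, "territory_b": b, "distance": d.distance(a, b)}
        for i, a in enumerate(d.territories)
        for b in d.territories[i + 1 :]
    ]
    pd.DataFrame(dist_rows).to_csv(dist_path, index=False)


def read_registry(ind_path, status_path, dist_path=None, coords_path=None) -> PopulationRegistry:
    """Build a registry from CSVs.

    Distances are accepted either as an explicit pair table (*dist_path*) or
    as territory coordinates (*coords_path*, Euclidean distances computed);
    the explicit matrix wins if both are given.
    """
    ind_df = pd.read_csv(ind_path, dtype={"id": str})
    status_df = pd.read_csv(status_path, dtype={"id": str, "territory": str})
    inds: dict[str, Individual] = {}
    for _, row in ind_df.iterrows():
        inds[row["id"]] = Individual(row["id"], row["sex"], int(row["birth_year"]))
    for _, row in status_df.iterrows():
        rec = inds[row["id"]]
        year = int(row["year"])
        rec.status_by_year[year] = Status(row["status"])
        terr = row.get("territory")
        if isinstance(terr, str) and terr:
            rec.territory_by_year[year] = terr
    if dist_path is not None:
        distances = DistanceMatrix.from_pairs(pd.read_csv(dist_path, dtype={0: str, 1: str}))
    elif coords_path is not None:
        cdf = pd.read_csv(coords_path, dtype={"territory": str})
        distances = DistanceMatrix.from_coordinates(
            {row["territory"]: (row["x"], row["y"]) for _, row in cdf.iterrows()}
        )
    else:
        raise ValueError("either dist_path or coords_path is required")
    return PopulationRegistry(inds.values(), distances)


def write_events(events: Sequence[ReproductiveEvent], path) -> None:
    rows = [
        {
            "female": e.female,
            "year": e.year,
            "social_male": e.social_male,
            "pups": ";".join(e.pups),
            "n_mature_sub_males": e.n_mature_sub_males,
            "territory": e.territory or "",
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events(path) -> list[ReproductiveEvent]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    events = []
    for _, row in df.iterrows():
        events.append(
            ReproductiveEvent(
                female=row["female"],
                year=int(row["year"]),
                social_male=row["social_male"],
                pups=tuple(p for p in row["pups"].split(";") if p),
                n_mature_sub_males=int(row["n_mature_sub_males"]),
                territory=row.get("territory") or None,
            )
        )
    return events


def loci_to_records(loci: Sequence[Locus]) -> list[dict]:
    """Serialize a locus panel to plain records (for YAML/JSON round trip)."""
    records = []
    for l in loci:
        rec: dict = {"name": l.name, "kind": l.kind.value}
        if l.allele_to_protein is not None:
            rec["allele_to_protein"] = dict(l.allele_to_protein)
        if l.functional is not None:
            rec["functional"] = dict(l.functional)
        records.append(rec)
    return records


def loci_from_records(records: Sequence[Mapping]) -> list[Locus]:
    return [
        Locus(
            name=r["name"],
            kind=LocusKind(r.get("kind", "microsatellite")),
            allele_to_protein=r.get("allele_to_protein"),
            functional=r.get("functional"),
        )
        for r in records
    ]


def validate_dataset(
    gt: GenotypeTable,
    registry: PopulationRegistry,
    events: Sequence[ReproductiveEvent],
) -> list[str]:
    """Cross-table consistency report (returns a list of problems)."""
    problems: list[str] = []
    for e in events:
        for who, role in [(e.female, "female"), (e.social_male, "social male")]:
            if who not in registry:
                problems.append(f"{e.litter_id}: {role} {who!r} not in registry")
            elif registry.status(who, e.year) is not Status.DOMINANT:
                problems.append(
                    f"{e.litter_id}: {role} {who!r} not dominant in {e.year}"
                )
        if (
            e.female in registry
            and e.social_male in registry
            and registry.territory(e.female, e.year)
            != registry.territory(e.social_male, e.year)
        ):
            problems.append(f"{e.litter_id}: pair not in the same territory")
        for p in e.pups:
            if p not in gt:
                problems.append(f"{e.litter_id}: pup {p!r} not genotyped")
    for ind in registry.individuals.values():
        for year, status in ind.status_by_year.items():
            if status is not Status.ABSENT and year - ind.birth_year < 0:
                problems.append(f"{ind.id}: negative age in {year}")
    return problems
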