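"""Exclusion-based maternity/paternity analysis and extra-pair young (EPY)
classification, plus a pedigree-relatedness oracle.

A pup is a within-pair young (WPY) when its genotype shows no mismatch with
the dominant (social) male given the known mother, and an extra-pair young
(EPY) when at least one locus is incompatible.  A "mismatch" with the mother
known is decided by full transmission-pattern enumeration at each locus: the
pup's allele pair must be decomposable into one maternal and one paternal
allele.  Candidate fathers for EPY are screened by the same rule; ties among
microsatellite-compatible candidates are broken on MHC-locus consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .genotype_io import GenotypeTable, Locus, ReproductiveEvent

__all__ = [
    "UNKNOWN",
    "ParentageCall",
    "count_mismatches",
    "classify_litter",
    "assign_father",
    "Pedigree",
    "EppSummary",
    "epp_summary",
    "round_half_up",
]

UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ParentageCall:
    pup: str
    litter: str
    maternity_mismatches: int | None
    paternity_mismatches_social: int | None
    classification: str  # 'WPY' | 'EPY' | 'unresolved'
    assigned_father: str | None = None
    assignment_basis: str | None = None  # 'exclusion_unique'|'mhc_consistency'|'unresolved'


def _duo_compatible(off: tuple[str, str], cand: tuple[str, str]) -> bool:
    return off[0] in cand or off[1] in cand


def _trio_compatible(
    off: tuple[str, str], mother: tuple[str, str], father: tuple[str, str]
) -> bool:
    x, y = off
    return (x in mother and y in father) or (y in mother and x in father)


def count_mismatches(
    offspring: str,
    candidate_parent: str,
    gt: GenotypeTable,
    known_other_parent: str | None = None,
    loci: Sequence[Locus] | None = None,
) -> int:
    """Number of loci at which *candidate_parent* is excluded.

    Without a known other parent, a locus mismatches when the offspring
    shares no allele with the candidate.  With the other parent known, a
    locus mismatches when no assignment of the offspring's two alleles to
    (maternal, paternal) gametes is consistent with both parental genotypes.
    Loci missing in the known parent fall back to the two-way rule.
    """
    if loci is None:
        loci = gt.microsat_loci
    n_shared = 0
    mismatches = 0
    for locus in loci:
        off = gt.call(offspring, locus.name)
        cand = gt.call(candidate_parent, locus.name)
        if off is None or cand is None:
            continue
        n_shared += 1
        other = (
            gt.call(known_other_parent, locus.name)
            if known_other_parent is not None
            else None
        )
        if other is None:
            ok = _duo_compatible(off, cand)
        else:
            ok = _trio_compatible(off, other, cand)
        mismatches += not ok
    if n_shared == 0:
        raise ValueError(
            f"no shared typed locus between {offspring!r} and {candidate_parent!r}"
        )
    return mismatches


def classify_litter(
    event: ReproductiveEvent,
    gt: GenotypeTable,
    max_paternal_mismatch: int = 0,
) -> list[ParentageCall]:
    """Classify every pup of a litter as WPY or EPY against the social male.

    Maternity is checked first (zero mismatches expected with the dominant
    female); paternity mismatches are then counted with the mother known.
    A pup with a single paternal mismatch is classified EPY under the default
    threshold: with a low genotyping error rate and a low microsatellite
    mutation rate a true within-pair pup essentially never shows even one
    incompatibility.  Untyped pups are returned as 'unresolved', never
    silently dropped.
    """
    calls: list[ParentageCall] = []
    for pup in event.pups:
        try:
            mat = count_mismatches(pup, event.female, gt)
            pat = count_mismatches(pup, event.social_male, gt, known_other_parent=event.female)
        except (ValueError, KeyError):
            calls.append(
                ParentageCall(pup, event.litter_id, None, None, "unresolved",
                              assignment_basis="unresolved")
            )
            continue
        cls = "WPY" if pat <= max_paternal_mismatch else "EPY"
        calls.append(ParentageCall(pup, event.litter_id, mat, pat, cls))
    return calls


def assign_father(
    pup: str,
    mother: str,
    candidates: Sequence[str],
    gt: GenotypeTable,
) -> tuple[str, str]:
    """Assign an extra-pair father among *candidates* by genetic exclusion.

    Candidates with zero microsatellite mismatches (mother known) are
    retained.  A unique survivor is assigned (``exclusion_unique``); among
    several survivors MHC-locus consistency is used as a tie-break
    (``mhc_consistency``); an unresolved tie or an empty survivor set yields
    ``UNKNOWN``.
    """
    compatible = []
    for cand in candidates:
        try:
            m = count_mismatches(pup, cand, gt, known_other_parent=mother)
        except ValueError:
            continue
        if m == 0:
            compatible.append(cand)
    if not compatible:
        return UNKNOWN, "unresolved"
    if len(compatible) == 1:
        return compatible[0], "exclusion_unique"
    mhc_loci = [l for l in gt.loci if l.kind.is_mhc]
    if mhc_loci:
        still = []
        for cand in compatible:
            try:
                m = count_mismatches(pup, cand, gt, known_other_parent=mother, loci=mhc_loci)
            except ValueError:
                still.append(cand)  # no MHC information: cannot exclude
                continue
            if m == 0:
                still.append(cand)
        if len(still) == 1:
            return still[0], "mhc_consistency"
    return UNKNOWN, "unresolved"


# -- pedigree oracle -----------------------------------------------------------


class Pedigree:
    """Parent links per individual; founders are unrelated and non-inbred.

    Relatedness between two individuals is twice their kinship coefficient,
    computed by the standard recursive algorithm.
    """

    def __init__(self, parents: Mapping[str, tuple[str | None, str | None]]) -> None:
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        for ind, (mo, fa) in parents.items():
            self.parents[str(ind)] = (
                None if mo in (None, "", UNKNOWN) else str(mo),
                None if fa in (None, "", UNKNOWN) else str(fa),
            )
        self._depth: dict[str, int] = {}
        self._kin: dict[tuple[str, str], float] = {}
        for ind in self.parents:
            self._compute_depth(ind)

    def _compute_depth(self, ind: str) -> int:
        """Generation depth (founders 0); detects cycles."""
        ind = str(ind)
        if ind in self._depth:
            if self._depth[ind] == -1:
                raise ValueError(f"pedigree cycle detected at {ind!r}")
            return self._depth[ind]
        if ind not in self.parents or self.parents[ind] == (None, None):
            self._depth[ind] = 0
            return 0
        self._depth[ind] = -1  # in progress
        d = 1 + max(
            self._compute_depth(p) for p in self.parents[ind] if p is not None
        )
        self._depth[ind] = d
        return d

    def depth(self, ind: str) -> int:
        return self._depth.get(str(ind), 0)

    def _parents_of(self, ind: str) -> tuple[str | None, str | None]:
        return self.parents.get(str(ind), (None, None))

    def kinship(self, a: str, b: str) -> float:
        a, b = str(a), str(b)
        key = (a, b) if a <= b else (b, a)
        if key in self._kin:
            return self._kin[key]
        if a == b:
            mo, fa = self._parents_of(a)
            f = 0.0 if mo is None or fa is None else self.kinship(mo, fa)
            val = 0.5 * (1 + f)
        else:
            # recurse on the individual further from the founders: it cannot
            # be an ancestor of the other
            if self.depth(a) < self.depth(b):
                a, b = b, a
            mo, fa = self._parents_of(a)
            if mo is None and fa is None:
                val = 0.0
            else:
                val = 0.5 * sum(
                    self.kinship(p, b) for p in (mo, fa) if p is not None
                )
        self._kin[key] = val
        return val

    def relatedness(self, a: str, b: str) -> float:
        """Pedigree relatedness = 2 x kinship coefficient."""
        return 2.0 * self.kinship(a, b)


def pedigree_relatedness(x: str, y: str, ped: Pedigree) -> float:
    return ped.relatedness(x, y)


# -- EPP summary ---------------------------------------------------------------


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal round-half-up (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EppSummary:
    n_pups: int
    n_epy: int
    pct_epy: float
    n_litters: int
    n_litters_with_epy: int
    pct_litters_with_epy: float
    epy_count_distribution: dict[int, int]
    n_full_epm_litters: int
    n_mixed_litters: int
    mean_epy_proportion_mixed: float | None
    n_unresolved: int
    epm_origin_counts: dict[str, int]
    epm_origin_pct: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_pups": self.n_pups,
            "n_epy": self.n_epy,
            "pct_epy": self.pct_epy,
            "n_litters": self.n_litters,
            "n_litters_with_epy": self.n_litters_with_epy,
            "pct_litters_with_epy": self.pct_litters_with_epy,
            "epy_count_distribution": dict(self.epy_count_distribution),
            "n_full_epm_litters": self.n_full_epm_litters,
            "n_mixed_litters": self.n_mixed_litters,
            "mean_epy_proportion_mixed": self.mean_epy_proportion_mixed,
            "n_unresolved": self.n_unresolved,
            "epm_origin_counts": dict(self.epm_origin_counts),
            "epm_origin_pct": dict(self.epm_origin_pct),
        }


def epp_summary(
    calls: Iterable[ParentageCall],
    epm_origin: Mapping[str, str] | None = None,
) -> EppSummary:
    """Population-level extra-pair paternity arithmetic.

    Percentages are the defining ratios rounded half-up to two decimals.
    *epm_origin* optionally maps a litter id to the origin class of its
    extra-pair male (e.g. ``family_subordinate``, ``within_study_disperser``,
    ``unknown``); the breakdown is reported over litters containing EPY.
    """
    by_litter: dict[str, list[ParentageCall]] = {}
    for c in calls:
        by_litter.setdefault(c.litter, []).append(c)
    n_pups = n_epy = n_unresolved = 0
    epy_dist: dict[int, int] = {}
    n_full = n_mixed = 0
    mixed_props: list[float] = []
    litters_with_epy: list[str] = []
    for litter, lcalls in by_litter.items():
        n_unresolved += sum(1 for c in lcalls if c.classification == "unresolved")
        resolved = [c for c in lcalls if c.classification in ("WPY", "EPY")]
        n_pups += len(resolved)
        k = sum(1 for c in resolved if c.classification == "EPY")
        n_epy += k
        if k > 0:
            litters_with_epy.append(litter)
            epy_dist[k] = epy_dist.get(k, 0) + 1
            if k == len(resolved):
                n_full += 1
            else:
                n_mixed += 1
                mixed_props.append(k / len(resolved))
    n_litters = len(by_litter)
    n_with = len(litters_with_epy)
    origin_counts: dict[str, int] = {}
    if epm_origin is not None:
        for litter in litters_with_epy:
            cls = epm_origin.get(litter, "unknown")
            origin_counts[cls] = origin_counts.get(cls, 0) + 1
    origin_pct = {
        cls: round_half_up(100.0 * n / n_with) for cls, n in origin_counts.items()
    }
    return EppSummary(
        n_pups=n_pups,
        n_epy=n_epy,
        pct_epy=round_half_up(100.0 * n_epy / n_pups) if n_pups else 0.0,
        n_litters=n_litters,
        n_litters_with_epy=n_with,
        pct_litters_with_epy=(
            round_half_up(100.0 * n_with / n_litters) if n_litters else 0.0
        ),
        epy_count_distribution=dict(sorted(epy_dist.items())),
        n_full_epm_litters=n_full,
        n_mixed_litters=n_mixed,
        mean_epy_proportion_mixed=(
            sum(mixed_props) / len(mixed_props) if mixed_props else None
        ),
        n_unresolved=n_unresolved,
        epm_origin_counts=origin_counts,
        epm_origin_pct=origin_pct,
    )
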