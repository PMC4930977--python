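"""Forward simulator of a territorial, socially monogamous population with
extra-pair paternity (EPP).

The simulated species lives in family groups on a grid of territories, each
group held by a dominant pair with subordinates of both sexes and pups.
Only the dominant female breeds (a litter of 1-7 pups per year); the
dominant male sires the litter unless an extra-pair male (EPM) intervenes.
The probability that a litter contains extra-pair young (EPY) follows a
logistic model in the number of sexually mature subordinate males, the
pair's neutral relatedness (linear + quadratic) and their MHC class II
protein dissimilarity.  The EPM is a mature subordinate of the family, a
mature male from another studied territory, or an un-sampled male from
outside the study area (whose genotype is withheld from the observed
genotype table, as it would be in the field).

Genotypes follow Mendelian inheritance at 16 microsatellite loci and two
MHC loci (class I: 3 alleles / 2 proteins; class II: 8 alleles / 7 proteins,
one of which is a non-functional stop-codon product), with a per-gamete
mutation rate and a per-call genotyping error applied when the observed
table is emitted.  Dominance vacancies are filled by mature candidates
weighted by an exponential dispersal-distance kernel; a mate-choice mode can
additionally bias male recruitment toward MHC class II dissimilar or
intermediately related partners, which is the signal the randomization test
is meant to detect.

All randomness flows from one seeded generator, so every output (including
exported fixture files) is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genotype_io import (
    DistanceMatrix,
    GenotypeTable,
    Individual,
    Locus,
    LocusKind,
    PopulationRegistry,
    ReproductiveEvent,
    Status,
    write_events,
    write_genepop,
    write_genotypes,
    write_registry,
)
from .parentage import Pedigree

__all__ = [
    "MhcSpec",
    "default_class_I",
    "default_class_II",
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate",
    "paper_scale_config",
    "null_config",
    "emulate_paper_scale",
    "export_fixtures",
    "simulate_relative_pairs",
    "simulate_pedigree_panel",
]


# -- marker specifications -----------------------------------------------------


@dataclass(frozen=True)
class MhcSpec:
    """An MHC locus: allele labels, allele->protein map, frequencies."""

    name: str
    kind: LocusKind
    alleles: tuple[str, ...]
    proteins: tuple[str, ...]  # protein label per allele, parallel to `alleles`
    frequencies: tuple[float, ...]
    nonfunctional_protein: str | None = None

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.frequencies), 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.name}: allele frequencies must sum to 1")
        if len(self.alleles) != len(self.proteins) or len(self.alleles) != len(self.frequencies):
            raise ValueError(f"{self.name}: allele/protein/frequency length mismatch")

    def to_locus(self) -> Locus:
        functional = None
        if self.nonfunctional_protein is not None:
            functional = {self.nonfunctional_protein: False}
        return Locus(
            self.name,
            self.kind,
            allele_to_protein=dict(zip(self.alleles, self.proteins)),
            functional=functional,
        )


def default_class_I() -> MhcSpec:
    """Class I locus: three alleles translating to two proteins."""
    return MhcSpec(
        name="UD",
        kind=LocusKind.MHC_CLASS_I,
        alleles=("UD*01", "UD*02", "UD*03"),
        proteins=("UDp1", "UDp2", "UDp1"),
        frequencies=(0.65, 0.08, 0.27),
    )


def default_class_II() -> MhcSpec:
    """Class II locus: eight alleles, seven proteins, one non-functional.

    Two alleles translate to the same protein, and the protein of the eighth
    allele carries a stop codon (non-functional).  The default frequencies
    put six of the seven proteins inside the 5-95% carrier band used by the
    presence/absence features.
    """
    return MhcSpec(
        name="DRB1",
        kind=LocusKind.MHC_CLASS_II,
        alleles=tuple(f"DRB1*0{i}" for i in range(1, 9)),
        proteins=("DRBp1", "DRBp2", "DRBp3", "DRBp4", "DRBp4",
                  "DRBp6", "DRBp7", "DRBp8"),
        frequencies=(0.34, 0.22, 0.19, 0.01, 0.01, 0.11, 0.08, 0.04),
        nonfunctional_protein="DRBp8",
    )


# -- configuration -------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for one simulated population.

    Defaults emulate the field system the package analyses: ~1-7 pups per
    litter (mean near 3.6), a modest stock of mature subordinate males
    (mean below 1 per family), microsatellite mutation rate 1.67e-4 per
    gamete per locus, genotyping error 3e-4 per single-locus call, and EPP
    whose log-odds follow the subordinate count, pair relatedness (with a
    quadratic term producing a minimum at intermediate relatedness) and MHC
    class II dissimilarity.
    """

    seed: int | None = None
    n_territories: int = 24
    years: int = 10
    start_year: int = 2000

    n_microsat_loci: int = 16
    n_alleles: int = 8
    microsat_frequencies: tuple[float, ...] | None = None  # default equifrequent
    mhc_class_I: MhcSpec = field(default_factory=default_class_I)
    mhc_class_II: MhcSpec = field(default_factory=default_class_II)

    mutation_rate: float = 1.67e-4
    genotyping_error: float = 3e-4
    missing_rate: float = 0.0
    # emulate the field workflow in which every mismatch-implicated pup and
    # its putative parents are re-typed and their genotypes confirmed: a
    # typing error that fakes a parent-offspring incompatibility is corrected
    # on the second read, while a real mutation persists
    retype_mismatches: bool = True

    litter_size_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.08, 2: 0.17, 3: 0.24, 4: 0.24, 5: 0.15, 6: 0.08, 7: 0.04}
    )
    breeding_prob: float = 0.75
    initial_sub_males: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.45, 1: 0.25, 2: 0.15, 3: 0.10, 4: 0.05}
    )

    # logistic model of EPY presence per litter
    epp_intercept: float = -2.0
    epp_beta_sub: float = 0.47
    epp_beta_r: float = -1.73
    epp_beta_r2: float = 8.40
    epp_beta_dissim: float = -0.86
    epy_count_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.30, 3: 0.20, 5: 0.05}
    )
    epm_origin_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "family_subordinate": 0.45,
            "within_study_disperser": 0.15,
            "outside_male": 0.40,
        }
    )

    dispersal_rate: float = 0.5  # exponential kernel, per territory-grid unit
    # random: pairing through coupled demography (vacancy succession);
    # independent: each event's social male is a fresh kernel-weighted draw
    #   from all eligible males (the exact null of the mate-choice test);
    # mhcII_dissimilar / intermediate_Rqg: recruitment biased by preference
    mate_choice_mode: str = "random"
    preference_strength: float = 1.5
    intermediate_r_target: float = 0.15
    annual_repairing: bool = False

    adult_mortality: float = 0.12
    sub_mortality: float = 0.15
    sub_emigration: float = 0.25
    pup_survival: float = 0.60
    maturity_age: int = 2

    def __post_init__(self) -> None:
        for dist in (self.litter_size_probs, self.initial_sub_males,
                     self.epy_count_probs, self.epm_origin_probs):
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"probabilities must sum to 1, got {total}")
        if not all(1 <= k <= 7 for k in self.litter_size_probs):
            raise ValueError("litter sizes must be in 1..7")
        for p in (self.mutation_rate, self.genotyping_error, self.missing_rate,
                  self.breeding_prob, self.adult_mortality, self.sub_mortality,
                  self.sub_emigration, self.pup_survival):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities")
        if self.mate_choice_mode not in (
            "random", "independent", "mhcII_dissimilar", "intermediate_Rqg"
        ):
            raise ValueError(f"unknown mate_choice_mode {self.mate_choice_mode!r}")


@dataclass
class SimTruth:
    """Ground truth: pedigree, WPY/EPY labels, extra-pair sires and origins."""

    pedigree: Pedigree
    labels: dict[str, str]  # pup -> 'WPY' | 'EPY'
    sire: dict[str, str]  # pup -> true father id
    epm_origin: dict[str, str]  # litter id -> origin class
    n_mutations: int = 0
    n_genotyping_errors: int = 0
    outside_males: set[str] = field(default_factory=set)


@dataclass
class SimDataset:
    genotypes: GenotypeTable
    registry: PopulationRegistry
    events: list[ReproductiveEvent]
    truth: SimTruth
    config: SimConfig
    true_genotypes: GenotypeTable | None = None


# -- internal helpers ----------------------------------------------------------


class _Ind:
    __slots__ = ("id", "sex", "birth_year", "mother", "father", "genome",
                 "territory", "status", "alive", "record_t", "record_s")

    def __init__(self, id, sex, birth_year, mother, father, genome, territory, status):
        self.id = id
        self.sex = sex
        self.birth_year = birth_year
        self.mother = mother
        self.father = father
        self.genome = genome  # int array (n_loci, 2)
        self.territory = territory
        self.status = status
        self.alive = True
        self.record_t: dict[int, str] = {}
        self.record_s: dict[int, Status] = {}


def _draw(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


class _Sim:
    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        # locus metadata: microsats first, then MHC I, MHC II
        if config.microsat_frequencies is None:
            mfreq = np.full(config.n_alleles, 1.0 / config.n_alleles)
        else:
            mfreq = np.asarray(config.microsat_frequencies, dtype=float)
            if not math.isclose(mfreq.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("microsat frequencies must sum to 1")
        self.freqs: list[np.ndarray] = [mfreq] * config.n_microsat_loci
        self.freqs.append(np.asarray(config.mhc_class_I.frequencies))
        self.freqs.append(np.asarray(config.mhc_class_II.frequencies))
        self.n_loci = len(self.freqs)
        self.micro_idx = np.arange(config.n_microsat_loci)
        self.i_mhc1 = config.n_microsat_loci
        self.i_mhc2 = config.n_microsat_loci + 1
        c2 = config.mhc_class_II
        # functional protein code per class II allele; -1 = non-functional
        prot_codes: dict[str, int] = {}
        self.mhc2_prot_code = np.empty(len(c2.alleles), dtype=int)
        for i, p in enumerate(c2.proteins):
            if p == c2.nonfunctional_protein:
                self.mhc2_prot_code[i] = -1
            else:
                self.mhc2_prot_code[i] = prot_codes.setdefault(p, len(prot_codes))
        # territory grid
        w = int(math.ceil(math.sqrt(config.n_territories)))
        self.territories = [f"T{i + 1:02d}" for i in range(config.n_territories)]
        self.coords = {
            t: (float(i % w), float(i // w)) for i, t in enumerate(self.territories)
        }
        self.distances = DistanceMatrix.from_coordinates(self.coords)
        self.pop: dict[str, _Ind] = {}
        self._counter = 0
        self.events: list[ReproductiveEvent] = []
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        self.labels: dict[str, str] = {}
        self.sire: dict[str, str] = {}
        self.epm_origin: dict[str, str] = {}
        self.outside_males: set[str] = set()
        self.n_mutations = 0

    # -- id / genotype primitives --------------------------------------------

    def _new_id(self, prefix: str = "I") -> str:
        self._counter += 1
        return f"{prefix}{self._counter:05d}"

    def _founder_genome(self) -> np.ndarray:
        g = np.empty((self.n_loci, 2), dtype=np.int64)
        for j, f in enumerate(self.freqs):
            g[j] = self.rng.choice(len(f), size=2, p=f)
        return g

    def _gamete(self, genome: np.ndarray) -> np.ndarray:
        pick = self.rng.integers(0, 2, size=self.n_loci)
        alleles = genome[np.arange(self.n_loci), pick]
        mut = self.rng.random(self.n_loci) < self.cfg.mutation_rate
        for j in np.flatnonzero(mut):
            k = len(self.freqs[j])
            if k > 1:
                shift = int(self.rng.integers(1, k))
                alleles[j] = (alleles[j] + shift) % k
                self.n_mutations += 1
        return alleles

    def _offspring_genome(self, mother: _Ind, father: _Ind) -> np.ndarray:
        return np.stack([self._gamete(mother.genome), self._gamete(father.genome)], axis=1)

    # -- genetic scores on true genotypes -------------------------------------

    def _qg(self, gx: np.ndarray, gy: np.ndarray) -> float:
        num_xy = den_xy = num_yx = den_yx = 0.0
        for j in self.micro_idx:
            f = self.freqs[j]
            a, b = gx[j]
            c, d = gy[j]
            share = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
            num_xy += share - f[a] - f[b]
            den_xy += 1 + (a == b) - f[a] - f[b]
            num_yx += share - f[c] - f[d]
            den_yx += 1 + (c == d) - f[c] - f[d]
        parts = [n / d for n, d in ((num_xy, den_xy), (num_yx, den_yx)) if d != 0]
        return sum(parts) / len(parts) if parts else 0.0

    def _dissim2(self, g_male: np.ndarray, g_female: np.ndarray) -> int:
        pm = {self.mhc2_prot_code[a] for a in g_male[self.i_mhc2]} - {-1}
        pf = {self.mhc2_prot_code[a] for a in g_female[self.i_mhc2]} - {-1}
        return len(pm - pf)

    # -- demography ------------------------------------------------------------

    def _spawn(self, sex, age, territory, status, year) -> _Ind:
        ind = _Ind(self._new_id(), sex, year - age, None, None,
                   self._founder_genome(), territory, status)
        self.pop[ind.id] = ind
        self.parents[ind.id] = (None, None)
        return ind

    def init_population(self) -> None:
        y0 = self.cfg.start_year
        for t in self.territories:
            self._spawn("M", int(self.rng.integers(3, 7)), t, Status.DOMINANT, y0)
            self._spawn("F", int(self.rng.integers(3, 7)), t, Status.DOMINANT, y0)
            n_sub = int(_draw(self.rng, self.cfg.initial_sub_males))
            for _ in range(n_sub):
                self._spawn("M", int(self.rng.integers(1, 4)), t, Status.SUBORDINATE, y0)
            for _ in range(int(self.rng.integers(0, 3))):
                self._spawn("F", int(self.rng.integers(1, 4)), t, Status.SUBORDINATE, y0)

    def _alive(self) -> list[_Ind]:
        return [self.pop[i] for i in sorted(self.pop) if self.pop[i].alive]

    def _dominant(self, territory: str, sex: str) -> _Ind | None:
        for ind in self._alive():
            if ind.territory == territory and ind.sex == sex and ind.status is Status.DOMINANT:
                return ind
        return None

    def _kernel(self, d: float) -> float:
        return math.exp(-self.cfg.dispersal_rate * d)

    def _preference(self, male: _Ind, female: _Ind | None) -> float:
        if female is None:
            return 1.0
        cfg = self.cfg
        if cfg.mate_choice_mode == "mhcII_dissimilar":
            return math.exp(cfg.preference_strength * self._dissim2(male.genome, female.genome))
        if cfg.mate_choice_mode == "intermediate_Rqg":
            r = self._qg(male.genome, female.genome)
            return math.exp(-cfg.preference_strength * (r - cfg.intermediate_r_target) ** 2)
        return 1.0

    def _fill_vacancies(self, year: int) -> None:
        cfg = self.cfg
        if cfg.annual_repairing:
            for ind in self._alive():
                if ind.sex == "M" and ind.status is Status.DOMINANT:
                    ind.status = Status.SUBORDINATE
        # females first: the resident female defines the male preference
        for sex in ("F", "M"):
            for t in self.territories:
                if self._dominant(t, sex) is not None:
                    continue
                female = self._dominant(t, "F") if sex == "M" else None
                cands = [
                    ind for ind in self._alive()
                    if ind.sex == sex
                    and ind.status is Status.SUBORDINATE
                    and year - ind.birth_year >= cfg.maturity_age
                ]
                if not cands:
                    continue
                weights = np.array(
                    [
                        self._kernel(self.distances.distance(c.territory, t))
                        * (self._preference(c, female) if sex == "M" else 1.0)
                        for c in cands
                    ]
                )
                if weights.sum() <= 0:
                    continue
                pick = cands[int(self.rng.choice(len(cands), p=weights / weights.sum()))]
                pick.territory = t
                pick.status = Status.DOMINANT

    def _mature_sub_males(self, territory: str, year: int) -> list[_Ind]:
        return [
            ind for ind in self._alive()
            if ind.sex == "M"
            and ind.status is Status.SUBORDINATE
            and ind.territory == territory
            and year - ind.birth_year >= self.cfg.maturity_age
        ]

    def _choose_epm(self, territory: str, female: _Ind, year: int) -> tuple[_Ind, str]:
        cfg = self.cfg
        order = ["family_subordinate", "within_study_disperser", "outside_male"]
        cls = str(_draw(self.rng, cfg.epm_origin_probs))
        for attempt in [cls] + [c for c in order if c != cls]:
            if attempt == "family_subordinate":
                cands = [
                    m for m in self._mature_sub_males(territory, year)
                    if m.mother != female.id
                ]
                if cands:
                    return cands[int(self.rng.integers(len(cands)))], attempt
            elif attempt == "within_study_disperser":
                cands = [
                    ind for ind in self._alive()
                    if ind.sex == "M"
                    and ind.territory != territory
                    and ind.status is Status.SUBORDINATE
                    and year - ind.birth_year >= cfg.maturity_age
                ]
                if cands:
                    w = np.array(
                        [
                            self._kernel(self.distances.distance(c.territory, territory))
                            for c in cands
                        ]
                    )
                    return cands[int(self.rng.choice(len(cands), p=w / w.sum()))], attempt
            else:
                out = _Ind(self._new_id("OUT"), "M", year - 4, None, None,
                           self._founder_genome(), None, Status.ABSENT)
                self.pop[out.id] = out
                self.parents[out.id] = (None, None)
                self.outside_males.add(out.id)
                return out, attempt
        raise AssertionError("unreachable: outside male always available")

    def _eligible_males(self, year: int) -> list[_Ind]:
        return [
            ind for ind in self._alive()
            if ind.sex == "M"
            and ind.id not in self.outside_males
            and ind.territory is not None
            and year - ind.birth_year >= self.cfg.maturity_age
        ]

    def _breed(self, year: int) -> None:
        cfg = self.cfg
        eligible = self._eligible_males(year) if cfg.mate_choice_mode == "independent" else []
        for t in self.territories:
            male = self._dominant(t, "M")
            female = self._dominant(t, "F")
            if male is None or female is None:
                continue
            if self.rng.random() >= cfg.breeding_prob:
                continue
            if cfg.mate_choice_mode == "independent" and eligible:
                # draw the event's social male i.i.d. from the kernel-weighted
                # candidate pool: the exact null of the mate-choice test
                w = np.array(
                    [self._kernel(self.distances.distance(c.territory, t)) for c in eligible]
                )
                male = eligible[int(self.rng.choice(len(eligible), p=w / w.sum()))]
            litter_size = int(_draw(self.rng, cfg.litter_size_probs))
            subs = self._mature_sub_males(t, year)
            n_sub = len(subs)
            r = self._qg(male.genome, female.genome)
            dis = self._dissim2(male.genome, female.genome)
            eta = (cfg.epp_intercept + cfg.epp_beta_sub * n_sub + cfg.epp_beta_r * r
                   + cfg.epp_beta_r2 * r * r + cfg.epp_beta_dissim * dis)
            has_epp = self.rng.random() < 1.0 / (1.0 + math.exp(-min(max(eta, -500), 500)))
            n_epy = 0
            epm = None
            origin = None
            if has_epp:
                n_epy = min(int(_draw(self.rng, cfg.epy_count_probs)), litter_size)
                epm, origin = self._choose_epm(t, female, year)
            epy_slots = set(
                self.rng.choice(litter_size, size=n_epy, replace=False).tolist()
            ) if n_epy else set()
            pups: list[str] = []
            for k in range(litter_size):
                father = epm if k in epy_slots else male
                genome = self._offspring_genome(female, father)
                pup = _Ind(self._new_id(), "M" if self.rng.random() < 0.5 else "F",
                           year, female.id, father.id, genome, t, Status.PUP)
                self.pop[pup.id] = pup
                self.parents[pup.id] = (female.id, father.id)
                self.labels[pup.id] = "EPY" if k in epy_slots else "WPY"
                self.sire[pup.id] = father.id
                pups.append(pup.id)
            event = ReproductiveEvent(
                female=female.id,
                year=year,
                social_male=male.id,
                pups=tuple(pups),
                n_mature_sub_males=n_sub,
                territory=t,
            )
            self.events.append(event)
            if n_epy:
                self.epm_origin[event.litter_id] = origin

    def _record(self, year: int) -> None:
        for ind in self._alive():
            if ind.territory is None:
                continue
            ind.record_t[year] = ind.territory
            ind.record_s[year] = ind.status

    def _turnover(self, year: int) -> None:
        cfg = self.cfg
        for ind in self._alive():
            if ind.id in self.outside_males:
                continue
            age = year - ind.birth_year
            if ind.status is Status.PUP:
                if self.rng.random() >= cfg.pup_survival:
                    ind.alive = False
                else:
                    ind.status = Status.SUBORDINATE
            elif ind.status is Status.DOMINANT:
                if self.rng.random() < cfg.adult_mortality:
                    ind.alive = False
            else:
                if self.rng.random() < cfg.sub_mortality:
                    ind.alive = False
                elif age >= cfg.maturity_age and self.rng.random() < cfg.sub_emigration:
                    ind.alive = False  # emigrated out of the study area

    def run(self) -> None:
        self.init_population()
        for year in range(self.cfg.start_year, self.cfg.start_year + self.cfg.years):
            self._fill_vacancies(year)
            if not any(
                ind.status is Status.DOMINANT and ind.sex == "M" for ind in self._alive()
            ):
                raise RuntimeError(f"population extinct (no eligible males) in {year}")
            self._breed(year)
            self._record(year)
            self._turnover(year)

    # -- exports ---------------------------------------------------------------

    def loci_spec(self) -> list[Locus]:
        loci = [Locus(f"MS{j + 1:02d}") for j in range(self.cfg.n_microsat_loci)]
        loci.append(self.cfg.mhc_class_I.to_locus())
        loci.append(self.cfg.mhc_class_II.to_locus())
        return loci

    def _labels_for(self, j: int) -> list[str]:
        if j < self.cfg.n_microsat_loci:
            return [str(100 + 2 * a) for a in range(self.cfg.n_alleles)]
        if j == self.i_mhc1:
            return list(self.cfg.mhc_class_I.alleles)
        return list(self.cfg.mhc_class_II.alleles)

    @staticmethod
    def _trio_ok(off: np.ndarray, mo: np.ndarray, fa: np.ndarray) -> bool:
        x, y = off
        return (x in mo and y in fa) or (y in mo and x in fa)

    def observed_table(self) -> tuple[GenotypeTable, int]:
        """Emit the observed genotype table (with genotyping error and
        missingness) for every studied individual; outside males withheld."""
        cfg = self.cfg
        loci = self.loci_spec()
        label_maps = [self._labels_for(j) for j in range(self.n_loci)]
        ids = [i for i in sorted(self.pop) if i not in self.outside_males]
        n_err = 0
        obs: dict[str, np.ndarray] = {}
        for ind_id in ids:
            genome = self.pop[ind_id].genome.copy()
            for j in range(self.n_loci):
                if self.rng.random() < cfg.genotyping_error:
                    k = len(self.freqs[j])
                    if k > 1:
                        shift = int(self.rng.integers(1, k))
                        slot = int(self.rng.random() < 0.5)
                        genome[j, slot] = (genome[j, slot] + shift) % k
                        n_err += 1
            obs[ind_id] = genome
        if cfg.retype_mismatches:
            # mismatch-triggered re-typing: where a single-read error fakes a
            # trio incompatibility, the confirmed (true) genotypes replace it
            for e in self.events:
                mo_id, fa_id = e.female, e.social_male
                for pup in e.pups:
                    for j in range(self.n_loci):
                        if self._trio_ok(obs[pup][j], obs[mo_id][j], obs[fa_id][j]):
                            continue
                        if self._trio_ok(
                            self.pop[pup].genome[j],
                            self.pop[mo_id].genome[j],
                            self.pop[fa_id].genome[j],
                        ):
                            for who in (pup, mo_id, fa_id):
                                obs[who][j] = self.pop[who].genome[j]
        calls: dict[str, dict[str, tuple | None]] = {}
        for ind_id in ids:
            rec: dict[str, tuple | None] = {}
            for j, locus in enumerate(loci):
                if cfg.missing_rate and self.rng.random() < cfg.missing_rate:
                    rec[locus.name] = None
                    continue
                a, b = obs[ind_id][j]
                rec[locus.name] = (label_maps[j][a], label_maps[j][b])
            calls[ind_id] = rec
        return GenotypeTable(ids, loci, calls), n_err

    def true_table(self) -> GenotypeTable:
        """Noise-free genotypes of every simulated individual (incl. outside
        males); the truth-side complement of the observed table."""
        loci = self.loci_spec()
        label_maps = [self._labels_for(j) for j in range(self.n_loci)]
        ids = sorted(self.pop)
        calls = {
            i: {
                loci[j].name: (label_maps[j][self.pop[i].genome[j, 0]],
                               label_maps[j][self.pop[i].genome[j, 1]])
                for j in range(self.n_loci)
            }
            for i in ids
        }
        return GenotypeTable(ids, loci, calls)

    def registry(self) -> PopulationRegistry:
        inds = []
        for i in sorted(self.pop):
            if i in self.outside_males:
                continue
            rec = self.pop[i]
            inds.append(
                Individual(
                    id=i,
                    sex=rec.sex,
                    birth_year=rec.birth_year,
                    territory_by_year=dict(rec.record_t),
                    status_by_year=dict(rec.record_s),
                )
            )
        return PopulationRegistry(inds, self.distances)


def simulate(config: SimConfig) -> SimDataset:
    """Run the forward simulation and return the full dataset with truth.

    The config's seed is mandatory: every stochastic draw flows from it.
    """
    if config.seed is None:
        raise ValueError("SimConfig.seed is mandatory")
    rng = np.random.default_rng(config.seed)
    sim = _Sim(config, rng)
    sim.run()
    gt, n_err = sim.observed_table()
    truth = SimTruth(
        pedigree=Pedigree(sim.parents),
        labels=dict(sim.labels),
        sire=dict(sim.sire),
        epm_origin=dict(sim.epm_origin),
        n_mutations=sim.n_mutations,
        n_genotyping_errors=n_err,
        outside_males=set(sim.outside_males),
    )
    return SimDataset(
        genotypes=gt,
        registry=sim.registry(),
        events=sim.events,
        truth=truth,
        config=config,
        true_genotypes=sim.true_table(),
    )


# -- presets -------------------------------------------------------------------


def paper_scale_config(seed: int = 2016, **overrides) -> SimConfig:
    """Preset sized like the field study: ~145 litters, mean litter size
    near 3.6, and an overall EPY rate of pups in the 5-10% band."""
    params = dict(
        seed=seed,
        n_territories=25,
        years=9,
        epp_intercept=-2.0,
        mate_choice_mode="random",
    )
    params.update(overrides)
    return SimConfig(**params)


def null_config(seed: int, n_territories: int = 10, years: int = 6, **overrides) -> SimConfig:
    """Small random-mating preset for nominal-level (type I) checks.

    Each reproductive event's social male is a fresh, independent kernel-
    weighted draw from the eligible males -- exactly the null hypothesis the
    bootstrap procedure simulates.  Under the demographically coupled
    ``random`` mode (vacancies filled without replacement, multi-year
    tenure) the test is conservative; see the methods note.
    """
    params = dict(
        seed=seed,
        n_territories=n_territories,
        years=years,
        mate_choice_mode="independent",
    )
    params.update(overrides)
    return SimConfig(**params)


def emulate_paper_scale(seed: int = 2016) -> SimDataset:
    return simulate(paper_scale_config(seed))


# -- fixture export ------------------------------------------------------------


def export_fixtures(dataset: SimDataset, out_dir) -> dict[str, Path]:
    """Write the CSV suite consumed by the other modules, plus truth tables
    and a JSON manifest of the configuration.  Deterministic under the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.csv",
        "individuals": out / "individuals.csv",
        "statuses": out / "statuses.csv",
        "distances": out / "distances.csv",
        "events": out / "events.csv",
        "truth_parentage": out / "truth_parentage.csv",
        "manifest": out / "manifest.json",
        "genepop": out / "genotypes.gen",
    }
    write_genotypes(dataset.genotypes, paths["genotypes"])
    write_registry(dataset.registry, paths["individuals"], paths["statuses"], paths["distances"])
    write_events(dataset.events, paths["events"])
    import pandas as pd

    rows = []
    pup_litter = {p: e.litter_id for e in dataset.events for p in e.pups}
    for pup in sorted(dataset.truth.labels):
        mo, fa = dataset.truth.pedigree.parents.get(pup, (None, None))
        rows.append(
            {
                "pup": pup,
                "litter": pup_litter.get(pup, ""),
                "mother": mo or "",
                "father": fa or "",
                "label": dataset.truth.labels[pup],
                "epm_origin": dataset.truth.epm_origin.get(pup_litter.get(pup, ""), ""),
            }
        )
    pd.DataFrame(rows).to_csv(paths["truth_parentage"], index=False)
    cfg = dataclasses.asdict(dataset.config)
    cfg["mhc_class_I"] = dataclasses.asdict(dataset.config.mhc_class_I)
    cfg["mhc_class_II"] = dataclasses.asdict(dataset.config.mhc_class_II)
    paths["manifest"].write_text(json.dumps(cfg, indent=2, sort_keys=True, default=str))
    write_genepop(dataset.genotypes, paths["genepop"])
    import yaml

    from .genotype_io import loci_to_records

    paths["loci"] = out / "loci.yaml"
    paths["loci"].write_text(
        yaml.safe_dump(loci_to_records(dataset.genotypes.loci), sort_keys=False)
    )
    paths["config"] = out / "config.yaml"
    paths["config"].write_text(
        yaml.safe_dump(
            {
                "genotypes": "genotypes.csv",
                "loci": "loci.yaml",
                "individuals": "individuals.csv",
                "statuses": "statuses.csv",
                "distances": "distances.csv",
                "events": "events.csv",
            },
            sort_keys=False,
        )
    )
    return paths


# -- focused pedigree generators ----------------------------------------------


def _mini_table(genomes: dict[str, np.ndarray], n_loci: int, n_alleles: int) -> GenotypeTable:
    loci = [Locus(f"MS{j + 1:02d}") for j in range(n_loci)]
    labels = [str(100 + 2 * a) for a in range(n_alleles)]
    calls = {
        i: {loci[j].name: (labels[g[j, 0]], labels[g[j, 1]]) for j in range(n_loci)}
        for i, g in genomes.items()
    }
    return GenotypeTable(sorted(genomes), loci, calls)


def _founder(rng, n_loci, n_alleles) -> np.ndarray:
    return rng.integers(0, n_alleles, size=(n_loci, 2))


def _child(rng, mother, father) -> np.ndarray:
    n = mother.shape[0]
    return np.stack(
        [mother[np.arange(n), rng.integers(0, 2, n)],
         father[np.arange(n), rng.integers(0, 2, n)]],
        axis=1,
    )


def simulate_relative_pairs(
    relationship: str,
    n_pairs: int,
    n_loci: int = 16,
    n_alleles: int = 8,
    seed: int | None = None,
) -> tuple[GenotypeTable, list[tuple[str, str]]]:
    """Simulate genotype pairs of a fixed pedigree relationship.

    ``relationship`` is one of ``parent_offspring``, ``full_sib``,
    ``half_sib`` or ``unrelated``; loci are independent with equifrequent
    alleles and inheritance is exactly Mendelian (no mutation, no error).
    """
    rng = np.random.default_rng(seed)
    genomes: dict[str, np.ndarray] = {}
    pairs: list[tuple[str, str]] = []
    for k in range(n_pairs):
        if relationship == "parent_offspring":
            mo, fa = _founder(rng, n_loci, n_alleles), _founder(rng, n_loci, n_alleles)
            a, b = fa, _child(rng, mo, fa)
        elif relationship == "full_sib":
            mo, fa = _founder(rng, n_loci, n_alleles), _founder(rng, n_loci, n_alleles)
            a, b = _child(rng, mo, fa), _child(rng, mo, fa)
        elif relationship == "half_sib":
            fa = _founder(rng, n_loci, n_alleles)
            mo1, mo2 = _founder(rng, n_loci, n_alleles), _founder(rng, n_loci, n_alleles)
            a, b = _child(rng, mo1, fa), _child(rng, mo2, fa)
        elif relationship == "unrelated":
            a, b = _founder(rng, n_loci, n_alleles), _founder(rng, n_loci, n_alleles)
        else:
            raise ValueError(f"unknown relationship {relationship!r}")
        ia, ib = f"P{k:05d}a", f"P{k:05d}b"
        genomes[ia], genomes[ib] = a, b
        pairs.append((ia, ib))
    return _mini_table(genomes, n_loci, n_alleles), pairs


def simulate_pedigree_panel(
    n_units: int = 60,
    n_loci: int = 16,
    n_alleles: int = 8,
    seed: int | None = None,
) -> tuple[GenotypeTable, Pedigree, list[tuple[str, str, str]]]:
    """A three-generation pedigree panel spanning relatedness 0.5 to 0.

    Each unit holds a grandparental couple, two full-sib offspring with
    unrelated spouses, grandchildren (full sibs, half sibs, first cousins)
    and designated unrelated pairs.  Returns the genotype table, the true
    pedigree and a list of (id_a, id_b, relationship) pairs covering
    parent-offspring (0.5), full sibs (0.5), half sibs (0.25), avuncular
    (0.25), first cousins (0.125) and unrelated (0).
    """
    rng = np.random.default_rng(seed)
    genomes: dict[str, np.ndarray] = {}
    parents: dict[str, tuple[str | None, str | None]] = {}
    pairs: list[tuple[str, str, str]] = []

    def founder(name):
        genomes[name] = _founder(rng, n_loci, n_alleles)
        parents[name] = (None, None)
        return name

    def child(name, mo, fa):
        genomes[name] = _child(rng, genomes[mo], genomes[fa])
        parents[name] = (mo, fa)
        return name

    for k in range(n_units):
        u = f"U{k:03d}"
        gm, gf = founder(f"{u}gm"), founder(f"{u}gf")
        a, b = child(f"{u}a", gm, gf), child(f"{u}b", gm, gf)
        sa, sb, um = founder(f"{u}sa"), founder(f"{u}sb"), founder(f"{u}um")
        c1, c2 = child(f"{u}c1", a, sa), child(f"{u}c2", a, sa)
        d1 = child(f"{u}d1", b, sb)
        h1 = child(f"{u}h1", um, sa)
        pairs += [
            (a, c1, "parent_offspring"),
            (c1, c2, "full_sib"),
            (c1, h1, "half_sib"),
            (b, c1, "avuncular"),
            (c1, d1, "first_cousin"),
            (sa, sb, "unrelated"),
        ]
    return _mini_table(genomes, n_loci, n_alleles), Pedigree(parents), pairs
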