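"""Neutral diversity and compatibility estimators and MHC protein scores.

Microsatellite-based individual diversity is measured by standardized
heterozygosity (SH), internal relatedness (IR) and homozygosity by locus
(HL); pairwise genetic compatibility by the Queller & Goodnight moment
estimator of relatedness (R_qg, ratio-of-sums multilocus form, the two
directional estimates averaged into a symmetric pair value).

MHC scores operate on *protein* labels, not allele labels: alleles that
translate to the same protein collapse, and a protein flagged non-functional
(a stop-codon product) is excluded from diversity and dissimilarity but kept
for presence/absence features, since carrying the allele may itself be
deleterious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .genotype_io import (
    AlleleFrequencies,
    GenotypeTable,
    Locus,
    LocusKind,
    allele_frequencies,
)

__all__ = [
    "DiversityScore",
    "CompatibilityScore",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "standardized_heterozygosity",
    "internal_relatedness",
    "homozygosity_by_locus",
    "qg_relatedness",
    "relatedness_deviation",
    "protein_sets",
    "mhc_protein_diversity",
    "mhc_protein_dissimilarity",
    "protein_presence_features",
]


@dataclass(frozen=True)
class DiversityScore:
    individual: str
    estimator: str
    value: float
    n_loci_used: int


@dataclass(frozen=True)
class CompatibilityScore:
    pair: tuple[str, str]
    estimator: str
    value: float
    n_loci_used: int


# -- per-locus population heterozygosity --------------------------------------


def observed_heterozygosity(
    gt: GenotypeTable, subset: Sequence[str] | None = None
) -> dict[str, float]:
    """Proportion of heterozygous calls per microsatellite locus."""
    inds = list(gt.individuals) if subset is None else list(subset)
    out: dict[str, float] = {}
    for locus in gt.microsat_loci:
        het = n = 0
        for ind in inds:
            call = gt.call(ind, locus.name)
            if call is None:
                continue
            n += 1
            het += call[0] != call[1]
        if n:
            out[locus.name] = het / n
    return out


def expected_heterozygosity(
    freqs: AlleleFrequencies, unbiased: bool = True
) -> dict[str, float]:
    """Expected heterozygosity ``1 - sum(p^2)`` per locus.

    With ``unbiased`` the small-sample correction ``n/(n-1)`` over allele
    copies is applied (Nei's unbiased gene diversity).
    """
    out: dict[str, float] = {}
    for name, f in freqs.freqs.items():
        h = 1.0 - sum(p * p for p in f.values())
        if unbiased:
            n = freqs.n_copies[name]
            if n > 1:
                h *= n / (n - 1)
        out[name] = h
    return out


# -- individual diversity ------------------------------------------------------


def standardized_heterozygosity(
    ind: str,
    gt: GenotypeTable,
    per_locus_het: Mapping[str, float] | None = None,
) -> DiversityScore:
    """Standardized heterozygosity (SH).

    The proportion of the individual's typed microsatellite loci that are
    heterozygous, divided by the mean population heterozygosity of those same
    loci.  ``per_locus_het`` defaults to the *observed* per-locus
    heterozygosity computed from the whole table (an expected-heterozygosity
    variant can be passed explicitly).
    """
    if per_locus_het is None:
        per_locus_het = observed_heterozygosity(gt)
    typed = gt.typed_loci(ind, LocusKind.MICROSATELLITE)
    if not typed:
        raise ValueError(f"{ind!r} typed at no microsatellite locus")
    het = sum(1 for l in typed if (c := gt.call(ind, l.name))[0] != c[1])
    mean_h = sum(per_locus_het[l.name] for l in typed) / len(typed)
    if mean_h == 0:
        raise ValueError("monomorphic panel: mean per-locus heterozygosity is 0")
    return DiversityScore(ind, "SH", (het / len(typed)) / mean_h, len(typed))


def internal_relatedness(
    ind: str, gt: GenotypeTable, freqs: AlleleFrequencies
) -> DiversityScore:
    """Internal relatedness (IR) = (2H - sum f) / (2N - sum f).

    H is the number of homozygous typed loci, N the number of typed loci and
    sum f the summed population frequencies of the individual's 2N allele
    copies.  Homozygotes for rare alleles score higher than homozygotes for
    common ones.
    """
    typed = gt.typed_loci(ind, LocusKind.MICROSATELLITE)
    if not typed:
        raise ValueError(f"{ind!r} typed at no microsatellite locus")
    n_hom = 0
    sum_f = 0.0
    for locus in typed:
        a, b = gt.call(ind, locus.name)
        n_hom += a == b
        f = freqs[locus.name]
        sum_f += f[a] + f[b]
    den = 2 * len(typed) - sum_f
    if den == 0:
        raise ValueError("IR denominator is zero")
    return DiversityScore(ind, "IR", (2 * n_hom - sum_f) / den, len(typed))


def homozygosity_by_locus(
    ind: str,
    gt: GenotypeTable,
    exp_het: Mapping[str, float] | None = None,
    freqs: AlleleFrequencies | None = None,
) -> DiversityScore:
    """Homozygosity by locus (HL), expected-heterozygosity weighted.

    ``HL = sum(E_l, homozygous loci) / (sum(E_l, homozygous) +
    sum(E_l, heterozygous))`` where ``E_l`` is the expected heterozygosity of
    locus *l*.  Loci at which the individual is untyped do not contribute.
    """
    if exp_het is None:
        if freqs is None:
            freqs = allele_frequencies(gt, loci=[l.name for l in gt.microsat_loci])
        exp_het = expected_heterozygosity(freqs)
    typed = gt.typed_loci(ind, LocusKind.MICROSATELLITE)
    if not typed:
        raise ValueError(f"{ind!r} typed at no microsatellite locus")
    e_hom = e_het = 0.0
    for locus in typed:
        a, b = gt.call(ind, locus.name)
        if a == b:
            e_hom += exp_het[locus.name]
        else:
            e_het += exp_het[locus.name]
    if e_hom + e_het == 0:
        raise ValueError("HL undefined: all typed loci have zero expected heterozygosity")
    return DiversityScore(ind, "HL", e_hom / (e_hom + e_het), len(typed))


# -- pairwise compatibility ----------------------------------------------------


def qg_relatedness(
    x: str, y: str, gt: GenotypeTable, freqs: AlleleFrequencies
) -> CompatibilityScore:
    """Queller & Goodnight relatedness between two individuals.

    Per shared typed microsatellite locus with ``x = (a, b)``, ``y = (c, d)``
    and population frequencies ``p``::

        num(x->y) = 0.5 (d_ac + d_ad + d_bc + d_bd) - p_a - p_b
        den(x->y) = 1 + d_ab - p_a - p_b

    where ``d`` is the Kronecker delta on allele identity.  The directional
    estimate is the ratio of sums over loci; the symmetric pair value is the
    mean of the two directions.  Loci monomorphic in the reference population
    are excluded (degenerate denominator).
    """
    num_xy = den_xy = num_yx = den_yx = 0.0
    n_used = 0
    for locus in gt.microsat_loci:
        cx = gt.call(x, locus.name)
        cy = gt.call(y, locus.name)
        if cx is None or cy is None:
            continue
        f = freqs[locus.name]
        if len(f) < 2:
            continue
        a, b = cx
        c, d = cy
        share = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        num_xy += share - f[a] - f[b]
        den_xy += 1 + (a == b) - f[a] - f[b]
        num_yx += share - f[c] - f[d]
        den_yx += 1 + (c == d) - f[c] - f[d]
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no shared typed polymorphic locus for ({x!r}, {y!r})")
    parts = [n / d for n, d in ((num_xy, den_xy), (num_yx, den_yx)) if d != 0]
    if not parts:
        raise ValueError("both directional denominators are zero")
    return CompatibilityScore((x, y), "R_qg", sum(parts) / len(parts), n_used)


def relatedness_deviation(r: float, r_ref: float) -> float:
    """Absolute deviation of a relatedness value from a reference value.

    The reference is typically the relatedness at which the fitted quadratic
    extra-pair-paternity model reaches its minimum ("intermediate"
    relatedness).
    """
    return abs(r - r_ref)


# -- MHC protein scores --------------------------------------------------------


def protein_sets(
    ind: str, gt: GenotypeTable, locus: Locus | str, functional_only: bool = True
) -> frozenset[str]:
    """Distinct protein labels produced by the individual's two MHC alleles.

    With ``functional_only`` the non-functional (stop codon) protein is
    removed from the set.
    """
    if isinstance(locus, str):
        locus = gt.locus(locus)
    if not locus.kind.is_mhc:
        raise ValueError(f"{locus.name!r} is not an MHC locus")
    call = gt.call(ind, locus.name)
    if call is None:
        raise ValueError(f"MHC call missing for {ind!r} at {locus.name!r}")
    proteins = {locus.protein(a) for a in call}
    if functional_only:
        proteins = {p for p in proteins if locus.is_functional(p)}
    return frozenset(proteins)


def mhc_protein_diversity(ind: str, gt: GenotypeTable, locus: Locus | str) -> DiversityScore:
    """Number of different functional MHC proteins an individual produces.

    Computed per locus; class I and class II are never pooled because the
    two classes sit under different selective pressures.
    """
    if isinstance(locus, str):
        locus = gt.locus(locus)
    value = len(protein_sets(ind, gt, locus, functional_only=True))
    return DiversityScore(ind, f"mhc_protein_diversity({locus.kind.value})", value, 1)


def mhc_protein_dissimilarity(
    male: str, female: str, gt: GenotypeTable, locus: Locus | str
) -> CompatibilityScore:
    """Number of functional proteins the male produces that the female does not.

    Directional by definition (male relative to female).
    """
    if isinstance(locus, str):
        locus = gt.locus(locus)
    m = protein_sets(male, gt, locus, functional_only=True)
    f = protein_sets(female, gt, locus, functional_only=True)
    return CompatibilityScore(
        (female, male),
        f"mhc_protein_dissimilarity({locus.kind.value})",
        len(m - f),
        1,
    )


def protein_presence_features(
    gt: GenotypeTable,
    locus: Locus | str,
    population: Sequence[str] | None = None,
    lower: float = 0.05,
    upper: float = 0.95,
) -> tuple[dict[str, dict[str, int]], dict[str, float]]:
    """Per-individual 0/1 presence indicators for MHC proteins.

    Only proteins carried by strictly more than ``lower`` and strictly less
    than ``upper`` of the typed individuals in *population* are retained
    (near-fixed and near-absent proteins give degenerate tests).  All
    proteins, including a non-functional one, are considered: carrying the
    stop-codon allele may itself matter.

    Returns
    -------
    features, dropped
        ``features[protein][individual]`` is the 0/1 indicator over typed
        individuals; ``dropped`` maps each excluded protein to its carrier
        proportion.
    """
    if isinstance(locus, str):
        locus = gt.locus(locus)
    if population is None:
        population = list(gt.individuals)
    if not population:
        raise ValueError("population must be non-empty")
    typed = [i for i in population if not gt.is_missing(i, locus.name)]
    if not typed:
        raise ValueError(f"no individual typed at {locus.name!r}")
    carriers: dict[str, set[str]] = {}
    for ind in typed:
        for p in protein_sets(ind, gt, locus, functional_only=False):
            carriers.setdefault(p, set()).add(ind)
    features: dict[str, dict[str, int]] = {}
    dropped: dict[str, float] = {}
    for p in sorted(carriers):
        prop = len(carriers[p]) / len(typed)
        if lower < prop < upper:
            features[p] = {ind: int(ind in carriers[p]) for ind in typed}
        else:
            dropped[p] = prop
    return features, dropped
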