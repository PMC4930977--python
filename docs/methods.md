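# Methods

`matechoice` implements the analysis chain of a genetic mate-choice study in
a territorial, socially monogamous mammal (the motivating system is the
Alpine marmot, *Marmota marmota*): family groups hold territories, only the
dominant pair routinely breeds, and extra-pair paternity (EPP) occurs.  The
questions the toolchain addresses are (i) whether social males or social
pairs differ genetically from what random mate choice would produce, and
(ii) whether the occurrence and number of extra-pair young (EPY) in a litter
depend on the pair's genetic characteristics, measured both at neutral
markers (microsatellites) and at functional MHC loci.

## Markers and estimators

Individuals are genotyped at a panel of microsatellites (16 by default in
the simulator) and at two MHC loci, one class I and one class II.  MHC
scores operate on *protein* labels: alleles translating to the same protein
collapse, and one class II protein carrying a premature stop codon is
treated as non-functional (excluded from diversity/dissimilarity scores but
retained in presence/absence features, since carrying the allele may itself
be deleterious).

Individual neutral diversity:

- **SH** (standardized heterozygosity): proportion of the individual's typed
  loci that are heterozygous, divided by the mean population heterozygosity
  of those same loci.  Population *observed* heterozygosity is the default
  reference (an expected-heterozygosity map can be passed instead); its mean
  over a population is ~1 by construction.
- **IR** (internal relatedness): `(2H - Σf) / (2N - Σf)` with `H` homozygous
  loci, `N` typed loci and `Σf` the summed population frequencies of the 2N
  allele copies.  Bounded in [-1, 1]; homozygotes for rare alleles score
  higher than homozygotes for common alleles.
- **HL** (homozygosity by locus): expected-heterozygosity-weighted
  proportion of homozygous loci, in [0, 1].

Pairwise neutral compatibility is Queller & Goodnight's moment estimator
`R_qg`.  Per locus, with focal genotype (a, b), partner (c, d) and
population frequencies `p`:

    num = 0.5 (δ_ac + δ_ad + δ_bc + δ_bd) − p_a − p_b
    den = 1 + δ_ab − p_a − p_b

The directional estimate is the ratio of sums over loci (not the mean of
per-locus ratios), and the reported pair value is the average of the two
directions — symmetric by construction.  Loci monomorphic in the reference
population are excluded (degenerate denominator); missing loci are skipped
pairwise, and `n_loci_used` is always reported.  Allele frequencies default
to the pooled set of all genotyped individuals across years; a subset hook
exists because the appropriate reference population is an analysis choice.

`relatedness_deviation(r, r_ref) = |r − r_ref|` measures distance from a
reference ("intermediate") relatedness, typically the vertex of the fitted
quadratic EPP model.

MHC scores per locus: **protein diversity** is the number of distinct
functional proteins an individual produces (0–2 for a single locus);
**protein dissimilarity** is the number of functional proteins the male
produces that the female does not — directional by definition, male relative
to female.  Presence/absence features retain only proteins carried by
strictly more than 5% and strictly less than 95% of typed individuals.

## Exclusion parentage

Maternity is checked first (dominant female vs. each pup; zero mismatches
expected).  A pup is a within-pair young (WPY) if its genotype shows zero
mismatches with the dominant male *given the known mother*, else an
extra-pair young (EPY).  A locus "mismatch" with the mother known is decided
by full transmission-pattern enumeration: the pup's allele pair must be
decomposable into one allele carryable by the mother and one by the
candidate father.  (The naive shares-an-allele rule is wrong here: offspring
(A,B) with mother (A,B) is *incompatible* with a candidate (C,C), because
one allele must still be paternal.)  A brute-force enumeration oracle
validates the closed-form rule in the tests.

A single paternal mismatch classifies a pup as EPY (configurable via
`max_paternal_mismatch`): with a per-call genotyping error of 3×10⁻⁴, a
microsatellite mutation rate of 1.67×10⁻⁴ per gamete per locus, and the
field workflow of re-typing every mismatch-implicated pup and its putative
parents, a true within-pair pup essentially never retains even one
incompatibility (the simulator measures ~0.5–0.6% false EPY over true WPY;
without the confirming re-type the single-read rate would be ~1.3%).

Extra-pair sires are assigned by exclusion among candidate males (zero
mismatches, mother known): a unique survivor is assigned; ties are broken on
MHC-locus consistency; unresolved ties and empty candidate sets yield
UNKNOWN.  Likelihood-based assignment with an explicit typing-error model is
deliberately out of scope.

Pedigree relatedness (the oracle for marker-based estimates) is twice the
kinship coefficient from the standard recursion, with founders unrelated and
non-inbred; a gene-dropping Monte Carlo cross-checks it in the tests.

## The bootstrap test of random mate choice

For each reproductive event, the candidate pool holds every male present in
the population that year and at least `min_age` (default 3) years old; the
observed social male is always a member.  Candidate weights follow a
dispersal-distance kernel evaluated at the territory distance to the focal
female — exponential decay `exp(-λd)` by default (rate per territory unit;
empirical dispersal-distance tables can be supplied as a step kernel, and a
uniform kernel reproduces unweighted choice, making results invariant to the
distance matrix).

The statistic is the mean over events of

    v(social male) − Σ_i w_i v(candidate_i)

with the observed social male excluded from the candidate side and weights
renormalised (including him biases the difference toward zero).  The null
distribution re-allocates, per event and per replicate, a pseudo-social male
drawn from the weighted pool, then evaluates the same contrast against the
remaining candidates; B = 1000 replicates by default.  The weighted pool
mean is the expectation of sampling a single "one of the other males"
candidate; a `single_candidate` mode implements the sampled variant
literally.  The exact two-tailed P reflects the observed difference around
the simulated mean: with `μ = mean(sims)` and `d = |obs − μ|`,

    p = (#{s > μ + d} + #{s < μ − d}) / B

with strict inequalities and resolution 1/B.  P is invariant to adding a
constant to every score.

**Calibration.**  With per-event independent allocation (the test's own
null), the measured type-I rate at the 5% level is 0.050 over 400 simulated
datasets (B = 200).  Under the demographically realistic regime — dominant
males seated by vacancy succession, without replacement within a year, with
multi-year tenure — the test is *conservative* (measured ~0.02): the
observed events are not independent draws from the pool, so the null
over-states the statistic's variance.  This is a property of the published
procedure worth knowing when interpreting marginal P values; the simulator
exposes both regimes (`mate_choice_mode="independent"` vs. `"random"`).
Power against a simulated preference for MHC class II dissimilar males
exceeds 0.5 (measured ≈1.0) at ~150 events with preference strength 1.5 on
the log-weight scale.

## GEE models of extra-pair paternity

EPY presence is modelled binomial-logit and EPY count Poisson-log, with
repeated litters of the same social pair as clusters under an exchangeable
working correlation.  Every model includes litter size, the number of
sexually mature subordinate males, pair relatedness `R_qg` and its square;
the genetic term under test enters linearly, one term per model.  The solver
is Fisher scoring on the GEE score equation with `V_i = φ A_i^{1/2} R(α)
A_i^{1/2}`; α is the pairwise Pearson-residual moment estimator with an
(N* − p) degrees-of-freedom correction and φ is Pearson χ²/(N − p), both
refreshed each iteration (these match geepack's and statsmodels' defaults;
the tests verify agreement with statsmodels GEE to ~10⁻⁸ on the
coefficients).  Inference uses the robust sandwich covariance; convergence
is max |Δβ| < 10⁻⁸ within 50 iterations, and non-convergence returns a
flagged fit rather than raising.  Covariates are left on their natural
scales.

The vertex `−β₁/(2β₂)` of the fitted quadratic is the relatedness at which
the linear predictor is extremal (a minimum iff β₂ > 0) — the "intermediate
relatedness" at which extra-pair paternity is least likely.  It is validated
by recovery of a planted vertex (±0.05 at 300 clusters), not against any
published coefficient table: the published coefficients come from the real
study population, which is not deposited.

## The synthetic population

`synthetic_data.simulate` is a forward simulator of the study system and the
source of every fixture: territories on a unit grid, each with a dominant
pair, subordinates and pups; annual breeding (probability 0.75 per occupied
territory), litter sizes 1–7 with mean ≈3.6; subordinate males mature at 2
years; vacancies are filled by mature candidates weighted by the exponential
dispersal kernel, optionally biased by an MHC class II dissimilarity or
intermediate-relatedness preference.  EPP per litter follows a logistic
model in the subordinate-male count (+0.47 per male), pair relatedness
(−1.73 r + 8.40 r², a minimum near intermediate relatedness) and class II
dissimilarity (−0.86); EPY counts within affected litters follow the
distribution {1: 45%, 2: 30%, 3: 20%, 5: 5%} truncated at litter size, sired
by one extra-pair male per litter, drawn as a family subordinate (45%), a
within-study disperser (15%) or an un-sampled outside male (40%) with
fallbacks when a class is empty.  Outside-male genotypes are withheld from
the observed table, emulating unknown sires.

Genetics: 16 unlinked microsatellites with 8 equifrequent alleles; a class I
MHC locus with 3 alleles / 2 proteins; a class II locus with 8 alleles / 7
proteins, one non-functional, with frequencies chosen so six of the seven
proteins fall inside the 5–95% carrier band.  Inheritance is Mendelian with
per-gamete mutation 1.67×10⁻⁴ (uniform switch to another allele) and
per-call genotyping error 3×10⁻⁴ applied when the observed table is
emitted; mismatch-implicated trios are re-typed (errors corrected, mutations
persist), matching the field workflow.  All draws flow from one seeded
generator; outputs and exported fixture files are byte-identical under a
fixed seed.

The `paper_scale_config` preset reproduces the scale of the motivating
study at its default seed: ~145–165 litters over 9 years on 25 territories,
mean litter size ≈3.5, and an overall EPY rate of pups inside 5–10%.
`null_config` is the small independent-allocation preset used for type-I
calibration.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: linkage and realistic allele-frequency spectra at
microsatellites, population genetic structure and inbreeding accumulation,
age- and mass-dependent demography, hibernation survival, observation error
in status assignment, and missing genotypes (the missingness rate defaults
to 0; a configurable rate exists).  Estimator recovery bounds are therefore
best-case for the marker panel sizes simulated.

## Numerical and design notes

- Allele labels are opaque strings; pairs are stored unordered (canonical
  sorted form), and "NA", "" and "0" all read as missing.
- Genepop export uses stable sorted 3-digit allele codes, `000000` for
  missing, and emits the code map alongside; an independent in-package
  reader closes the round trip.
- Percentages in the EPP summary are their defining ratios rounded half-up
  to two decimals.
- Exchangeable α is clamped to its valid range
  (−1/(max cluster size − 1), 1); the linear predictor is clipped at ±30 to
  guard the logistic against separation, which is also warned about.
- Spearman CIs use the Fisher z-transform with SE 1/√(n−3).
- The bootstrap contribution of a singleton pool is 0 and flagged; events
  with an undefined statistic are dropped with a warning, never silently.
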