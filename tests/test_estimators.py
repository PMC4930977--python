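import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import matechoice.estimators as est
from matechoice.genotype_io import GenotypeTable, Locus, allele_frequencies
from matechoice.synthetic_data import default_class_II, simulate_relative_pairs
from .conftest import random_table


# -- independent brute-force recomputations (spreadsheet style) ----------------


def brute_sh(ind, gt, het):
    loci = [l for l in gt.microsat_loci if gt.call(ind, l.name) is not None]
    prop = np.mean([gt.call(ind, l.name)[0] != gt.call(ind, l.name)[1] for l in loci])
    return prop / np.mean([het[l.name] for l in loci])


def brute_ir(ind, gt, freqs):
    h = n = 0
    sf = 0.0
    for l in gt.microsat_loci:
        c = gt.call(ind, l.name)
        if c is None:
            continue
        n += 1
        h += c[0] == c[1]
        sf += freqs[l.name][c[0]] + freqs[l.name][c[1]]
    return (2 * h - sf) / (2 * n - sf)

def brute_hl(ind, gt, eh):
    num = den = 0.0
    for l in gt.microsat_loci:
        c = gt.call(ind, l.name)
        if c is None:
            continue
        den += eh[l.name]
        if c[0] == c[1]:
            num += eh[l.name]
    return num / den


def brute_qg(x, y, gt, freqs):
    def direction(gx, gy, f):
        a, b = gx
        c, d = gy
        num = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d)) - f[a] - f[b]
        den = 1 + (a == b) - f[a] - f[b]
        return num, den
    sums = [0.0, 0.0, 0.0, 0.0]
    for l in gt.microsat_loci:
        cx, cy = gt.call(x, l.name), gt.call(y, l.name)
        if cx is None or cy is None or len(freqs[l.name]) < 2:
            continue
        n1, d1 = direction(cx, cy, freqs[l.name])
        n2, d2 = direction(cy, cx, freqs[l.name])
        sums[0] += n1; sums[1] += d1; sums[2] += n2; sums[3] += d2
    return 0.5 * (sums[0] / sums[1] + sums[2] / sums[3])


def _table(calls, loci=None):
    if loci is None:
        names = sorted({n for row in calls.values() for n in row})
        loci = [Locus(n) for n in names]
    return GenotypeTable(list(calls), loci, calls)


class TestStandardizedHeterozygosity:
    def test_fully_heterozygous_against_het_half(self):
        calls = {"x": {f"L{j}": ("A", "B") for j in range(4)}}
        gt = _table(calls)
        sh = est.standardized_heterozygosity("x", gt, {f"L{j}": 0.5 for j in range(4)})
        assert sh.value == pytest.approx(2.0)
        assert sh.n_loci_used == 4

    def test_fully_homozygous_is_zero(self):
        calls = {"x": {f"L{j}": ("A", "A") for j in range(4)}}
        sh = est.standardized_heterozygosity("x", _table(calls), {f"L{j}": 0.5 for j in range(4)})
        assert sh.value == 0.0

    def test_all_missing_errors(self):
        gt = _table({"x": {"L0": None}})
        with pytest.raises(ValueError):
            est.standardized_heterozygosity("x", gt, {"L0": 0.5})

    def test_population_mean_near_one(self):
        gt = random_table(n_ind=600, seed=17)
        het = est.observed_heterozygosity(gt)
        vals = [est.standardized_heterozygosity(i, gt, het).value for i in gt.individuals]
        assert abs(np.mean(vals) - 1.0) < 0.05


class TestInternalRelatedness:
    def test_single_locus_homozygote_is_one(self):
        gt = _table({"x": {"L0": ("A", "A")}, "y": {"L0": ("A", "B")}})
        f = allele_frequencies(gt)
        assert f["L0"]["A"] == 0.75
        # IR = (2 - 1.5) / (2 - 1.5) = 1 for the homozygote, any frequency
        assert est.internal_relatedness("x", gt, f).value == pytest.approx(1.0)

    def test_single_locus_heterozygote_is_minus_one(self):
        gt = _table({"x": {"L0": ("A", "B")}, "y": {"L0": ("A", "B")}})
        f = allele_frequencies(gt)
        assert est.internal_relatedness("x", gt, f).value == pytest.approx(-1.0)


class TestHomozygosityByLocus:
    def test_extremes(self):
        het = {"x": {f"L{j}": ("A", "B") for j in range(3)}}
        hom = {"y": {f"L{j}": ("A", "A") for j in range(3)}}
        eh = {f"L{j}": 0.4 for j in range(3)}
        assert est.homozygosity_by_locus("x", _table(het), eh).value == 0.0
        assert est.homozygosity_by_locus("y", _table(hom), eh).value == 1.0


class TestBruteForceAgreement:
    """SH/IR/HL/QG against plain reimplementations, 16-locus fixtures."""

    def test_sixteen_locus_agreement(self):
        gt = random_table(n_ind=12, n_loci=16, seed=29, missing_rate=0.08)
        freqs = allele_frequencies(gt)
        het = est.observed_heterozygosity(gt)
        eh = est.expected_heterozygosity(freqs)
        for ind in gt.individuals:
            assert est.standardized_heterozygosity(ind, gt, het).value == pytest.approx(
                brute_sh(ind, gt, het), abs=1e-12
            )
            assert est.internal_relatedness(ind, gt, freqs).value == pytest.approx(
                brute_ir(ind, gt, freqs), abs=1e-12
            )
            assert est.homozygosity_by_locus(ind, gt, eh).value == pytest.approx(
                brute_hl(ind, gt, eh), abs=1e-12
            )
        inds = gt.individuals
        for x, y in zip(inds[::2], inds[1::2]):
            assert est.qg_relatedness(x, y, gt, freqs).value == pytest.approx(
                brute_qg(x, y, gt, freqs), abs=1e-12
            )


class TestQgRelatedness:
    def _two_ind(self, cx, cy):
        gt = _table({"x": {"L0": cx}, "y": {"L0": cy}})
        from matechoice.genotype_io import AlleleFrequencies

        f = AlleleFrequencies({"L0": {"A": 0.5, "B": 0.5}}, {"L0": 4})
        return gt, f

    def test_identical_homozygotes(self):
        gt, f = self._two_ind(("A", "A"), ("A", "A"))
        assert est.qg_relatedness("x", "y", gt, f).value == pytest.approx(1.0)

    def test_opposite_homozygotes(self):
        gt, f = self._two_ind(("A", "A"), ("B", "B"))
        assert est.qg_relatedness("x", "y", gt, f).value == pytest.approx(-1.0)

    def test_symmetry_is_exact(self):
        gt = random_table(n_ind=10, n_loci=8, seed=31)
        f = allele_frequencies(gt)
        for x, y in [("I000", "I001"), ("I002", "I009"), ("I004", "I005")]:
            assert (
                est.qg_relatedness(x, y, gt, f).value
                == est.qg_relatedness(y, x, gt, f).value
            )

    def test_parent_offspring_mean(self):
        gt, pairs = simulate_relative_pairs("parent_offspring", 500, seed=4)
        f = allele_frequencies(gt)
        vals = [est.qg_relatedness(a, b, gt, f).value for a, b in pairs]
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_monomorphic_locus_skipped(self):
        calls = {
            "x": {"L0": ("A", "A"), "L1": ("A", "B")},
            "y": {"L0": ("A", "A"), "L1": ("A", "A")},
        }
        gt = _table(calls)
        f = allele_frequencies(gt)
        score = est.qg_relatedness("x", "y", gt, f)
        assert score.n_loci_used == 1  # L0 monomorphic


class TestRelatednessDeviation:
    @pytest.mark.parametrize(
        "r,ref,expected", [(0.17, 0.17, 0.0), (-0.03, 0.17, 0.20), (0.37, 0.17, 0.20)]
    )
    def test_absolute_deviation(self, r, ref, expected):
        assert est.relatedness_deviation(r, ref) == pytest.approx(expected)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    p=st.floats(0.05, 0.95),
    homozygous=st.booleans(),
)
def test_single_locus_closed_forms(p, homozygous):
    """IR is +/-1 and HL is 1/0 at a single diallelic locus, any frequency."""
    from matechoice.genotype_io import AlleleFrequencies

    call = ("A", "A") if homozygous else ("A", "B")
    gt = _table({"x": {"L0": call}})
    f = AlleleFrequencies({"L0": {"A": p, "B": 1 - p}}, {"L0": 100})
    ir = est.internal_relatedness("x", gt, f).value
    hl = est.homozygosity_by_locus("x", gt, est.expected_heterozygosity(f, unbiased=False)).value
    if homozygous:
        assert ir == pytest.approx(1.0)
        assert hl == 1.0
    else:
        assert ir == pytest.approx(-1.0)
        assert hl == 0.0


class TestMhcProteins:
    @pytest.fixture
    def gt(self, mhc2_locus):
        calls = {
            "hom1": {"DRB1": ("DRB1*01", "DRB1*01")},
            "het12": {"DRB1": ("DRB1*01", "DRB1*02")},
            "collapse45": {"DRB1": ("DRB1*04", "DRB1*05")},
            "stop": {"DRB1": ("DRB1*01", "DRB1*08")},
            "stophom": {"DRB1": ("DRB1*08", "DRB1*08")},
            "f1": {"DRB1": ("DRB1*01", "DRB1*01")},
            "m23": {"DRB1": ("DRB1*02", "DRB1*03")},
        }
        return GenotypeTable(list(calls), [mhc2_locus], calls)

    def test_same_protein_collapses(self, gt):
        assert est.protein_sets("hom1", gt, "DRB1") == {"DRBp1"}
        assert est.protein_sets("collapse45", gt, "DRB1") == {"DRBp4"}

    def test_stop_codon_product_removed_when_functional_only(self, gt):
        assert est.protein_sets("stop", gt, "DRB1", functional_only=True) == {"DRBp1"}
        assert est.protein_sets("stop", gt, "DRB1", functional_only=False) == {
            "DRBp1",
            "DRBp8",
        }

    def test_diversity_counts(self, gt):
        assert est.mhc_protein_diversity("het12", gt, "DRB1").value == 2
        assert est.mhc_protein_diversity("hom1", gt, "DRB1").value == 1
        assert est.mhc_protein_diversity("stophom", gt, "DRB1").value == 0

    def test_dissimilarity_directional(self, gt):
        # male {p2,p3} vs female {p1}: 2 new proteins; reversed only 1
        assert est.mhc_protein_dissimilarity("m23", "f1", gt, "DRB1").value == 2
        assert est.mhc_protein_dissimilarity("f1", "m23", gt, "DRB1").value == 1

    def test_dissimilarity_identity(self, gt):
        for male in ("het12", "m23", "stop"):
            for female in ("hom1", "collapse45"):
                pm = est.protein_sets(male, gt, "DRB1")
                pf = est.protein_sets(female, gt, "DRB1")
                dis = est.mhc_protein_dissimilarity(male, female, gt, "DRB1").value
                assert dis + len(pm & pf) == len(pm)

    def test_missing_call_errors(self, mhc2_locus):
        gt = GenotypeTable(["x"], [mhc2_locus], {"x": {"DRB1": None}})
        with pytest.raises(ValueError):
            est.protein_sets("x", gt, "DRB1")


class TestProteinPresenceFeatures:
    def test_filter_boundaries(self, mhc2_locus):
        # protein DRBp2 carried by 1/25 = 4% -> excluded; DRBp1 by 50% -> kept
        calls = {}
        for k in range(25):
            if k == 0:
                calls[f"i{k}"] = {"DRB1": ("DRB1*02", "DRB1*03")}
            elif k < 13:
                calls[f"i{k}"] = {"DRB1": ("DRB1*01", "DRB1*03")}
            else:
                calls[f"i{k}"] = {"DRB1": ("DRB1*03", "DRB1*03")}
        gt = GenotypeTable(list(calls), [mhc2_locus], calls)
        features, dropped = est.protein_presence_features(gt, "DRB1")
        assert "DRBp2" in dropped and dropped["DRBp2"] == pytest.approx(0.04)
        assert "DRBp1" in features
        assert sum(features["DRBp1"].values()) == 12
        assert "DRBp3" in dropped  # carried by 100%

    def test_default_frequencies_pass_six_proteins(self, mhc2_locus):
        spec = default_class_II()
        rng = np.random.default_rng(77)
        probs = np.array(spec.frequencies)
        calls = {
            f"i{k}": {"DRB1": tuple(rng.choice(spec.alleles, 2, p=probs))}
            for k in range(600)
        }
        gt = GenotypeTable(list(calls), [mhc2_locus], calls)
        features, _ = est.protein_presence_features(gt, "DRB1")
        assert len(features) == 6
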