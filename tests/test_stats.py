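"""Statistic oracles: forced Table-style configurations, hand-computed
variance decompositions, exact-test enumerations and invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karstabc.io import MicrosatGenotypes, SequenceAlignment
from karstabc.stats import (
    SaturationError,
    allelic_richness,
    amova_two_groups,
    fisher_combine,
    fis_wc,
    fst_haplotype_pairwise,
    fst_microsat_pairwise,
    genic_diff_exact_mc,
    great_circle_km,
    haplotype_diversity,
    hwe_exact_mc,
    k2p_distance,
    mantel_ibd,
    microsat_summary,
    net_k2p_between_groups,
    nucleotide_diversity,
    phist_pairwise,
    rst_pairwise,
    seq_summary,
)


def _aln(seqs, ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return SequenceAlignment("test", ids, seqs)


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts, h3, sd3",
        [
            ((11,), 0.000, 0.000),          # monomorphic sample of 11
            ((6, 1), 0.286, 0.196),         # 7 sequences, two haplotypes
            ((5, 1, 1, 1), 0.643, 0.184),   # 8 sequences, four haplotypes
            ((13, 3), 0.325, 0.125),        # 16 sequences, two haplotypes
        ],
    )
    def test_forced_configurations(self, counts, h3, sd3):
        h, sd = haplotype_diversity(counts)
        assert round(h, 3) == pytest.approx(h3, abs=5e-4)
        assert round(sd, 3) == pytest.approx(sd3, abs=5e-4)

    def test_unique_composition_of_7(self):
        # among all 2-part compositions of 7, only (6,1) gives 0.286
        matches = [
            c for c in [(6, 1), (5, 2), (4, 3)]
            if round(haplotype_diversity(c)[0], 3) == 0.286
        ]
        assert matches == [(6, 1)]

    def test_invariant_under_relabeling(self, rng):
        counts = rng.integers(1, 30, size=6)
        h1, _ = haplotype_diversity(counts)
        h2, _ = haplotype_diversity(rng.permutation(counts))
        assert h1 == pytest.approx(h2)

    def test_n_below_2_error(self):
        with pytest.raises(ValueError):
            haplotype_diversity((1,))


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        pi, sd = nucleotide_diversity(_aln(["ACGT"] * 5))
        assert pi == 0 and sd == 0

    def test_two_sequences_one_diff(self):
        pi, _ = nucleotide_diversity(_aln(["AAAAAAAAAA", "AAAAAAAAAT"]))
        assert pi == pytest.approx(0.1)

    def test_three_sequence_hand_enumeration(self):
        pi, _ = nucleotide_diversity(_aln(["AAAA", "AAAT", "AATT"]))
        assert pi == pytest.approx((1 + 2 + 1) / (3 * 4.0) / 1.0, abs=1e-12)

    def test_pairwise_deletion(self):
        # the N site is ignored for the pair containing it
        pi, _ = nucleotide_diversity(_aln(["AAAA", "AAAN"]))
        assert pi == 0

    def test_toy_fixture_hand_values(self, toy):
        exp = toy["expected"]["alignment"]
        pi, sd = nucleotide_diversity(toy["alignment"])
        assert pi == pytest.approx(exp["pi"], rel=1e-9)
        assert sd == pytest.approx(exp["pi_sd"], rel=1e-9)
        counts = exp["hap_counts"]
        h, hsd = haplotype_diversity(counts)
        assert h == pytest.approx(exp["h"], rel=1e-9)
        assert hsd == pytest.approx(exp["h_sd"], rel=1e-9)


class TestSeqSummary:
    def test_monomorphic(self):
        assert seq_summary(_aln(["ACGT"] * 4)) == (1, 0, 0.0)

    def test_hand_counts(self):
        k, S, W = seq_summary(_aln(["AAAA", "AAAT", "AATT"]))
        assert (k, S) == (3, 2)
        assert W == pytest.approx(4 / 3)

    def test_two_haplotypes_combinatorial(self):
        seqs = ["AAAA"] * 6 + ["ATTT"]
        k, S, W = seq_summary(_aln(seqs))
        assert (k, S) == (2, 3)
        assert W == pytest.approx(3 * 6 * 1 / 21)

    def test_toy_fixture(self, toy):
        exp = toy["expected"]["alignment"]
        k, S, W = seq_summary(toy["alignment"])
        assert (k, S) == (exp["k"], exp["S"])
        assert W == pytest.approx(exp["W"], rel=1e-9)

    def test_order_invariance(self, rng):
        seqs = ["AAAA", "AAAT", "AATT", "CATT"]
        perm = rng.permutation(4)
        a = seq_summary(_aln(seqs))
        b = seq_summary(_aln([seqs[i] for i in perm]))
        assert a == b


class TestK2P:
    def test_identical(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10) == 0

    def test_closed_form(self):
        # 100 sites: 10 transitions (A<->G), 5 transversions (A<->C)
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        assert k2p_distance(s1, s2) == pytest.approx(0.17018, abs=1e-5)

    def test_saturation_error(self):
        s1 = "AA"
        s2 = "CC"  # Q = 1 -> 1-2Q < 0
        with pytest.raises(SaturationError):
            k2p_distance(s1, s2)

    def test_net_distance_monomorphic_groups(self):
        s1, s2 = "A" * 100, "G" * 10 + "C" * 5 + "A" * 85
        aln = _aln([s1, s1, s2, s2])
        part = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
        dA = net_k2p_between_groups(aln, part, "x", "y")
        assert dA == pytest.approx(k2p_distance(s1, s2))

    def test_net_distance_identical_monomorphic_groups(self):
        aln = _aln(["ACGTACGTCC", "ACGTACGTCC", "ACGTACGTCC", "ACGTACGTCC"])
        part = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
        assert net_k2p_between_groups(aln, part, "x", "y") == pytest.approx(0, abs=1e-12)


class TestAmovaPhist:
    def test_hand_computed_variance_decomposition(self):
        # groups {h1,h1,h2} vs {h3,h3,h3}; d(h1,h2)=1, d(h1,h3)=2, d(h2,h3)=3
        # hand AMOVA: sigma_a = 1, sigma_w = 1/6 -> Phi = 6/7
        seqs = ["AAAA", "AAAA", "AAAT", "ATTA", "ATTA", "ATTA"]
        part = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = phist_pairwise(_aln(seqs), part, "g1", "g2", n_perm=99,
                             rng=np.random.default_rng(0))
        assert res.value == pytest.approx(6 / 7)

    def test_fixed_groups_phi_one(self):
        seqs = ["AAAA"] * 3 + ["TTTT"] * 3
        part = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = phist_pairwise(_aln(seqs), part, "a", "b", 99, np.random.default_rng(0))
        assert res.value == pytest.approx(1.0)
        assert res.permutation_p <= 0.11

    def test_duplication_invariance(self):
        # duplicating every individual within groups leaves Phi unchanged
        seqs = ["AAAA", "AAAT", "AATT", "ATTT", "TTTT", "CTTT"]
        lab = np.array([0, 0, 0, 1, 1, 1])
        arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(6, 4)
        d2 = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                d2[i, j] = (arr[i] != arr[j]).sum()
        # the variance-component ratio is scale invariant asymptotically;
        # the small-sample df correction decays as duplication grows
        dup8 = np.repeat(np.arange(6), 8)
        phi8 = amova_two_groups(d2[np.ix_(dup8, dup8)], np.repeat(lab, 8))
        phi16 = amova_two_groups(d2[np.ix_(np.repeat(np.arange(6), 16),
                                           np.repeat(np.arange(6), 16))],
                                 np.repeat(lab, 16))
        assert phi16 == pytest.approx(phi8, abs=0.01)

    def test_haplotype_fst_equals_phist_on_equidistant_alleles(self):
        # all distinct alleles at distance 1 <-> identity distance
        alleles = ["x", "x", "y", "z", "z", "w"]
        labels = ["a", "a", "a", "b", "b", "b"]
        # all four haplotypes differ at the single last site: equidistant
        seqs = {"x": "AAAA", "y": "AAAC", "z": "AAAG", "w": "AAAT"}
        part = {f"s{i}": labels[i] for i in range(6)}
        res_f = fst_haplotype_pairwise(alleles, labels, "a", "b", 49,
                                       np.random.default_rng(1))
        res_p = phist_pairwise(_aln([seqs[a] for a in alleles]), part, "a", "b",
                               49, np.random.default_rng(1))
        assert res_f.value == pytest.approx(res_p.value)

    def test_null_permutation_p_uniformish(self, rng):
        # panmictic pool split at random: ~5% rejection at alpha=0.05
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            arr = rng.choice(list("ACGT"), size=(10, 8))
            seqs = ["".join(r) for r in arr]
            part = {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}
            res = phist_pairwise(_aln(seqs), part, "a", "b", 99, rng)
            hits += res.permutation_p <= 0.05
        # binomial 95% band around 0.05 for 200 reps: [0.02, 0.085]
        assert 1 <= hits <= 20


class TestMicrosatDiversity:
    def test_hand_het(self):
        # individuals AA, AB: Ho=0.5; p=(0.75,0.25), He=4/3*(1-0.625)=0.5
        from karstabc.stats import observed_expected_het
        ho, he = observed_expected_het(np.array([[1, 1], [1, 2]]))
        assert ho == pytest.approx(0.5)
        assert he == pytest.approx(0.5)

    def test_monomorphic(self):
        from karstabc.stats import observed_expected_het
        ho, he = observed_expected_het(np.array([[3, 3]] * 10))
        assert ho == 0 and he == 0

    def test_toy_fixture_values(self, toy):
        exp = toy["expected"]["genotypes"]
        geno = toy["genotypes"]
        part = {s: "pop" for s in geno.sample_ids}
        out = microsat_summary(geno, part, rarefaction_g=2,
                               rng=np.random.default_rng(0))[0]
        assert out.Ho == pytest.approx(exp["Ho_mean"])
        assert out.He == pytest.approx(exp["He_mean"])
        assert out.AR == pytest.approx(exp["AR_mean"])
        assert out.Fis == pytest.approx(exp["Fis"])


class TestAllelicRichness:
    def test_monomorphic_any_g(self):
        for g in (1, 2, 5):
            assert allelic_richness({7: 10}, g) == pytest.approx(1.0)

    def test_hand_hypergeometric(self):
        assert allelic_richness({1: 3, 2: 1}, 2) == pytest.approx(1.5)

    def test_full_rarefaction_returns_k(self):
        counts = {1: 4, 2: 3, 3: 2, 4: 1}
        assert allelic_richness(counts, 10) == pytest.approx(4.0)

    def test_nondecreasing_in_g(self):
        counts = {1: 6, 2: 3, 3: 1}
        ars = [allelic_richness(counts, g) for g in range(1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))
        assert 1 <= ars[1] <= 2

    def test_g_exceeds_copies_error(self):
        with pytest.raises(ValueError):
            allelic_richness({1: 2}, 3)


class TestFis:
    def _geno(self, pairs, loci=1):
        arr = np.array(pairs)[:, None, :] if loci == 1 else np.array(pairs)
        return MicrosatGenotypes([f"i{k}" for k in range(len(pairs))],
                                 [f"l{j}" for j in range(arr.shape[1])], arr)

    def test_all_heterozygous(self):
        g = self._geno([(1, 2)] * 6)
        assert fis_wc(g) == pytest.approx(-1.0)

    def test_hand_variance_components(self, toy):
        assert fis_wc(toy["genotypes"]) == pytest.approx(
            toy["expected"]["genotypes"]["Fis"]
        )

    def test_hw_population_near_zero(self, rng):
        p = np.array([0.5, 0.3, 0.2])
        geno = rng.choice(3, size=(2000, 1, 2), p=p) + 1
        g = MicrosatGenotypes([f"i{k}" for k in range(2000)], ["l"], geno)
        assert abs(fis_wc(g)) < 0.05

    def test_monomorphic_undefined(self):
        g = self._geno([(1, 1)] * 4)
        with pytest.raises(ValueError):
            fis_wc(g)


class TestHweExact:
    def test_levene_enumeration_aa_bb(self, toy):
        exp = toy["expected"]["hwe"]["aa_bb"]
        p = hwe_exact_mc(np.array(exp["genotypes"]), rng=np.random.default_rng(0))
        assert p == pytest.approx(exp["p"], rel=1e-9)

    def test_most_probable_config(self, toy):
        exp = toy["expected"]["hwe"]["ab_ab"]
        p = hwe_exact_mc(np.array(exp["genotypes"]), rng=np.random.default_rng(0))
        assert p == pytest.approx(1.0)

    def test_monomorphic_p_one(self):
        assert hwe_exact_mc(np.array([[2, 2]] * 5)) == 1.0

    def test_mc_agrees_with_enumeration(self, rng):
        geno = np.array([[1, 1]] * 4 + [[1, 2]] * 3 + [[2, 2]] * 2 + [[2, 3]] * 2)
        exact = hwe_exact_mc(geno, rng=rng)
        mc = hwe_exact_mc(geno, mc_reps=20000, rng=rng, enumerate_limit=0)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_uniform_under_hw(self, rng):
        # p-values from HW-simulated data are approximately uniform
        ps = []
        for _ in range(300):
            copies = rng.choice([1, 2], size=40, p=[0.6, 0.4])
            geno = copies.reshape(20, 2)
            ps.append(hwe_exact_mc(geno, rng=rng))
        # exact-test p-values are conservative/discrete; check the bulk
        assert np.mean(np.array(ps) <= 0.05) <= 0.08


class TestGenicDifferentiation:
    def test_fixed_table_enumeration(self, toy):
        exp = toy["expected"]["allele_tables"]["fixed_2x2"]
        p = genic_diff_exact_mc(np.array(exp["table"]), rng=np.random.default_rng(0))
        assert p == pytest.approx(exp["p"], rel=1e-9)

    def test_mixed_2x3_enumeration(self, toy):
        exp = toy["expected"]["allele_tables"]["mixed_2x3"]
        p = genic_diff_exact_mc(np.array(exp["table"]), rng=np.random.default_rng(0))
        assert p == pytest.approx(exp["p"], rel=1e-9)

    def test_identical_rows(self):
        p = genic_diff_exact_mc(np.array([[5, 3], [5, 3]]))
        assert p == pytest.approx(1.0)

    def test_mc_agrees_with_enumeration_small_tables(self, rng):
        for _ in range(5):
            t = rng.integers(0, 4, size=(2, 2)) + [[1, 0], [0, 1]]
            exact = genic_diff_exact_mc(t, rng=rng)
            mc = genic_diff_exact_mc(t, mc_reps=20000, rng=rng, enumerate_limit=0)
            assert mc == pytest.approx(exact, abs=0.02)

    def test_fisher_combination(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        assert fisher_combine([1e-6, 1e-6]) < 1e-8


class TestMicrosatFstRst:
    def _two_pops(self, pop1, pop2, loci=1):
        pairs = pop1 + pop2
        arr = np.array(pairs).reshape(len(pairs), loci, 2)
        ids = [f"i{k}" for k in range(len(pairs))]
        part = {f"i{k}": ("a" if k < len(pop1) else "b") for k in range(len(pairs))}
        g = MicrosatGenotypes(ids, [f"l{j}" for j in range(loci)], arr)
        return g, part

    def test_theta_hand_case(self):
        # pop1 {(10,10),(10,12)}, pop2 {(12,12),(12,12)} -> theta = 2/3
        g, part = self._two_pops([(10, 10), (10, 12)], [(12, 12), (12, 12)])
        res = fst_microsat_pairwise(g, part, "a", "b", 49, np.random.default_rng(0))
        assert res.value == pytest.approx(2 / 3)

    def test_fixed_difference_theta_one(self):
        g, part = self._two_pops([(10, 10)] * 4, [(20, 20)] * 4)
        res = fst_microsat_pairwise(g, part, "a", "b", 99, np.random.default_rng(0))
        assert res.value == pytest.approx(1.0)

    def test_panmictic_split_near_zero(self, rng):
        geno = rng.integers(10, 14, size=(40, 3, 2))
        ids = [f"i{k}" for k in range(40)]
        g = MicrosatGenotypes(ids, ["l1", "l2", "l3"], geno)
        part = {f"i{k}": ("a" if k < 20 else "b") for k in range(40)}
        res = fst_microsat_pairwise(g, part, "a", "b", 99, rng)
        assert abs(res.value) < 0.1
        assert res.permutation_p > 0.05 or abs(res.value) < 0.05

    def test_rst_fixed_sizes_one(self):
        g, part = self._two_pops([(10, 10)] * 3, [(20, 20)] * 3)
        res = rst_pairwise(g, part, "a", "b", 49, np.random.default_rng(0))
        assert res.value == pytest.approx(1.0)

    def test_rst_hand_variance_decomposition(self):
        # gene copies (10,10,10,14) vs (14,14,14,14): sigma_a=4, sigma_w=2
        g, part = self._two_pops([(10, 10), (10, 14)], [(14, 14), (14, 14)])
        res = rst_pairwise(g, part, "a", "b", 49, np.random.default_rng(0))
        assert res.value == pytest.approx(2 / 3)

    def test_rst_identical_distributions_near_zero(self, rng):
        pop = [(10, 12), (12, 14), (10, 14), (12, 12)]
        g, part = self._two_pops(pop, pop)
        res = rst_pairwise(g, part, "a", "b", 49, rng)
        assert res.value < 0.2


class TestMantel:
    def test_proportional_matrices(self, rng):
        n = 5
        geo = np.exp(rng.uniform(1, 5, size=(n, n)))
        geo = (geo + geo.T) / 2
        np.fill_diagonal(geo, 0)
        lin = np.log(geo, where=geo > 0, out=np.zeros_like(geo)) * 0.1
        diff = lin / (1 + lin)  # linearises back to exactly 0.1*ln(geo)
        r2, p = mantel_ibd(diff, geo, 999, rng)
        assert r2 == pytest.approx(1.0)
        assert p <= 0.05

    def test_exhaustive_enumeration_four_units(self, rng):
        n = 4
        diff = np.array([[0, .1, .3, .2], [.1, 0, .15, .25],
                         [.3, .15, 0, .05], [.2, .25, .05, 0]])
        geo = np.array([[0, 10, 40, 80], [10, 0, 20, 60],
                        [40, 20, 0, 30], [80, 60, 30, 0]], dtype=float)
        iu = np.triu_indices(n, 1)
        lin = diff / (1 - diff)

        def corr(perm):
            lp = lin[np.ix_(perm, perm)][iu]
            return np.corrcoef(lp, np.log(geo[iu]))[0, 1]

        obs = corr(np.arange(n))
        exact = np.mean([
            corr(np.array(pm)) >= obs - 1e-12
            for pm in itertools.permutations(range(n))
        ])
        r2, p = mantel_ibd(diff, geo, 4999, rng)
        assert r2 == pytest.approx(obs**2)
        assert p == pytest.approx(exact, abs=0.03)

    def test_fst_one_excluded_with_warning(self, rng):
        diff = np.array([[0, 1.0, .2], [1.0, 0, .1], [.2, .1, 0]])
        geo = np.full((3, 3), 10.0)
        np.fill_diagonal(geo, 0)
        with pytest.warns(UserWarning, match="excluded"):
            mantel_ibd(diff, geo, 99, rng)

    def test_great_circle(self):
        # one degree of longitude at the equator
        d = great_circle_km(0, 0, 0, 1)
        assert d == pytest.approx(6371 * math.pi / 180, rel=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(counts=st.lists(st.integers(1, 40), min_size=2, max_size=8))
def test_h_in_unit_interval(counts):
    h, sd = haplotype_diversity(counts)
    assert 0 <= h <= 1 and sd >= 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data())
def test_permutation_p_in_half_open_interval(data):
    n_per_side = data.draw(st.integers(2, 5))
    rng_loc = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    arr = rng_loc.choice(list("ACGT"), size=(2 * n_per_side, 6))
    seqs = ["".join(r) for r in arr]
    part = {f"s{i}": ("a" if i < n_per_side else "b") for i in range(2 * n_per_side)}
    res = phist_pairwise(_aln(seqs), part, "a", "b", 49, rng_loc)
    assert 0 < res.permutation_p <= 1
    # attainable values of (b+1)/(B+1)
    assert round(res.permutation_p * 50) == pytest.approx(res.permutation_p * 50)
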